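# Methods

This note documents the models, defaults and numerical choices behind
`capacitrack`, and what the synthetic-data tests do and do not establish
about real data.

## Data model and units

Expression arrives as genes × samples tables in one of three tagged units:
`counts`, `fpkm` (both non-negative) or `log2fpkm`. All statistics that
are ratios of moments (means, CV²) are computed on the linear FPKM scale;
clustering, correlation and PCA operate on log₂(FPKM + pseudocount). The
pseudocount defaults to 1 (log₂(FPKM+1)), the field's usual convention; a
separate floor of 10⁻⁶ FPKM is applied only where a bare logarithm of a
mean is needed (the CV² trend), to keep it finite. "Expressed" defaults
to FPKM ≥ 1 in ≥ 1 sample; both knobs are exposed
(`expression.min_fpkm`, `expression.min_samples` in the config).

Gene identifiers are opaque strings. Cross-species work restricts both
matrices to strictly 1-to-1 rows of an ortholog table — a row survives
only if its gene appears exactly once on each side of the whole table, so
many-to-one families are discarded entirely rather than resolved.

## Variable genes

For gene g with linear-scale mean μ_g and variance σ²_g (ddof = 1),
CV²_g = σ²_g/μ²_g. The trend

  log CV² = log(a₁/μ + a₀),  a₀, a₁ ≥ 0

is fitted by bounded nonlinear least squares in (log μ, log CV²) space
over genes with mean ≥ 0.1 FPKM and CV² > 0, initialized at
a₀ = median CV², a₁ = median(CV²·μ). The a₁/μ term captures
sampling-noise inflation at low expression; a₀ is the mean-independent
noise floor. Selection takes genes with mean log₂ FPKM ≥ 0.5 and excess
log CV² ≥ 1 natural-log unit (≈ 2.7× the trend); both thresholds are
configurable, ordered by descending excess with ties broken by gene id.
If every floored gene is exactly constant the trend degenerates to
a₀ = a₁ = 0 rather than failing.

## Differential expression stand-in

The time-course DE stage exists to feed the downstream filter
(padj < 0.01, fold change > 2) and the pairwise-count/union operations,
not to model counts. It is a Welch *t*-test per gene on log₂(FPKM+1) with
Benjamini–Hochberg adjustment across all tested genes; fold changes are
ratios of linear-scale group means with pseudocount 1. Degenerate genes
(zero variance in both groups) get p = 1 when the means agree and the
smallest positive double when they differ. A `p_values` hook lets an
external engine's per-gene p-values replace the built-in test while
keeping the filter and union logic. The union operation collects
significant genes over all timepoint pairs within each cell line.

## Soft clustering

Replicates are averaged per timepoint, then each gene's profile is
z-scored across timepoints (ddof = 1); exactly flat genes are dropped and
counted. Fuzzy c-means uses the classical alternating updates with
Euclidean distance; memberships row-normalize at every iteration and the
objective J = Σ u^m d² is non-increasing (asserted per iteration in
tests). Numerical choices:

* fuzzifier m = 1.25 (small-m regime typical of temporal-profile
  clustering; m → 1 recovers hard k-means), configurable;
* initialization on k distinct genes sampled without replacement from a
  seeded generator; 10 restarts with best-objective selection, because
  the algorithm is init-sensitive;
* membership powers are computed on distances normalized by the row
  minimum, so small fuzzifiers cannot overflow; a gene coinciding exactly
  with a centroid receives membership 1 there (limit convention);
* hard assignments take the argmax membership, ties to the lowest
  cluster id;
* convergence when the maximum centroid shift falls below 10⁻⁶, cap 300
  iterations.

**Cluster number.** J(k) is the hard within-cluster sum of squares of the
best multi-start run per k. The elbow is the interior k maximizing the
second difference of **log** J(k). On the linear scale the second
difference is dominated by the geometric decay of J at small k and, on
five-archetype data, peaks at k = 3; the log-scale curvature measures
relative improvement and reliably flattens past the true k. When the
strongest curvature is below 0.05 log-units the selection is flagged
low-confidence (featureless curve, e.g. single-archetype data).

**Semantic labels (k = 5).** Per centroid: net change Δ = last − first,
range, and interior-extremum prominence (how far the trajectory over- or
undershoots both endpoints strictly inside the course). The up-and-down
cluster is the centroid with positive prominence and |Δ| < 0.5·range
(largest prominence wins; exact ties are an error). Using an extremum of
either sign keeps the labeling consistent under sign flips of the data,
which swap the four directional labels and leave up-and-down fixed. The
remaining four centroids must split 2/2 by sign of Δ; within each pair
the centroid whose interpolated half-change time is earlier is "early".
Any other geometry raises a labeling error with diagnostics rather than
guessing.

**Enrichment.** Per (hard cluster, gene set): one-sided hypergeometric
upper tail restricted to a user-supplied universe, BH-adjusted across all
(cluster, set) pairs.

## Cluster correspondence

Cluster ids of two datasets are reconciled by an assignment-problem
optimum (Hungarian) on Pearson correlation between standardized
centroids, with the shorter time axis linearly interpolated onto the
longer; a mean matched correlation below 0.5 flags the match
low-confidence. When both clusterings carry semantic labels, label
identity defines the mapping and a disagreement with the correlation
optimum raises a warning. Labeled clusterings are recast into the
canonical numbering (1 = early down … 5 = late up) before a grouping
scheme is applied, so scheme cluster ids always mean the same archetypes.

Two "similar cluster" schemes ship as presets, because the within-line
and embryo-vs-line comparisons group clusters differently:
`hpsc_vs_hpsc` (down {1,2}/{1,2}, up {4,5}/{4,5}) and `embryo_vs_hpsc`
(down {1,2}/{1,2}, up {3,4,5}/{4,5} — the embryo's cluster 3 rises and
stays up, the in vitro cluster 3 returns to baseline, so cluster 3 joins
the upregulated group on the embryo side only). A gene is "same" when its
mapped cluster ids agree, "similar" when they differ but share a scheme
group, otherwise "neither"; in particular in vitro cluster-3 genes that
the scheme leaves ungrouped count as "neither". The comparison universe
defaults to genes clustered in both datasets (intersection); genes absent
from one side are tallied as dropped, not errors, and
n_same + n_similar + n_neither = n_compared exactly.

## Fractional stage identity

Signatures are arithmetic means of reference cells per stage on linear
FPKM (mixtures are additive on that scale), restricted to the harmonized
analysis gene set — by default the same variable/DE genes the trajectory
analyses use; both the gene set and the scale are configurable since
reasonable pipelines differ here. The decomposition

  min_f ‖S f − x‖₂²  s.t. f ≥ 0, 1ᵀf = 1

is solved exactly: every support (non-empty subset of stages) yields an
equality-constrained least-squares problem whose sum-to-one constraint is
eliminated by the null-space substitution f = e₁ + Z y, leaving a
well-conditioned rectangular least squares on the original data scale
(the raw KKT system of the normal equations mixes ~10⁸-scale entries
with unit constraint rows and is numerically singular). The optimum of
the inequality-constrained program is the feasible support solution with
least objective; with the typical 3–4 stages the 2^k − 1 supports are
enumerated exhaustively (an SQP refinement guards the pathological
k > 12 case). Rank deficiency on the winning support is flagged as
non-uniqueness, not an error. An independent penalty solver (NNLS on the
system augmented with a heavily weighted sum row) and a simplex grid
search serve as cross-check oracles in the tests only.

ICM-like stages can appear in PCA displays while being excluded from the
signature basis; the default basis is EPI / post-E / post-L.

## Sample-level statistics

Pearson correlation and PCA run on log₂ values. PCA mean-centers each
gene, decomposes by SVD, and fixes each component's sign so its
largest-magnitude gene loading is positive (cross-platform determinism).
Zero-variance samples get NaN correlations and are reported. The joint
projection concatenates harmonized time-course and reference samples with
no batch correction — methodological offsets are part of the reported
geometry, not modeled away.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *design* of a capacitation study: a 6-
timepoint × 3-replicate × 2-cell-line bulk time course whose variable
genes follow five archetypal log₂-mean trajectories ("early" completes
its change by the 2nd of 6 timepoints, "late" starts after the 3rd,
up-and-down is a mid-course triangle; base levels uniform on 1–9 log₂
FPKM, amplitudes 2–5 log₂ units), a stage-annotated reference whose
signatures combine stage-specific marker blocks (full column rank, hence
identifiable deconvolution) with monotone gradient genes (stages order
along a trajectory axis, emulating developmental progression), known
simplex mixtures of those signatures, ortholog tables with many-to-one
decoys, and GMT sets optionally enriched for one archetype.

Noise is multiplicative log-normal on the linear-scale mean with
σ² = ln(1 + CV²) and unit expectation, so the realized coefficient of
variation equals `noise_cv` exactly and `noise_cv = 0` returns the
planted means bitwise. Replicate dispersion of real bulk libraries is not
calibrated to any particular study — `noise_cv` defaults (0.15–0.2 in the
demo and tests) are plausible round values, and the planted means are
shared across the two pseudo-cell-lines. Consequently the demo's
correspondence fractions are near 100% by construction; they exercise the
machinery, they do not predict the agreement level of real cell lines.
The generators also omit count noise (a negative-binomial count mode is
out of scope of the analyses here), dropout, batch structure,
library-size artefacts and read-level data, so passing tests demonstrate
correctness of the algorithms under the stated noise model, not
robustness to those real-data pathologies.

Problem sizes used by the test suite and the acceptance script — 500–
5000 genes, 20–100 mixtures, 20 elbow replicates, a 1200-gene demo —
were chosen as the smallest scales at which the planted structure is
statistically unambiguous (e.g. binomial CIs of ±4% at n = 500 for the
correspondence fractions).

## Known limitations

* The DE stand-in is a normal-theory test on transformed abundances; it
  is exact for the package's log-normal generator but is not a count
  model, and padj/fold-change lists on real count data will differ from
  dispersion-shrinkage engines.
* The elbow criterion assumes J(k) is measured on a consistent multi-
  start protocol; with very few restarts the non-increase of J(k) in k
  is not guaranteed.
* Semantic labeling is defined only for k = 5 and refuses ambiguous
  centroid geometry instead of guessing.
* Correspondence fractions carry no significance statement; they are
  descriptive proportions.
* Deconvolution assumes the sample is a convex combination of the given
  signatures; scaling a sample changes fractions continuously, and
  recovery guarantees are asserted for unscaled mixtures only.
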