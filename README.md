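# capacitrack

Transcriptome-trajectory analysis of pluripotent stem cell **capacitation**
— the formative transition by which naïve (pre-implantation-like) human
pluripotent stem cells acquire competence for lineage induction over a
~10-day time course. The package is written for computational biologists
who want to characterize such bulk/single-cell expression time courses and
compare them with embryonic epiblast references:

* **Variable-gene detection** — per gene, the squared coefficient of
  variation CV² = σ²/μ² (linear FPKM) is regressed on mean expression with
  the standard trend log CV² = log(a₁/μ + a₀); genes are selected by
  thresholds on mean log₂ FPKM (x-axis) and on the excess of observed
  log CV² over the fitted trend (y-axis).
* **Time-course differential expression** — Welch *t* on log₂(FPKM+1) with
  Benjamini–Hochberg adjustment, filtered at padj < 0.01 and fold change
  > 2, unioned over all timepoint pairs within each cell line.
* **Soft clustering of temporal dynamics** — fuzzy c-means on standardized
  per-timepoint profiles, minimizing J = Σ_{g,c} u_{gc}^m ‖x_g − v_c‖²;
  the cluster number is chosen by an elbow criterion on the
  within-cluster sum of squares, and k = 5 clusters receive semantic
  labels (early down, late down, up-and-down, early up, late up) from
  centroid geometry.
* **Cluster correspondence** — fractions of shared genes assigned to the
  *same* cluster, or to a *similar* cluster (different dynamics, same
  direction group), between cell lines or between species through a
  strictly 1-to-1 ortholog map.
* **Fractional stage identity** — each sample x is decomposed onto
  embryonic epiblast stage signatures S (per-stage mean expression of
  reference cells; EPI, post-E, post-L) by the quadratic program
  min_f ‖S f − x‖² s.t. f ≥ 0, Σf = 1, solved exactly by active-set
  enumeration.
* **Global sample statistics** — Pearson correlation structure, PCA
  trajectories (including joint projections of time-course samples with
  reference cells), pairwise variable-gene count tables.

A synthetic-data module generates every input — archetypal time courses,
stage-annotated references, known signature mixtures, ortholog maps with
decoys, GMT gene sets — with planted, recorded ground truth, so the whole
pipeline is testable without any external download.

## Worked example

Generate a synthetic bundle and run the full pipeline:

```bash
capacitrack demo --seed 3 --out d
capacitrack run --config d/config.yaml
```

The demo plants 1200 genes (400 variable across five temporal archetypes)
over 6 timepoints × 3 replicates × 2 pseudo-cell-lines, plus a 4-stage
embryo-like reference connected through a 90% 1-to-1 ortholog map. The run
log ends with `run complete: d/run/manifest.json`; the manifest records
the analysis funnel (1200 genes in, 400 in the DE union, k = 5 per cell
line) and every output TSV. Individual stages are also exposed:

```text
$ capacitrack hvg d/timecourse.tsv --out hvg.tsv
373 variable genes (a0=0.06439, a1=6.765e-20)

$ capacitrack correspond d/run/membership_CL1.tsv d/run/centroids_CL1.tsv \
      d/run/membership_CL2.tsv d/run/centroids_CL2.tsv
n=400: same 100.0%, same-or-similar 100.0%

$ capacitrack identity d/timecourse.tsv d/samples.tsv d/reference.tsv \
      d/reference_samples.tsv --orthologs d/orthologs.tsv | head -4
timepoint  stage  mean_fraction  sd_fraction  n
       d0    EPI       0.510274     0.005622  6
       d0 post-E       0.420591     0.016498  6
       d0 post-L       0.069134     0.011436  6
```

The HVG line reports the fitted trend (a₀ ≈ 0.064 is the asymptotic CV² of
the demo's noisy genes; a₁ ≈ 0 because the planted noise is
mean-independent). The correspondence line shows that the two pseudo-lines
— which share planted trajectories by construction — fall into identical
clusters. The identity table gives, per timepoint, the mean ± s.d. stage
fractions over replicates of both cell lines; each timepoint's three
fractions sum to 1.

Exit codes: 0 success, 2 configuration error, 3 data/format error,
4 numerical failure.

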