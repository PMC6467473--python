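"""Synthetic expression data with planted, recorded ground truth.

Every downstream stage of the package (variable-gene detection, soft
clustering, cluster correspondence, stage deconvolution) is exercised on
data produced here, so each generator plants the quantity the stage is
supposed to recover and records it in a :class:`PlantedTruth` sidecar:

* a bulk time course in which variable genes follow one of five temporal
  archetypes (early down, late down, up-and-down, early up, late up) on a
  flat non-variable background;
* a stage-annotated single-cell-like reference whose per-stage means act as
  deconvolution signatures, combining stage-specific marker blocks (for
  identifiability) with monotone "developmental gradient" genes (so stages
  order along a principal trajectory axis);
* samples that are known simplex mixtures of those signatures;
* ortholog maps with a controlled fraction of 1-to-1 rows plus
  many-to-one decoys;
* GMT gene sets, optionally enriched for one archetype.

Noise is multiplicative log-normal on the linear (FPKM-scale) mean, with
sigma chosen so the realized coefficient of variation equals ``noise_cv``
and the expectation equals the planted mean. All generators are pure
functions of their arguments including ``seed``; ``noise_cv=0`` returns the
planted means exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, SampleSheet

#: The five temporal archetypes of variable genes, in canonical order
#: (cluster 1..5); non-variable genes carry the label "background".
ARCHETYPES = ("early_down", "late_down", "up_n_dn", "early_up", "late_up")

#: Directional archetypes grouped by direction; partners within a group share
#: the direction of change but differ in timing ("similar clusters").
DIRECTION_GROUPS = {
    "down": ("early_down", "late_down"),
    "up": ("early_up", "late_up"),
}

_TIMING_PARTNER = {
    "early_down": "late_down", "late_down": "early_down",
    "early_up": "late_up", "late_up": "early_up",
}


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators.

    gene_archetype maps every gene to an archetype label (or "background");
    hvg_flags marks the genes planted as highly variable; stage_fractions
    records the simplex mixing vector of each mixture sample;
    ortholog_pairs lists the planted 1-to-1 pairs.
    """

    gene_archetype: dict[str, str] = field(default_factory=dict)
    hvg_flags: dict[str, bool] = field(default_factory=dict)
    stage_fractions: dict[str, list[float]] = field(default_factory=dict)
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        valid = set(ARCHETYPES) | {"background"}
        bad = {a for a in self.gene_archetype.values() if a not in valid}
        if bad:
            raise ValueError(f"unknown archetype labels: {sorted(bad)}")
        for sample, f in self.stage_fractions.items():
            arr = np.asarray(f, dtype=float)
            if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-12:
                raise ValueError(f"stage fractions of {sample!r} are off the simplex")
        a_side = [a for a, _ in self.ortholog_pairs]
        b_side = [b for _, b in self.ortholog_pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("ortholog_pairs is not a bijection")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_archetype": self.gene_archetype,
            "hvg_flags": self.hvg_flags,
            "stage_fractions": self.stage_fractions,
            "ortholog_pairs": [list(p) for p in self.ortholog_pairs],
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            gene_archetype=d["gene_archetype"],
            hvg_flags={k: bool(v) for k, v in d["hvg_flags"].items()},
            stage_fractions=d["stage_fractions"],
            ortholog_pairs=[tuple(p) for p in d["ortholog_pairs"]],
            seed=int(d["seed"]),
        )


# ---------------------------------------------------------------------------
# helpers


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation ``cv``."""
    if cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv * cv)
    return np.exp(rng.normal(0.0, np.sqrt(sigma2), shape) - sigma2 / 2.0)


def archetype_level_profiles(
    n_timepoints: int,
    early_end: float = 0.2,
    late_start: float = 0.6,
) -> dict[str, np.ndarray]:
    """Relative log2-level profiles h(t) in [0, 1] for the five archetypes.

    Timepoints sit at equally spaced positions on [0, 1]. "Early" changes
    ramp linearly over [0, early_end] (complete by the 2nd of 6 timepoints
    at the defaults), "late" changes over [late_start, 1] (none before the
    4th of 6), and up-and-down is a triangle peaking mid-course. Downward
    archetypes start high and end low.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    pos = np.linspace(0.0, 1.0, n_timepoints)

    def ramp(a: float, b: float) -> np.ndarray:
        return np.clip((pos - a) / (b - a), 0.0, 1.0)

    g_early, g_late = ramp(0.0, early_end), ramp(late_start, 1.0)
    g_mid = 1.0 - np.abs(pos - 0.5) / 0.5
    return {
        "early_down": 1.0 - g_early,
        "late_down": 1.0 - g_late,
        "up_n_dn": g_mid,
        "early_up": g_early,
        "late_up": g_late,
    }


def _default_gene_ids(n: int, prefix: str = "GENE") -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(n)]


# ---------------------------------------------------------------------------
# time course


def generate_timecourse_from_archetypes(
    gene_archetype: Mapping[str, str],
    timepoints: Sequence[str],
    n_replicates: int,
    n_cell_lines: int,
    noise_cv: float,
    seed: int,
    base_log2_range: tuple[float, float] = (1.0, 9.0),
    amplitude_log2_range: tuple[float, float] = (2.0, 5.0),
    cell_line_names: Sequence[str] | None = None,
) -> tuple[ExpressionMatrix, SampleSheet, PlantedTruth]:
    """Bulk FPKM time course realizing an explicit gene -> archetype map.

    Per gene, the log2 mean trajectory is ``base + amplitude * h(t)`` with
    h the archetype's relative level profile (background genes are flat at
    ``base``); planted means are shared across cell lines so that the two
    pseudo-lines follow the same trajectory. Observed FPKM is the planted
    linear-scale mean times log-normal noise of coefficient of variation
    ``noise_cv``.
    """
    if len(timepoints) < 2:
        raise ValueError("need at least 2 timepoints")
    if n_replicates < 1 or n_cell_lines < 1:
        raise ValueError("replicate and cell-line counts must be positive")
    genes = [str(g) for g in gene_archetype]
    n_genes = len(genes)
    if n_genes == 0:
        raise ValueError("empty gene set")
    rng = np.random.default_rng(seed)
    profiles = archetype_level_profiles(len(timepoints))

    base = rng.uniform(*base_log2_range, n_genes)
    amp = rng.uniform(*amplitude_log2_range, n_genes)
    log2_mean = np.tile(base[:, None], (1, len(timepoints)))
    for i, g in enumerate(genes):
        arch = gene_archetype[g]
        if arch != "background":
            log2_mean[i] = base[i] + amp[i] * profiles[arch]
    mean_fpkm = np.power(2.0, log2_mean)

    if cell_line_names is None:
        cell_line_names = [f"CL{i + 1}" for i in range(n_cell_lines)]
    elif len(cell_line_names) != n_cell_lines:
        raise ValueError("cell_line_names length must equal n_cell_lines")

    columns, rows, data = [], [], []
    for line in cell_line_names:
        for t_idx, tp in enumerate(timepoints):
            for rep in range(1, n_replicates + 1):
                sid = f"{line}.{tp}.r{rep}"
                columns.append(sid)
                rows.append((sid, line, str(line), str(tp), f"r{rep}"))
                noise = _lognormal_factors(rng, noise_cv, n_genes)
                data.append(mean_fpkm[:, t_idx] * noise)
    values = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    sheet = SampleSheet(
        pd.DataFrame(
            [r[1:] for r in rows],
            index=pd.Index([r[0] for r in rows], name="sample"),
            columns=["dataset", "cell_line", "timepoint", "replicate"],
        )
    )
    truth = PlantedTruth(
        gene_archetype=dict(gene_archetype),
        hvg_flags={g: gene_archetype[g] != "background" for g in genes},
        seed=seed,
    )
    return ExpressionMatrix(values, "fpkm"), sheet, truth


def generate_timecourse(
    n_genes: int,
    n_variable: int,
    timepoints: Sequence[str],
    n_replicates: int,
    n_cell_lines: int,
    noise_cv: float,
    seed: int,
) -> tuple[ExpressionMatrix, SampleSheet, PlantedTruth]:
    """Time course with ``n_variable`` archetype genes (equal-sized groups up
    to rounding, assigned to randomly chosen genes) on a flat background."""
    if n_genes <= 0 or n_variable <= 0:
        raise ValueError("n_genes and n_variable must be positive")
    if n_variable > n_genes:
        raise ValueError("n_variable cannot exceed n_genes")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA1]))
    genes = _default_gene_ids(n_genes)
    variable = sorted(rng.choice(n_genes, size=n_variable, replace=False).tolist())
    archetype_map = {g: "background" for g in genes}
    for chunk, arch in zip(np.array_split(np.asarray(variable), len(ARCHETYPES)),
                           ARCHETYPES):
        for i in chunk:
            archetype_map[genes[int(i)]] = arch
    return generate_timecourse_from_archetypes(
        archetype_map, timepoints, n_replicates, n_cell_lines, noise_cv, seed
    )


# ---------------------------------------------------------------------------
# stage reference and mixtures


def generate_stage_reference(
    n_genes: int,
    stages: Sequence[str],
    cells_per_stage: int,
    separation: float,
    noise_cv: float,
    seed: int,
    marker_fraction: float = 0.4,
    gradient_fraction: float = 0.4,
    gene_ids: Sequence[str] | None = None,
) -> tuple[ExpressionMatrix, SampleSheet]:
    """Stage-annotated reference cells with distinct per-stage signatures.

    Three planted gene classes shape the signatures:

    * marker genes (``marker_fraction`` of genes, split round-robin across
      stages) are shifted up by ``separation`` log2 units in their stage
      only — this keeps the signature matrix full column rank;
    * gradient genes (``gradient_fraction``) increase or decrease linearly
      with stage index by up to ``separation`` log2 units — this places the
      stage centroids in order along a single trajectory axis, emulating a
      developmental progression;
    * the remainder are flat background.

    ``separation=0`` collapses all stage means onto a common profile.
    """
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    if n_genes <= 0 or cells_per_stage <= 0:
        raise ValueError("sizes must be positive")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    genes = list(gene_ids) if gene_ids is not None else _default_gene_ids(n_genes)
    if len(genes) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    n_stages = len(stages)

    base = rng.uniform(1.0, 8.0, n_genes)
    log2_mean = np.tile(base[:, None], (1, n_stages))
    n_marker = int(round(n_genes * marker_fraction))
    n_grad = int(round(n_genes * gradient_fraction))
    grad_pos = np.linspace(0.0, 1.0, n_stages)
    for i in range(n_marker):
        log2_mean[i, i % n_stages] += separation
    for j in range(n_grad):
        i = n_marker + j
        if i >= n_genes:
            break
        sign = 1.0 if j % 2 == 0 else -1.0
        log2_mean[i] = base[i] + sign * separation * grad_pos
    mean_fpkm = np.power(2.0, log2_mean)

    columns, rows, data = [], [], []
    for s_idx, stage in enumerate(stages):
        for c in range(1, cells_per_stage + 1):
            sid = f"{stage}.c{c}"
            columns.append(sid)
            rows.append((sid, "reference", "embryo", str(stage), f"c{c}"))
            noise = _lognormal_factors(rng, noise_cv, n_genes)
            data.append(mean_fpkm[:, s_idx] * noise)
    values = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    sheet = SampleSheet(
        pd.DataFrame(
            [r[1:] for r in rows],
            index=pd.Index([r[0] for r in rows], name="sample"),
            columns=["dataset", "cell_line", "timepoint", "replicate"],
        )
    )
    return ExpressionMatrix(values, "fpkm"), sheet


def generate_mixtures(
    signatures,
    fractions: Sequence[Sequence[float]],
    noise_cv: float,
    seed: int,
    sample_ids: Sequence[str] | None = None,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Samples whose mean is a known simplex combination of stage signatures.

    ``signatures`` is a :class:`~capacitrack.stage_identity.SignatureSet`
    (or any object with a genes x stages ``matrix`` DataFrame). Each
    fraction vector must be non-negative and sum to 1 within 1e-9; it is
    renormalized exactly before use and recorded in the returned truth.
    """
    S = signatures.matrix if hasattr(signatures, "matrix") else signatures
    S = pd.DataFrame(S)
    rng = np.random.default_rng(seed)
    n_genes, n_stages = S.shape
    used: list[np.ndarray] = []
    for j, f in enumerate(fractions):
        arr = np.asarray(f, dtype=float)
        if arr.shape != (n_stages,):
            raise ValueError(f"fraction vector {j} has length {arr.size}, expected {n_stages}")
        if arr.min() < -1e-9 or abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"fraction vector {j} is off the probability simplex")
        arr = np.clip(arr, 0.0, None)
        used.append(arr / arr.sum())
    if sample_ids is None:
        sample_ids = [f"mix{j:03d}" for j in range(len(used))]
    data = {}
    for sid, f in zip(sample_ids, used):
        mean = S.to_numpy() @ f
        data[sid] = mean * _lognormal_factors(rng, noise_cv, n_genes)
    values = pd.DataFrame(data, index=S.index)
    truth = PlantedTruth(
        stage_fractions={str(s): f.tolist() for s, f in zip(sample_ids, used)},
        seed=seed,
    )
    return ExpressionMatrix(values, "fpkm"), truth


# ---------------------------------------------------------------------------
# orthologs, gene sets, benchmark variability data


def generate_ortholog_map(
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    frac_one_to_one: float,
    seed: int,
) -> pd.DataFrame:
    """Two-column ortholog table: a planted bijection on a fraction of genes
    plus many-to-one decoy rows that strict 1-to-1 filtering must drop.

    Decoy rows map each remaining A-gene to two B-genes drawn from the
    leftover B pool, so neither side of a decoy row is unique.
    """
    if not 0.0 <= frac_one_to_one <= 1.0:
        raise ValueError("frac_one_to_one must lie in [0, 1]")
    genes_a, genes_b = [str(g) for g in genes_a], [str(g) for g in genes_b]
    if not genes_a or not genes_b:
        return pd.DataFrame(columns=["gene_a", "gene_b"])
    rng = np.random.default_rng(seed)
    n = min(len(genes_a), len(genes_b))
    n_bij = int(round(frac_one_to_one * n))
    perm_a = [genes_a[i] for i in rng.permutation(len(genes_a))]
    perm_b = [genes_b[i] for i in rng.permutation(len(genes_b))]
    rows = list(zip(perm_a[:n_bij], perm_b[:n_bij]))
    leftover_b = perm_b[n_bij:]
    for a in perm_a[n_bij:n]:
        if not leftover_b:
            break
        picks = rng.choice(len(leftover_b), size=2, replace=len(leftover_b) < 2)
        for p in picks:
            rows.append((a, leftover_b[int(p)]))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b"])


def generate_gene_sets(
    genes: Sequence[str],
    n_sets: int,
    set_size: int,
    enriched_cluster: str | None = None,
    gene_archetype: Mapping[str, str] | None = None,
    enrichment_purity: float = 0.8,
    seed: int = 0,
) -> dict[str, list[str]]:
    """GMT-style gene sets drawn from ``genes``; when ``enriched_cluster``
    is given, the first set draws at least ``enrichment_purity`` of its
    members from genes of that archetype (requires ``gene_archetype``)."""
    genes = [str(g) for g in genes]
    if set_size > len(genes):
        raise ValueError("set_size cannot exceed the number of genes")
    if n_sets <= 0 or set_size <= 0:
        raise ValueError("n_sets and set_size must be positive")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    start = 0
    if enriched_cluster is not None:
        if gene_archetype is None:
            raise ValueError("gene_archetype map required for an enriched set")
        pool = [g for g in genes if gene_archetype.get(g) == enriched_cluster]
        n_from = min(len(pool), int(np.ceil(enrichment_purity * set_size)))
        if n_from == 0:
            raise ValueError(f"no genes with archetype {enriched_cluster!r}")
        members = [pool[i] for i in rng.choice(len(pool), n_from, replace=False)]
        others = [g for g in genes if g not in set(members)]
        extra = rng.choice(len(others), set_size - n_from, replace=False)
        members += [others[int(i)] for i in extra]
        sets[f"SET_ENRICHED_{enriched_cluster}"] = sorted(members)
        start = 1
    for k in range(start, n_sets):
        idx = rng.choice(len(genes), set_size, replace=False)
        sets[f"SET{k:02d}"] = sorted(genes[int(i)] for i in idx)
    return sets


def generate_hvg_dataset(
    n_genes: int,
    n_hvg: int,
    n_samples: int,
    cv_background: float = 0.1,
    cv_hvg: float = 0.6,
    seed: int = 0,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Variability benchmark: flat-mean genes whose noise CV is either
    ``cv_background`` or, for ``n_hvg`` randomly chosen genes, ``cv_hvg``.
    Mean expression is log-uniform over ~2..512 FPKM so the CV2-vs-mean
    trend is probed across the expression range."""
    if n_hvg > n_genes:
        raise ValueError("n_hvg cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = _default_gene_ids(n_genes)
    hvg_idx = set(rng.choice(n_genes, n_hvg, replace=False).tolist())
    mean_fpkm = np.power(2.0, rng.uniform(1.0, 9.0, n_genes))
    cvs = np.where([i in hvg_idx for i in range(n_genes)], cv_hvg, cv_background)
    data = np.empty((n_genes, n_samples))
    for i in range(n_genes):
        data[i] = mean_fpkm[i] * _lognormal_factors(rng, float(cvs[i]), n_samples)
    values = pd.DataFrame(data, index=genes,
                          columns=[f"s{j:03d}" for j in range(n_samples)])
    truth = PlantedTruth(
        gene_archetype={g: "background" for g in genes},
        hvg_flags={g: (i in hvg_idx) for i, g in enumerate(genes)},
        seed=seed,
    )
    return ExpressionMatrix(values, "fpkm"), truth


def generate_correspondence_truth(
    n_directional: int = 500,
    n_up_n_dn: int = 125,
    p_same: float = 0.6,
    p_similar: float = 0.25,
    p_opposite: float = 0.15,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """Paired archetype maps for a planted cross-dataset comparison.

    Dataset A assigns the four directional archetypes round-robin to
    ``n_directional`` genes (plus ``n_up_n_dn`` up-and-down genes so both
    datasets still carry five clusters). Dataset B's archetype per
    directional gene is drawn from exact planted proportions: ``p_same``
    keep A's archetype, ``p_similar`` switch to the same-direction partner
    of different timing, ``p_opposite`` flip direction. Returns
    (archetypes_a, archetypes_b, category per directional gene).
    """
    if abs(p_same + p_similar + p_opposite - 1.0) > 1e-9:
        raise ValueError("category probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    directional = [a for a in ARCHETYPES if a != "up_n_dn"]
    genes = _default_gene_ids(n_directional + n_up_n_dn)
    arch_a: dict[str, str] = {}
    for i in range(n_directional):
        arch_a[genes[i]] = directional[i % len(directional)]
    for i in range(n_directional, len(genes)):
        arch_a[genes[i]] = "up_n_dn"

    n_same = int(round(p_same * n_directional))
    n_sim = int(round(p_similar * n_directional))
    cats = np.array(["same"] * n_same + ["similar"] * n_sim
                    + ["opposite"] * (n_directional - n_same - n_sim))
    cats = cats[rng.permutation(n_directional)]

    arch_b: dict[str, str] = {}
    categories: dict[str, str] = {}
    for i in range(n_directional):
        g, a = genes[i], arch_a[genes[i]]
        cat = str(cats[i])
        categories[g] = cat
        if cat == "same":
            arch_b[g] = a
        elif cat == "similar":
            arch_b[g] = _TIMING_PARTNER[a]
        else:
            group = "up" if a in DIRECTION_GROUPS["down"] else "down"
            arch_b[g] = DIRECTION_GROUPS[group][int(rng.integers(2))]
    for i in range(n_directional, len(genes)):
        arch_b[genes[i]] = "up_n_dn"
    return arch_a, arch_b, categories
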