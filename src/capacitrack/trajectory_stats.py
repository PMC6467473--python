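"""Sample-level global analyses: correlation structure, PCA trajectories,
and pairwise variable-gene counts.

PCA is computed on log2 expression by singular value decomposition of the
per-gene mean-centered data, with a deterministic sign convention (the
largest-magnitude loading of each component is positive). The joint
projection places time-course samples and embryo reference cells in one
score space after ortholog harmonization; no batch correction is applied —
methodological offsets between datasets are simply reported as part of the
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UnitError
from .expression_io import (
    ExpressionMatrix,
    SampleSheet,
    harmonize_orthologs,
)
from .variable_genes import pairwise_de


@dataclass
class CorrelationResult:
    """Symmetric Pearson correlation matrix over samples; zero-variance
    samples get NaN correlations (unit diagonal kept) and are listed in
    ``degenerate_samples``."""

    matrix: pd.DataFrame
    degenerate_samples: list[str]


def sample_correlation(matrix: ExpressionMatrix) -> CorrelationResult:
    """Pairwise Pearson correlation of samples on log2 expression."""
    if matrix.unit != "log2fpkm":
        raise UnitError("sample_correlation expects log2fpkm values")
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = matrix.values.to_numpy(dtype=float)
    sd = X.std(axis=0)
    degenerate = [s for s, z in zip(matrix.sample_ids, sd == 0) if z]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    for i, z in enumerate(sd == 0):
        if z:
            corr[i, :] = np.nan
            corr[:, i] = np.nan
    np.fill_diagonal(corr, 1.0)
    out = pd.DataFrame(corr, index=matrix.sample_ids, columns=matrix.sample_ids)
    return CorrelationResult(matrix=out, degenerate_samples=degenerate)


@dataclass
class PCAProjection:
    """Scores, loadings and explained-variance fractions of a PCA.

    ``scores`` is samples x components, ``loadings`` genes x components
    (orthonormal columns), ``explained_variance_ratio`` non-increasing and
    summing to at most 1.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def pca_project(
    matrix: ExpressionMatrix,
    gene_subset: Sequence[str] | None = None,
    n_components: int = 3,
) -> PCAProjection:
    """Mean-centered PCA (via SVD) of samples on log2 expression.

    Samples are the observations; each gene is centered across samples.
    The sign of every component is fixed so its largest-magnitude gene
    loading is positive, making scores reproducible across platforms.
    """
    if matrix.unit != "log2fpkm":
        raise UnitError("pca_project expects log2fpkm values")
    if gene_subset is not None:
        if len(gene_subset) == 0:
            raise ValueError("gene_subset is empty")
        matrix = matrix.subset_genes(list(gene_subset))
    max_comp = min(matrix.n_genes, matrix.n_samples - 1)
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must lie in [1, {max_comp}]")
    X = matrix.values.to_numpy(dtype=float).T  # samples x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    for c in range(n_components):
        lead = np.argmax(np.abs(Vt[c]))
        if Vt[c, lead] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    scores = U * s
    total_var = float((Xc**2).sum())
    evr = (s**2) / total_var if total_var > 0 else np.zeros_like(s)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAProjection(
        scores=pd.DataFrame(scores, index=matrix.sample_ids, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=matrix.gene_ids, columns=comp_names),
        explained_variance_ratio=evr,
    )


@dataclass
class JointProjection:
    """A PCA over concatenated datasets plus each sample's dataset of
    origin ("timecourse" or "reference")."""

    pca: PCAProjection
    origin: pd.Series


def joint_projection(
    timecourse: ExpressionMatrix,
    reference: ExpressionMatrix,
    ortholog_table: pd.DataFrame | None = None,
    gene_subset: Sequence[str] | None = None,
    n_components: int = 3,
) -> JointProjection:
    """Project time-course samples and reference cells into one PCA space.

    When an ortholog table is given the two matrices are first restricted
    to 1-to-1 pairs and the reference rows renamed into the time-course
    namespace; otherwise gene ids must already be shared. ``gene_subset``
    (time-course namespace) selects the analysis genes, typically the
    variable genes of the time course.
    """
    if timecourse.unit != reference.unit:
        raise UnitError("both matrices must share a unit")
    if ortholog_table is not None:
        tc, ref = harmonize_orthologs(timecourse, reference, ortholog_table)
        ref = ExpressionMatrix(
            ref.values.set_axis(tc.values.index, axis=0), ref.unit
        )
    else:
        shared = [g for g in timecourse.gene_ids if g in set(reference.gene_ids)]
        tc = timecourse.subset_genes(shared)
        ref = reference.subset_genes(shared)
    if gene_subset is not None:
        keep = [g for g in gene_subset if g in set(tc.gene_ids)]
        if not keep:
            raise ValueError("gene_subset does not intersect the harmonized genes")
        tc, ref = tc.subset_genes(keep), ref.subset_genes(keep)
    combined = ExpressionMatrix(
        pd.concat([tc.values, ref.values], axis=1), tc.unit
    )
    pca = pca_project(combined, n_components=n_components)
    origin = pd.Series(
        ["timecourse"] * tc.n_samples + ["reference"] * ref.n_samples,
        index=combined.sample_ids,
    )
    return JointProjection(pca=pca, origin=origin)


def pairwise_variable_counts(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    alpha: float = 0.01,
    min_fc: float = 2.0,
) -> dict[str, pd.DataFrame]:
    """Symmetric timepoint x timepoint table of differential gene counts,
    one table per cell line (diagonal zero). Timepoints with fewer than 2
    replicates in a line are omitted from that line's table."""
    out: dict[str, pd.DataFrame] = {}
    for line in sheet.cell_lines():
        tps = [t for t in sheet.timepoints()
               if len(sheet.samples_for(cell_line=line, timepoint=t)) >= 2]
        counts = pd.DataFrame(0, index=tps, columns=tps, dtype=int)
        for t1, t2 in combinations(tps, 2):
            res = pairwise_de(
                matrix, sheet,
                sheet.samples_for(cell_line=line, timepoint=t1),
                sheet.samples_for(cell_line=line, timepoint=t2),
                alpha=alpha, min_fc=min_fc,
            )
            n = len(res.significant)
            counts.loc[t1, t2] = n
            counts.loc[t2, t1] = n
        out[line] = counts
    return out
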