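"""Highly-variable-gene detection and time-course differential expression.

Variable genes are found by regressing the squared coefficient of variation
(CV2 = variance / mean^2, computed on linear-scale FPKM) against mean
expression. The trend log CV2 = log(a1/mu + a0) is the standard
mean-variance relationship of normalized expression data: a0 captures the
mean-independent (multiplicative) noise floor, a1/mu the sampling-noise
term that dominates at low expression. Genes are selected by thresholds on
the x-axis (mean log2 FPKM) and the y-axis (excess of observed log CV2
over the fitted trend).

Differential expression between sample groups uses a Welch t-test on
log2(FPKM + 1) with Benjamini-Hochberg adjustment. This is a deliberately
simple, fully specified test whose role is to feed the downstream filter
(padj and fold-change thresholds) and the pairwise-count and union
operations; ``p_values`` hooks let an external engine's per-gene p-values
be plugged in instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .errors import FitError, UnitError
from .expression_io import ExpressionMatrix, FPKM_FLOOR, SampleSheet

_LOG_FLOOR = 1e-300  # keeps log() finite inside the trend model


@dataclass
class CV2Fit:
    """Fitted CV2-vs-mean trend plus per-gene statistics.

    ``table`` is indexed by gene with columns mean_fpkm, mean_log2fpkm,
    cv2, log_cv2, fitted_log_cv2, excess (observed minus fitted log CV2,
    natural log). ``a0`` is the asymptotic CV2 at high expression, ``a1``
    the mean-scaled term. Genes excluded from the fit (below the expression
    floor or with zero variance) still receive fitted values and excess.
    """

    a0: float
    a1: float
    table: pd.DataFrame
    n_fitted: int

    def predict_log_cv2(self, mean_fpkm: np.ndarray) -> np.ndarray:
        mu = np.maximum(np.asarray(mean_fpkm, dtype=float), FPKM_FLOOR)
        return np.log(self.a1 / mu + self.a0 + _LOG_FLOOR)


def fit_cv2_trend(matrix: ExpressionMatrix, min_mean_fpkm: float = 0.1) -> CV2Fit:
    """Fit log CV2 = log(a1/mu + a0) across genes by nonlinear least squares.

    Means and CV2 are computed per gene on the linear FPKM scale across all
    samples; the fit runs in (log mu, log CV2) space over genes with mean
    >= ``min_mean_fpkm`` and positive CV2, with non-negativity bounds on
    (a0, a1) and initialization a0 = median CV2, a1 = median(CV2 * mu).
    """
    if matrix.unit != "fpkm":
        raise UnitError("fit_cv2_trend requires a linear-scale fpkm matrix")
    if matrix.n_samples < 3:
        raise FitError("need at least 3 samples to estimate CV2")
    vals = matrix.values.to_numpy(dtype=float)
    mu = vals.mean(axis=1)
    var = vals.var(axis=1, ddof=1)
    # exactly constant genes get exactly zero variance (np.var can leave
    # ~1e-32 residue from the mean subtraction)
    var[vals.max(axis=1) == vals.min(axis=1)] = 0.0
    mu_floored = np.maximum(mu, FPKM_FLOOR)
    cv2 = var / (mu_floored * mu_floored)
    log_cv2 = np.log(cv2 + _LOG_FLOOR)

    floor_mask = mu >= min_mean_fpkm
    if int(floor_mask.sum()) < 10:
        raise FitError(
            f"only {int(floor_mask.sum())} genes pass the expression floor; need >= 10"
        )
    fit_mask = floor_mask & (cv2 > 0)
    if int(fit_mask.sum()) < 2:
        # every floored gene is exactly constant: the trend is identically 0
        a0, a1 = 0.0, 0.0
    else:
        mu_fit, y_fit = mu_floored[fit_mask], log_cv2[fit_mask]
        a0_init = float(np.median(cv2[fit_mask]))
        a1_init = float(np.median(cv2[fit_mask] * mu_fit))

        def residuals(params: np.ndarray) -> np.ndarray:
            a0, a1 = params
            return np.log(a1 / mu_fit + a0 + _LOG_FLOOR) - y_fit

        sol = optimize.least_squares(
            residuals,
            x0=np.array([max(a0_init, 1e-12), max(a1_init, 1e-12)]),
            bounds=(np.zeros(2), np.full(2, np.inf)),
        )
        a0, a1 = float(sol.x[0]), float(sol.x[1])
    fitted = np.log(a1 / mu_floored + a0 + _LOG_FLOOR)
    table = pd.DataFrame(
        {
            "mean_fpkm": mu,
            "mean_log2fpkm": np.log2(mu_floored),
            "cv2": cv2,
            "log_cv2": log_cv2,
            "fitted_log_cv2": fitted,
            "excess": log_cv2 - fitted,
        },
        index=matrix.values.index,
    )
    return CV2Fit(a0=a0, a1=a1, table=table, n_fitted=int(fit_mask.sum()))


def select_variable_genes(
    fit: CV2Fit,
    min_log2fpkm: float = 0.5,
    min_excess: float = 1.0,
) -> list[str]:
    """Genes with mean log2 FPKM >= ``min_log2fpkm`` and log CV2 at least
    ``min_excess`` natural-log units above the fitted trend, ordered by
    descending excess with ties broken by gene id."""
    t = fit.table
    sel = t[(t["mean_log2fpkm"] >= min_log2fpkm) & (t["excess"] >= min_excess)]
    order = sel.sort_values(["excess"], ascending=False, kind="mergesort")
    # stable sort on -excess, then resolve exact ties lexicographically
    ordered = sorted(order.index, key=lambda g: (-order.at[g, "excess"], str(g)))
    return [str(g) for g in ordered]


# ---------------------------------------------------------------------------
# differential expression stand-in


@dataclass
class DEResult:
    """Per-gene differential-expression statistics for one contrast.

    ``table`` is indexed by gene with columns log2fc (group A over group B,
    linear means with pseudocount 1), p and padj (Benjamini-Hochberg over
    all tested genes). ``significant`` lists genes passing padj < alpha and
    |fold change| > min_fc, sorted by gene id.
    """

    table: pd.DataFrame
    alpha: float
    min_fc: float

    @property
    def significant(self) -> list[str]:
        t = self.table
        hits = t[(t["padj"] < self.alpha) & (t["log2fc"].abs() > np.log2(self.min_fc))]
        return sorted(str(g) for g in hits.index)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def pairwise_de(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.01,
    min_fc: float = 2.0,
    p_values: Mapping[str, float] | None = None,
) -> DEResult:
    """Welch t-test DE between two sample groups with BH adjustment.

    Tests run per gene on log2(FPKM + 1); fold change is computed on
    linear-scale group means with pseudocount 1. Genes with zero variance
    in both groups get p = 1 when the means agree and the smallest positive
    float when they differ (the t statistic is undefined there).
    ``p_values`` overrides the built-in test with externally computed
    per-gene p-values (e.g. from a count-model engine).
    """
    if matrix.unit != "fpkm":
        raise UnitError("pairwise_de requires a linear-scale fpkm matrix")
    group_a, group_b = list(map(str, group_a)), list(map(str, group_b))
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    sheet.check_matches(matrix)
    xa = matrix.values[group_a].to_numpy(dtype=float)
    xb = matrix.values[group_b].to_numpy(dtype=float)
    la, lb = np.log2(xa + 1.0), np.log2(xb + 1.0)

    if p_values is not None:
        p = np.array([float(p_values[g]) for g in matrix.gene_ids])
    else:
        import warnings

        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            # near-identical replicates trip scipy's catastrophic-cancellation
            # warning; the degenerate cases are handled explicitly below
            warnings.simplefilter("ignore", RuntimeWarning)
            p = stats.ttest_ind(la, lb, axis=1, equal_var=False).pvalue
        var_zero = (la.var(axis=1) == 0) & (lb.var(axis=1) == 0)
        equal_means = np.isclose(la.mean(axis=1), lb.mean(axis=1))
        p = np.where(var_zero & equal_means, 1.0, p)
        p = np.where(var_zero & ~equal_means, np.finfo(float).tiny, p)
        p = np.where(np.isnan(p), 1.0, p)

    log2fc = np.log2(xa.mean(axis=1) + 1.0) - np.log2(xb.mean(axis=1) + 1.0)
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "padj": bh_adjust(p)},
        index=matrix.values.index,
    )
    return DEResult(table=table, alpha=alpha, min_fc=min_fc)


def timecourse_de_union(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    alpha: float = 0.01,
    min_fc: float = 2.0,
) -> list[str]:
    """Union over all timepoint pairs, within each cell line, of the
    pairwise DE gene lists — the "differentially expressed between any two
    time points in at least one cell line" gene universe. Timepoints with
    fewer than 2 replicates in a cell line are skipped for that line."""
    union: set[str] = set()
    for line in sheet.cell_lines():
        tps = [t for t in sheet.timepoints()
               if len(sheet.samples_for(cell_line=line, timepoint=t)) >= 2]
        for t1, t2 in combinations(tps, 2):
            res = pairwise_de(
                matrix, sheet,
                sheet.samples_for(cell_line=line, timepoint=t1),
                sheet.samples_for(cell_line=line, timepoint=t2),
                alpha=alpha, min_fc=min_fc,
            )
            union.update(res.significant)
    return sorted(union)
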