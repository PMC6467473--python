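"""Fractional stage identity by simplex-constrained least squares.

Each sample's linear-scale expression vector x is modeled as an additive
mixture of per-stage signature profiles (columns of the genes x stages
matrix S):

    minimize   || S f - x ||_2^2
    subject to f >= 0,  sum(f) = 1

The solution is computed exactly: with a handful of stages, every support
(subset of stages allowed to be nonzero) admits a closed-form
equality-constrained least-squares solution through its KKT system, and
the optimum of the inequality-constrained program is the feasible support
solution of least objective. This exhaustive active-set enumeration is
KKT-exact — no penalty approximation of the sum-to-one constraint is
involved — and degrades gracefully on rank-deficient signatures (the
solve proceeds; non-uniqueness is flagged).

Signatures are the arithmetic mean expression of the reference cells of
each stage, on linear FPKM, restricted to the analysis gene set (typically
the harmonized variable genes).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .expression_io import ExpressionMatrix, SampleSheet, UnitError

#: Supports are enumerated exhaustively up to this stage count; beyond it a
#: sequential quadratic solver refines the best enumerated vertex/edge.
_MAX_ENUM_STAGES = 12


@dataclass(frozen=True)
class SignatureSet:
    """Genes x stages matrix of per-stage mean expression (linear FPKM)."""

    matrix: pd.DataFrame

    def __post_init__(self):
        if self.matrix.columns.duplicated().any():
            raise ValueError("duplicate stage labels")
        if self.matrix.index.duplicated().any():
            raise ValueError("duplicate gene ids in signature set")
        if (self.matrix.to_numpy() == 0).all(axis=1).any():
            raise ValueError("signature set contains an all-zero gene row")

    @property
    def stages(self) -> list[str]:
        return [str(s) for s in self.matrix.columns]

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.matrix.index]


@dataclass
class FractionProfile:
    """Stage fractions of one sample on the probability simplex."""

    sample_id: str
    fractions: pd.Series
    residual_norm: float
    objective: float
    unique: bool = True

    def __post_init__(self):
        f = self.fractions.to_numpy(dtype=float)
        assert f.min() >= -1e-12 and abs(f.sum() - 1.0) <= 1e-6


def build_signatures(
    reference: ExpressionMatrix,
    sheet: SampleSheet,
    stages: Sequence[str],
    genes: Sequence[str] | None = None,
) -> SignatureSet:
    """Per-stage mean expression over the reference cells of each stage.

    Stage labels live in the sample sheet's timepoint column. All-zero
    gene rows (never detected in any requested stage) are dropped with a
    warning, since they carry no deconvolution information.
    """
    if reference.unit != "fpkm":
        raise UnitError("signatures are built on linear-scale fpkm values")
    sheet.check_matches(reference)
    cols = {}
    for stage in stages:
        cells = sheet.samples_for(timepoint=str(stage))
        if not cells:
            raise ValueError(f"stage {stage!r} has no reference cells")
        cols[str(stage)] = reference.values[cells].mean(axis=1)
    S = pd.DataFrame(cols)
    if genes is not None:
        missing = set(map(str, genes)) - set(S.index.astype(str))
        if missing:
            raise KeyError(f"{len(missing)} requested genes absent from reference")
        S = S.loc[list(genes)]
    zero = (S.to_numpy() == 0).all(axis=1)
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} all-zero signature rows",
                      stacklevel=2)
        S = S.loc[~zero]
    return SignatureSet(S)


def _solve_support(S: np.ndarray, x: np.ndarray,
                   support: tuple[int, ...]) -> np.ndarray:
    """Equality-constrained least squares on one support.

    The sum-to-one constraint is eliminated exactly by the null-space
    substitution f = e1 + Z y (columns of Z are e_{i+1} - e_1), leaving an
    unconstrained rectangular least-squares problem in y on the original
    data scale — numerically far better behaved than the raw KKT system of
    the normal equations. Returns the support-sized fraction vector, which
    sums to 1 by construction; rank deficiency falls back to the min-norm
    solution.
    """
    A = S[:, list(support)]
    q = A.shape[1]
    if q == 1:
        return np.ones(1)
    f0 = np.zeros(q)
    f0[0] = 1.0
    Z = np.vstack([-np.ones((1, q - 1)), np.eye(q - 1)])
    y, *_ = np.linalg.lstsq(A @ Z, x - A @ f0, rcond=None)
    return f0 + Z @ y


def solve_fractions(signatures: SignatureSet, x, sample_id: str = "sample") -> FractionProfile:
    """Exact simplex-constrained least-squares decomposition of one sample.

    ``x`` is an expression vector aligned to the signature gene rows (a
    pandas Series is reindexed onto them). Among all stage supports the
    feasible KKT solution with the least objective is returned; a
    rank-deficient winning support (non-unique optimum) sets
    ``unique=False``.
    """
    S = signatures.matrix.to_numpy(dtype=float)
    n_genes, n_stages = S.shape
    if n_genes < n_stages:
        raise ValueError("need at least as many genes as stages")
    if isinstance(x, pd.Series):
        x = x.reindex(signatures.matrix.index).to_numpy(dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    if x.shape != (n_genes,):
        raise ValueError(f"sample vector has length {x.size}, expected {n_genes}")

    def objective(f: np.ndarray) -> float:
        r = S @ f - x
        return float(r @ r)

    best_f, best_obj, best_support = None, np.inf, None
    if n_stages <= _MAX_ENUM_STAGES:
        supports = [
            tuple(i for i in range(n_stages) if mask >> i & 1)
            for mask in range(1, 2**n_stages)
        ]
    else:  # pragma: no cover - pathological stage counts
        supports = [tuple(range(n_stages))]
    feas_tol = 1e-9
    for support in supports:
        f_sub = _solve_support(S, x, support)
        if f_sub.min() < -feas_tol:
            continue
        f = np.zeros(n_stages)
        f[list(support)] = np.clip(f_sub, 0.0, None)
        f /= f.sum()
        obj = objective(f)
        if best_f is None or obj < best_obj - 1e-12:
            best_f, best_obj, best_support = f, obj, support
    if best_f is None or n_stages > _MAX_ENUM_STAGES:
        StS, Stx = S.T @ S, S.T @ x
        res = optimize.minimize(
            objective,
            x0=best_f if best_f is not None else np.full(n_stages, 1.0 / n_stages),
            jac=lambda f: 2.0 * (StS @ f - Stx),
            bounds=[(0.0, 1.0)] * n_stages,
            constraints=[{"type": "eq", "fun": lambda f: f.sum() - 1.0,
                          "jac": lambda f: np.ones(n_stages)}],
            method="SLSQP",
        )
        cand = np.clip(res.x, 0.0, None)
        cand /= cand.sum()
        if best_f is None or objective(cand) < best_obj:
            best_f = cand
            best_obj = objective(cand)
            best_support = tuple(np.flatnonzero(best_f > 1e-12))
    rank = np.linalg.matrix_rank(S[:, list(best_support)])
    return FractionProfile(
        sample_id=str(sample_id),
        fractions=pd.Series(best_f, index=signatures.matrix.columns),
        residual_norm=float(np.sqrt(max(best_obj, 0.0))),
        objective=max(best_obj, 0.0),
        unique=rank == len(best_support),
    )


def identity_timecourse(
    timecourse: ExpressionMatrix,
    sheet: SampleSheet,
    signatures: SignatureSet,
) -> tuple[list[FractionProfile], pd.DataFrame]:
    """Stage fractions for every time-course sample, plus a tidy
    timepoint x stage summary (replicate mean and s.d. per fraction).

    The time course is restricted to the signature gene rows; samples are
    solved independently and summarized in sample-sheet timepoint order.
    """
    if timecourse.unit != "fpkm":
        raise UnitError("identity_timecourse expects linear-scale fpkm values")
    sheet.check_matches(timecourse)
    genes = [g for g in signatures.gene_ids if g in set(timecourse.gene_ids)]
    if len(genes) < len(signatures.stages):
        raise ValueError("too few shared genes between time course and signatures")
    sig = SignatureSet(signatures.matrix.loc[genes])
    sub = timecourse.subset_genes(genes)
    profiles = [
        solve_fractions(sig, sub.values[sid], sample_id=sid)
        for sid in sub.sample_ids
    ]
    by_sample = pd.DataFrame(
        {p.sample_id: p.fractions for p in profiles}
    ).T
    by_sample["timepoint"] = sheet.table.loc[by_sample.index, "timepoint"].astype(str)
    rows = []
    for tp in sheet.timepoints():
        grp = by_sample[by_sample["timepoint"] == tp].drop(columns="timepoint")
        for stage in sig.stages:
            rows.append(
                (tp, stage, float(grp[stage].mean()),
                 float(grp[stage].std(ddof=1)) if len(grp) > 1 else 0.0,
                 len(grp))
            )
    summary = pd.DataFrame(
        rows, columns=["timepoint", "stage", "mean_fraction", "sd_fraction", "n"]
    )
    return profiles, summary
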