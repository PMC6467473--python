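"""Soft clustering of temporal expression profiles.

Replicates are averaged per timepoint, each gene's profile is standardized
(mean 0, sd 1 across timepoints), and genes are partitioned by fuzzy
c-means: the soft analogue of k-means in which gene g carries a graded
membership u[g,c] in every cluster c, controlled by the fuzzifier m > 1
(m -> 1 recovers hard k-means). The update equations are the classical
alternating minimization of

    J = sum_{g,c} u[g,c]^m * ||x_g - v_c||^2

    u[g,c] = ( sum_j (d_gc / d_gj)^(2/(m-1)) )^(-1)
    v_c    = sum_g u[g,c]^m x_g / sum_g u[g,c]^m

J is non-increasing across iterations and membership rows sum to 1 at every
iteration. The cluster number is chosen by an elbow criterion on the
within-cluster sum of squares J(k): the interior k maximizing the second
difference J(k-1) - 2 J(k) + J(k+1).

With k = 5 the centroids receive the semantic labels early_down,
late_down, up_n_dn, early_up, late_up from their trajectory geometry
(net change, peak position, half-change time). Per-cluster gene-set
enrichment uses the one-sided hypergeometric upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, LabelingError, UnitError
from .expression_io import ExpressionMatrix, SampleSheet
from .synthetic_data import ARCHETYPES
from .variable_genes import bh_adjust


@dataclass
class StandardizedProfiles:
    """Genes x timepoints standardized temporal profiles plus the genes
    dropped for zero temporal variance."""

    profiles: pd.DataFrame
    dropped: list[str]

    @property
    def timepoints(self) -> list[str]:
        return [str(t) for t in self.profiles.columns]


@dataclass
class MembershipMatrix:
    """Fuzzy c-means result: memberships, centroids, hard assignments.

    Cluster ids are 1-based integers. ``memberships`` is genes x clusters,
    rows summing to 1; ``centroids`` is clusters x timepoints on the
    standardized scale; ``hard_assignment`` maps gene -> argmax cluster
    (ties broken by the lowest cluster id); ``labels`` maps cluster id ->
    semantic archetype name once :func:`label_clusters` has run.
    """

    memberships: pd.DataFrame
    centroids: pd.DataFrame
    hard_assignment: pd.Series
    objective: float
    n_iter: int
    converged: bool
    objective_path: list[float] = field(default_factory=list)
    labels: dict[int, str] | None = None

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.memberships.index]

    def assignment_by_label(self) -> pd.Series:
        if self.labels is None:
            raise ValueError("clusters have not been labeled")
        return self.hard_assignment.map(self.labels)


def standardize_profiles(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    cell_line: str | None = None,
) -> StandardizedProfiles:
    """Collapse replicates to per-timepoint means, then z-score each gene
    across timepoints (ddof=1). Genes with zero temporal variance are
    dropped and reported. Operates on log2-scale values."""
    if matrix.unit != "log2fpkm":
        raise UnitError("standardize_profiles expects log2fpkm values")
    tps = sheet.timepoints()
    if len(tps) < 2:
        raise ValueError("need at least 2 timepoints")
    cols = {}
    for tp in tps:
        samples = sheet.samples_for(cell_line=cell_line, timepoint=tp)
        if not samples:
            raise ValueError(f"no samples at timepoint {tp!r}")
        cols[tp] = matrix.values[samples].mean(axis=1)
    means = pd.DataFrame(cols)
    sd = means.std(axis=1, ddof=1)
    # exact flatness test: pandas' variance can return ~1e-15 on constant rows
    keep = (means.max(axis=1) > means.min(axis=1)) & (sd > 0)
    dropped = [str(g) for g in means.index[~keep]]
    z = means.loc[keep].sub(means.loc[keep].mean(axis=1), axis=0).div(sd[keep], axis=0)
    return StandardizedProfiles(profiles=z, dropped=dropped)


# ---------------------------------------------------------------------------
# fuzzy c-means


def _memberships_from_distances(d2: np.ndarray, m: float) -> np.ndarray:
    """u[g,c] from squared distances; exact-zero distances get membership 1
    on the first coinciding centroid (the m -> limit convention)."""
    expo = 1.0 / (m - 1.0)
    zero_rows = (d2 <= 0.0).any(axis=1)
    # normalize by the row minimum so the power never overflows (ratios >= 1,
    # inverse powers <= 1); underflow of far clusters to 0 is harmless
    dmin = np.where(zero_rows, 1.0, d2.min(axis=1))[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.power(d2 / dmin, -expo)
        u = inv / inv.sum(axis=1, keepdims=True)
    if zero_rows.any():
        for g in np.flatnonzero(zero_rows):
            u[g] = 0.0
            u[g, int(np.argmax(d2[g] <= 0.0))] = 1.0
    return u


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    k: int,
    m: float = 1.25,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
    init_centroids: np.ndarray | None = None,
) -> MembershipMatrix:
    """Single fuzzy c-means run from a seeded initialization.

    Centroids are initialized on k distinct genes sampled without
    replacement (or on ``init_centroids`` when given) and the standard
    membership/centroid updates alternate until the maximum centroid shift
    falls below ``tol`` or ``max_iter`` is reached. The objective recorded
    after every membership update is non-increasing.
    """
    if m <= 1.0:
        raise ValueError("fuzzifier m must exceed 1")
    X = profiles.to_numpy(dtype=float)
    n, t = X.shape
    if not 2 <= k <= n:
        raise ValueError(f"k={k} must lie in [2, n_genes={n}]")
    rng = np.random.default_rng(seed)
    if init_centroids is None:
        idx = rng.choice(n, size=k, replace=False)
        V = X[idx].copy()
    else:
        V = np.asarray(init_centroids, dtype=float).copy()
        if V.shape != (k, t):
            raise ValueError(f"init_centroids must be {(k, t)}")

    path: list[float] = []
    converged = False
    U = np.full((n, k), 1.0 / k)
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - V[None, :, :]) ** 2).sum(axis=2)
        U = _memberships_from_distances(d2, m)
        path.append(float((np.power(U, m) * d2).sum()))
        W = np.power(U, m)
        V_new = (W.T @ X) / W.sum(axis=0)[:, None]
        shift = float(np.abs(V_new - V).max())
        V = V_new
        if shift < tol:
            converged = True
            break
    cluster_ids = list(range(1, k + 1))
    memberships = pd.DataFrame(U, index=profiles.index, columns=cluster_ids)
    centroids = pd.DataFrame(V, index=cluster_ids, columns=profiles.columns)
    hard = pd.Series(np.argmax(U, axis=1) + 1, index=profiles.index)
    return MembershipMatrix(
        memberships=memberships,
        centroids=centroids,
        hard_assignment=hard,
        objective=path[-1],
        n_iter=len(path),
        converged=converged,
        objective_path=path,
    )


def _spawn_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def cluster_profiles(
    profiles: pd.DataFrame,
    k: int,
    m: float = 1.25,
    n_starts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
) -> MembershipMatrix:
    """Multi-start fuzzy c-means; returns the run with the best (lowest)
    objective. Fuzzy c-means is sensitive to initialization, so several
    seeded restarts are the default."""
    best: MembershipMatrix | None = None
    for s in _spawn_seeds(seed, n_starts):
        mm = fuzzy_cmeans(profiles, k, m=m, tol=tol, max_iter=max_iter, seed=s)
        if best is None or mm.objective < best.objective:
            best = mm
    assert best is not None
    return best


def hard_wss(profiles: pd.DataFrame, mm: MembershipMatrix) -> float:
    """Within-cluster sum of squared distances of each gene to its
    hard-assigned centroid."""
    X = profiles.to_numpy(dtype=float)
    V = mm.centroids.to_numpy(dtype=float)
    assign = mm.hard_assignment.to_numpy() - 1
    return float(((X - V[assign]) ** 2).sum())


@dataclass
class ElbowResult:
    """Cluster-number selection audit trail."""

    k: int
    table: pd.DataFrame  # index k, columns wss, second_diff
    low_confidence: bool


def elbow_select_k(
    profiles: pd.DataFrame,
    k_range: Sequence[int],
    m: float = 1.25,
    n_starts: int = 10,
    seed: int = 0,
    flat_threshold: float = 0.05,
) -> ElbowResult:
    """Choose the cluster number by the elbow of the J(k) curve.

    For every k in ``k_range`` (at least 3 consecutive values) the hard
    within-cluster sum of squares of the best multi-start fuzzy c-means
    run is computed. The elbow is located on the log curve: the selected k
    maximizes the second difference
    log J(k-1) - 2 log J(k) + log J(k+1) over interior k (ties to the
    smallest k). Working on the log scale makes the statistic a curvature
    of relative improvement — a plain linear-scale second difference is
    dominated by the geometric decay of J at small k and misses the
    flattening point. When the strongest elbow curvature is below
    ``flat_threshold`` (log units) the selection is flagged low-confidence
    (near-featureless curve, e.g. a single archetype).
    """
    ks = sorted(int(k) for k in k_range)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values (no interior point)")
    seeds = _spawn_seeds(seed, n_starts)
    wss: dict[int, float] = {}
    for k in ks:
        best = np.inf
        for s in seeds:
            mm = fuzzy_cmeans(profiles, k, m=m, seed=s)
            best = min(best, hard_wss(profiles, mm))
        wss[k] = best
    floor = max(wss.values()) * 1e-12 + 1e-300
    logw = {k: float(np.log(v + floor)) for k, v in wss.items()}
    second = {
        ks[i]: logw[ks[i - 1]] - 2.0 * logw[ks[i]] + logw[ks[i + 1]]
        for i in range(1, len(ks) - 1)
    }
    k_sel = min(second, key=lambda k: (-second[k], k))
    low_conf = max(second.values()) < flat_threshold
    table = pd.DataFrame(
        {"wss": [wss[k] for k in ks],
         "second_diff": [second.get(k, np.nan) for k in ks]},
        index=pd.Index(ks, name="k"),
    )
    return ElbowResult(k=k_sel, table=table, low_confidence=low_conf)


# ---------------------------------------------------------------------------
# semantic labeling


def _half_change_time(c: np.ndarray, delta: float) -> float:
    """Interpolated timepoint index at which a centroid first achieves half
    of its net start-to-end change (in the direction of that change)."""
    target = 0.5 * delta
    prog = c - c[0]
    sign = 1.0 if delta >= 0 else -1.0
    for i in range(1, len(c)):
        if sign * prog[i] >= sign * target:
            p0, p1 = sign * prog[i - 1], sign * prog[i]
            if p1 == p0:
                return float(i)
            return (i - 1) + (sign * target - p0) / (p1 - p0)
    return float(len(c))


def label_clusters(mm: MembershipMatrix) -> MembershipMatrix:
    """Assign the five semantic archetype labels to k=5 centroids.

    The up-and-down cluster is the centroid with an interior peak whose net
    change |last - first| is below half its range (the largest such peak
    wins); the remaining four split by the sign of the net change into
    down- and up-regulated pairs, within which the centroid reaching half
    of its total change earlier is "early". Ambiguous geometry (no
    up-and-down candidate, tied candidates, or a sign split other than 2/2)
    raises :class:`LabelingError` with diagnostics.
    """
    if mm.k != 5:
        raise ValueError(f"semantic labeling requires k=5, got k={mm.k}")
    C = mm.centroids.to_numpy(dtype=float)
    ids = list(mm.centroids.index)
    T = C.shape[1]
    delta = C[:, -1] - C[:, 0]
    crange = C.max(axis=1) - C.min(axis=1)
    # interior-extremum prominence: how far the trajectory over- or
    # undershoots both endpoints somewhere strictly inside the course
    prominence = np.full(5, -np.inf)
    for i in range(5):
        imax, imin = int(C[i].argmax()), int(C[i].argmin())
        if 0 < imax < T - 1:
            prominence[i] = C[i, imax] - max(C[i, 0], C[i, -1])
        if 0 < imin < T - 1:
            prominence[i] = max(prominence[i], min(C[i, 0], C[i, -1]) - C[i, imin])
    candidate = (prominence > 0) & (np.abs(delta) < 0.5 * crange)
    if not candidate.any():
        raise LabelingError(
            "no up-and-down candidate: "
            f"net changes {np.round(delta, 3).tolist()}, "
            f"prominences {np.round(prominence, 3).tolist()}"
        )
    peaks = np.where(candidate, prominence, -np.inf)
    top = float(peaks.max())
    if int((peaks == top).sum()) > 1:
        raise LabelingError(
            f"tied up-and-down candidates among clusters "
            f"{[ids[i] for i in np.flatnonzero(peaks == top)]}"
        )
    und = int(peaks.argmax())
    rest = [i for i in range(5) if i != und]
    down = [i for i in rest if delta[i] < 0]
    up = [i for i in rest if delta[i] > 0]
    if len(down) != 2 or len(up) != 2:
        raise LabelingError(
            f"expected 2 down- and 2 up-regulated centroids, got "
            f"{len(down)} down / {len(up)} up (net changes {np.round(delta, 3).tolist()})"
        )
    labels: dict[int, str] = {ids[und]: "up_n_dn"}
    for pair, (early, late) in ((down, ("early_down", "late_down")),
                                (up, ("early_up", "late_up"))):
        t0, t1 = (_half_change_time(C[i], float(delta[i])) for i in pair)
        first, second = (pair[0], pair[1]) if (t0, pair[0]) <= (t1, pair[1]) else (pair[1], pair[0])
        labels[ids[first]] = early
        labels[ids[second]] = late
    assert sorted(labels.values()) == sorted(ARCHETYPES)
    return replace(mm, labels=labels)


# ---------------------------------------------------------------------------
# gene-set enrichment


def cluster_set_enrichment(
    mm: MembershipMatrix,
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of each gene set in each hard
    cluster, restricted to ``universe``; Benjamini-Hochberg adjustment runs
    across all (cluster, set) pairs. p = P(overlap >= observed) under
    sampling |cluster| genes from the universe containing |set| successes."""
    uni = set(map(str, universe))
    if not uni:
        raise ValueError("empty gene universe")
    missing = set(mm.gene_ids) - uni
    if missing:
        raise ValueError(f"{len(missing)} clustered genes absent from universe")
    rows = []
    N = len(uni)
    for cluster in mm.centroids.index:
        members = {g for g, c in mm.hard_assignment.items() if c == cluster} & uni
        n = len(members)
        for set_name, set_genes in gene_sets.items():
            K = len(set(map(str, set_genes)) & uni)
            overlap = len(members & set(map(str, set_genes)))
            p = float(stats.hypergeom.sf(overlap - 1, N, K, n))
            rows.append((cluster, set_name, overlap, n, K, N, p))
    out = pd.DataFrame(
        rows, columns=["cluster", "gene_set", "overlap", "cluster_size",
                       "set_size", "universe_size", "p"],
    )
    out["padj"] = bh_adjust(out["p"]) if len(out) else []
    return out


# ---------------------------------------------------------------------------
# membership I/O (CLI round trips)


def write_membership(mm: MembershipMatrix, members_path: str | Path,
                     centroids_path: str | Path) -> None:
    mtab = mm.memberships.copy()
    mtab.columns = [f"cluster_{c}" for c in mtab.columns]
    mtab["hard"] = mm.hard_assignment
    if mm.labels is not None:
        mtab["label"] = mm.hard_assignment.map(mm.labels)
    mtab.to_csv(members_path, sep="\t", index_label="gene_id")
    ctab = mm.centroids.copy()
    if mm.labels is not None:
        ctab.insert(0, "label", [mm.labels[c] for c in ctab.index])
    ctab.to_csv(centroids_path, sep="\t", index_label="cluster")


def read_membership(members_path: str | Path,
                    centroids_path: str | Path) -> MembershipMatrix:
    mtab = pd.read_csv(members_path, sep="\t", index_col=0)
    mtab.index = mtab.index.astype(str)
    ctab = pd.read_csv(centroids_path, sep="\t", index_col=0)
    labels = None
    if "label" in ctab.columns:
        labels = {int(c): str(l) for c, l in ctab["label"].items()}
        ctab = ctab.drop(columns=["label"])
    mem_cols = [c for c in mtab.columns if c.startswith("cluster_")]
    memberships = mtab[mem_cols]
    memberships.columns = [int(c.split("_")[1]) for c in mem_cols]
    return MembershipMatrix(
        memberships=memberships,
        centroids=ctab.set_axis([int(c) for c in ctab.index], axis=0),
        hard_assignment=mtab["hard"].astype(int),
        objective=float("nan"),
        n_iter=0,
        converged=True,
        labels=labels,
    )
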