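"""Cluster correspondence between datasets, cell lines or species.

Two clusterings of (a shared set of) genes are compared as the fraction of
genes assigned to the *same* cluster and to the same *or a similar*
cluster, where "similar" means a different cluster of the same direction
group (e.g. both downregulated). Cluster ids are first reconciled by an
assignment-problem optimum on centroid correlation, so the fractions are
invariant under any renumbering of either clustering.

Two grouping schemes are shipped as presets, because the within-hPSC and
the embryo-vs-hPSC comparisons group clusters differently:

* ``hpsc_vs_hpsc``    — down = {1, 2} / {1, 2}, up = {4, 5} / {4, 5};
* ``embryo_vs_hpsc``  — down = {1, 2} / {1, 2}, up = {3, 4, 5} / {4, 5}
  (the embryo's cluster 3 rises and stays up, so it joins the upregulated
  group on the embryo side only).

Genes whose two clusters fall in no common group count as "neither"; in
particular an in vitro cluster-3 gene is "neither" unless the scheme
places cluster 3 in a group on that side.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .expression_io import filter_one_to_one
from .soft_clustering import MembershipMatrix


@dataclass(frozen=True)
class ClusterGroupScheme:
    """Named grouping of cluster ids into direction groups, one cluster set
    per dataset side (A, B)."""

    name: str
    groups: dict[str, tuple[frozenset[int], frozenset[int]]]

    def __post_init__(self):
        for side in (0, 1):
            seen: set[int] = set()
            for label, pair in self.groups.items():
                dup = seen & set(pair[side])
                if dup:
                    raise ValueError(
                        f"cluster(s) {sorted(dup)} appear in more than one group "
                        f"on side {'AB'[side]} of scheme {self.name!r}"
                    )
                seen |= set(pair[side])

    def group_of(self, cluster: int, side: int) -> str | None:
        for label, pair in self.groups.items():
            if cluster in pair[side]:
                return label
        return None


SCHEMES: dict[str, ClusterGroupScheme] = {
    "hpsc_vs_hpsc": ClusterGroupScheme(
        "hpsc_vs_hpsc",
        {"down": (frozenset({1, 2}), frozenset({1, 2})),
         "up": (frozenset({4, 5}), frozenset({4, 5}))},
    ),
    "embryo_vs_hpsc": ClusterGroupScheme(
        "embryo_vs_hpsc",
        {"down": (frozenset({1, 2}), frozenset({1, 2})),
         "up": (frozenset({3, 4, 5}), frozenset({4, 5}))},
    ),
}


@dataclass
class ClusterMatch:
    """Optimal bijection between two clusterings' ids.

    ``b_to_a`` renumbers dataset-B clusters into dataset-A ids. The match
    maximizes the total Pearson correlation between paired centroids;
    ``low_confidence`` flags a mean matched correlation below 0.5.
    """

    b_to_a: dict[int, int]
    correlation: pd.DataFrame
    mean_matched_correlation: float
    low_confidence: bool


def _interp_centroids(c: pd.DataFrame, n_target: int) -> np.ndarray:
    """Linear interpolation of centroids onto a normalized time axis of
    ``n_target`` points."""
    src = np.linspace(0.0, 1.0, c.shape[1])
    dst = np.linspace(0.0, 1.0, n_target)
    return np.vstack([np.interp(dst, src, row) for row in c.to_numpy(dtype=float)])


def match_cluster_ids(mm_a: MembershipMatrix, mm_b: MembershipMatrix) -> ClusterMatch:
    """Match cluster ids across datasets by centroid-shape correlation.

    Centroids of B are interpolated onto A's normalized time axis when the
    two courses have different lengths. When both clusterings carry
    semantic labels, label identity defines the mapping and a warning is
    raised if it disagrees with the correlation optimum.
    """
    if mm_a.k != mm_b.k:
        raise ValueError(f"cluster counts differ: {mm_a.k} vs {mm_b.k}")
    k = mm_a.k
    A = mm_a.centroids.to_numpy(dtype=float)
    B = _interp_centroids(mm_b.centroids, A.shape[1])
    corr = np.corrcoef(A, B)[:k, k:]
    row, col = linear_sum_assignment(-corr)
    ids_a, ids_b = list(mm_a.centroids.index), list(mm_b.centroids.index)
    optimum = {ids_b[j]: ids_a[i] for i, j in zip(row, col)}
    mean_corr = float(corr[row, col].mean())

    mapping = optimum
    if mm_a.labels is not None and mm_b.labels is not None:
        by_label = {}
        a_of_label = {lab: cid for cid, lab in mm_a.labels.items()}
        for cid_b, lab in mm_b.labels.items():
            by_label[cid_b] = a_of_label[lab]
        if by_label != optimum:
            warnings.warn(
                "semantic-label mapping disagrees with the centroid-correlation "
                f"optimum; using labels ({by_label} vs {optimum})",
                stacklevel=2,
            )
        mapping = by_label
    return ClusterMatch(
        b_to_a=mapping,
        correlation=pd.DataFrame(corr, index=ids_a, columns=ids_b),
        mean_matched_correlation=mean_corr,
        low_confidence=mean_corr < 0.5,
    )


@dataclass
class CorrespondenceResult:
    """Same / similar / neither verdicts for a shared gene set.

    Fractions are proportions of ``n_compared``; both are NaN when the
    shared set is empty. ``n_dropped`` counts requested genes missing from
    either assignment (excluded from the denominator, not an error).
    """

    n_compared: int
    n_same: int
    n_similar: int
    n_neither: int
    frac_same: float
    frac_same_or_similar: float
    verdicts: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self):
        assert self.n_same + self.n_similar + self.n_neither == self.n_compared


def correspondence_fractions(
    assign_a: Mapping[str, int],
    assign_b: Mapping[str, int],
    scheme: ClusterGroupScheme,
    shared_genes: Sequence[str],
) -> CorrespondenceResult:
    """Per-gene same/similar/neither verdicts over ``shared_genes``.

    ``assign_b`` must already be expressed in dataset-A cluster ids (apply
    :func:`match_cluster_ids` first when the clusterings were produced
    independently); both assignments are then compared per gene: equal ids
    are "same"; unequal ids within one scheme group are "similar".
    """
    rows, dropped = [], 0
    for g in map(str, shared_genes):
        if g not in assign_a or g not in assign_b:
            dropped += 1
            continue
        ca, cb = int(assign_a[g]), int(assign_b[g])
        if ca == cb:
            verdict = "same"
        else:
            ga, gb = scheme.group_of(ca, 0), scheme.group_of(cb, 1)
            verdict = "similar" if ga is not None and ga == gb else "neither"
        rows.append((g, ca, cb, verdict))
    verdicts = pd.DataFrame(rows, columns=["gene", "cluster_a", "cluster_b", "verdict"])
    n = len(rows)
    n_same = int((verdicts["verdict"] == "same").sum()) if n else 0
    n_sim = int((verdicts["verdict"] == "similar").sum()) if n else 0
    return CorrespondenceResult(
        n_compared=n,
        n_same=n_same,
        n_similar=n_sim,
        n_neither=n - n_same - n_sim,
        frac_same=n_same / n if n else float("nan"),
        frac_same_or_similar=(n_same + n_sim) / n if n else float("nan"),
        verdicts=verdicts,
        n_dropped=dropped,
    )


def _canonical_renumbering(mm_a: MembershipMatrix) -> dict[int, int]:
    """Map dataset-A cluster ids onto the canonical archetype numbering
    (1 = early_down ... 5 = late_up) via semantic labels, so the shipped
    schemes' cluster-id groups mean what they say. Identity when A carries
    no labels (ids are then taken at face value)."""
    from .synthetic_data import ARCHETYPES

    if mm_a.labels is None:
        return {int(c): int(c) for c in mm_a.centroids.index}
    canon = {lab: i + 1 for i, lab in enumerate(ARCHETYPES)}
    return {int(c): canon[lab] for c, lab in mm_a.labels.items()}


def dataset_correspondence(
    mm_a: MembershipMatrix,
    mm_b: MembershipMatrix,
    scheme: ClusterGroupScheme,
    shared_genes: Sequence[str] | None = None,
) -> CorrespondenceResult:
    """Correspondence between two clusterings over the same gene namespace
    (e.g. the two cell lines). Cluster ids are reconciled by
    :func:`match_cluster_ids` and, when A is semantically labeled, recast
    into the canonical archetype numbering the schemes refer to; the
    default universe is the genes clustered in both datasets."""
    match = match_cluster_ids(mm_a, mm_b)
    canon = _canonical_renumbering(mm_a)
    assign_a = {str(g): canon[int(c)] for g, c in mm_a.hard_assignment.items()}
    assign_b = {str(g): canon[int(match.b_to_a[int(c)])]
                for g, c in mm_b.hard_assignment.items()}
    if shared_genes is None:
        shared_genes = sorted(set(assign_a) & set(assign_b))
    return correspondence_fractions(assign_a, assign_b, scheme, shared_genes)


def cross_species_correspondence(
    mm_species_a: MembershipMatrix,
    mm_species_b: MembershipMatrix,
    ortholog_table: pd.DataFrame,
    scheme: ClusterGroupScheme,
    shared_genes: Sequence[str] | None = None,
) -> CorrespondenceResult:
    """Correspondence across species through a 1-to-1 ortholog map.

    Species-B gene ids are translated into species-A ids over the strictly
    1-to-1 rows of the table; the comparison universe defaults to genes
    clustered in both species after that filtering. ``shared_genes`` (in
    species-A ids) restricts the universe further.
    """
    strict = filter_one_to_one(ortholog_table)
    b_to_a_gene = dict(zip(strict["gene_b"].astype(str), strict["gene_a"].astype(str)))
    match = match_cluster_ids(mm_species_a, mm_species_b)
    canon = _canonical_renumbering(mm_species_a)
    assign_a = {str(g): canon[int(c)] for g, c in mm_species_a.hard_assignment.items()}
    assign_b = {
        b_to_a_gene[str(g)]: canon[int(match.b_to_a[int(c)])]
        for g, c in mm_species_b.hard_assignment.items()
        if str(g) in b_to_a_gene
    }
    if shared_genes is None:
        shared_genes = sorted(set(assign_a) & set(assign_b))
    return correspondence_fractions(assign_a, assign_b, scheme, shared_genes)
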