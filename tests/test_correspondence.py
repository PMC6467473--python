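import numpy as np
import pandas as pd
import pytest

from capacitrack import synthetic_data as sd
from capacitrack import to_log2
from capacitrack.correspondence import (
    SCHEMES,
    ClusterGroupScheme,
    correspondence_fractions,
    cross_species_correspondence,
    dataset_correspondence,
    match_cluster_ids,
)
from capacitrack.soft_clustering import (
    MembershipMatrix,
    cluster_profiles,
    label_clusters,
    standardize_profiles,
)

HPSC = SCHEMES["hpsc_vs_hpsc"]


def _mm_from_centroids(C, assignment=None):
    ids = list(C.index)
    genes = list(assignment) if assignment else [f"g{i}" for i in ids]
    hard = pd.Series(assignment) if assignment else pd.Series(ids, index=genes)
    mem = pd.DataFrame(0.0, index=genes, columns=ids)
    for g, c in hard.items():
        mem.loc[g, c] = 1.0
    return MembershipMatrix(
        memberships=mem, centroids=C, hard_assignment=hard,
        objective=0.0, n_iter=1, converged=True,
    )


def _archetype_centroids(perm=None):
    profiles = sd.archetype_level_profiles(6)
    rows = []
    order = list(sd.ARCHETYPES)
    if perm:
        order = [order[i] for i in perm]
    for arch in order:
        p = profiles[arch]
        rows.append((p - p.mean()) / p.std(ddof=1))
    return pd.DataFrame(rows, index=range(1, 6), columns=[f"t{i}" for i in range(6)])


class TestMatchClusterIds:
    def test_identity_for_same_input(self):
        mm = _mm_from_centroids(_archetype_centroids())
        match = match_cluster_ids(mm, mm)
        assert match.b_to_a == {c: c for c in range(1, 6)}
        assert not match.low_confidence

    def test_recovers_known_permutation(self):
        mm_a = _mm_from_centroids(_archetype_centroids())
        perm = [3, 0, 4, 1, 2]  # B cluster i+1 holds archetype perm[i]
        mm_b = _mm_from_centroids(_archetype_centroids(perm=perm))
        match = match_cluster_ids(mm_a, mm_b)
        assert match.b_to_a == {i + 1: perm[i] + 1 for i in range(5)}

    def test_interpolates_different_time_axes(self):
        mm_a = _mm_from_centroids(_archetype_centroids())
        profiles = sd.archetype_level_profiles(9)
        rows = [(p - p.mean()) / p.std(ddof=1) for p in
                (profiles[a] for a in sd.ARCHETYPES)]
        mm_b = _mm_from_centroids(
            pd.DataFrame(rows, index=range(1, 6), columns=[f"u{i}" for i in range(9)])
        )
        match = match_cluster_ids(mm_a, mm_b)
        assert match.b_to_a == {c: c for c in range(1, 6)}

    def test_unequal_k_rejected(self):
        mm_a = _mm_from_centroids(_archetype_centroids())
        C4 = _archetype_centroids().iloc[:4]
        mm_b = _mm_from_centroids(C4)
        with pytest.raises(ValueError, match="differ"):
            match_cluster_ids(mm_a, mm_b)

    def test_anticorrelated_flagged_low_confidence(self):
        # five near-identical rising centroids vs their negations: every
        # cross-correlation is strongly negative
        rng = np.random.default_rng(0)
        ramp = np.linspace(-1, 1, 6)
        rows = [ramp + rng.normal(0, 0.05, 6) for _ in range(5)]
        C = pd.DataFrame(rows, index=range(1, 6), columns=[f"t{i}" for i in range(6)])
        mm_a = _mm_from_centroids(C)
        mm_b = _mm_from_centroids(-C)
        match = match_cluster_ids(mm_a, mm_b)
        assert match.low_confidence
        assert sorted(match.b_to_a) == [1, 2, 3, 4, 5]


class TestCorrespondenceFractions:
    def test_identical_assignments_all_same(self):
        assign = {f"g{i}": (i % 5) + 1 for i in range(50)}
        res = correspondence_fractions(assign, assign, HPSC, list(assign))
        assert res.frac_same == 1.0 and res.frac_same_or_similar == 1.0

    def test_hand_counted_five_gene_example(self):
        """A=(1,2,4,5,3), B=(1,4,5,5,3) with down={1,2}, up={4,5}:
        3/5 same, 4/5 same-or-similar."""
        genes = [f"g{i}" for i in range(5)]
        assign_a = dict(zip(genes, [1, 2, 4, 5, 3]))
        assign_b = dict(zip(genes, [1, 4, 5, 5, 3]))
        res = correspondence_fractions(assign_a, assign_b, HPSC, genes)
        assert res.n_same == 3 and res.n_similar == 1 and res.n_neither == 1
        assert res.frac_same == pytest.approx(0.60)
        assert res.frac_same_or_similar == pytest.approx(0.80)

    def test_empty_shared_genes_gives_nan(self):
        res = correspondence_fractions({}, {}, HPSC, [])
        assert res.n_compared == 0
        assert np.isnan(res.frac_same) and np.isnan(res.frac_same_or_similar)

    def test_missing_genes_counted_as_dropped(self):
        res = correspondence_fractions({"g0": 1}, {"g0": 1}, HPSC, ["g0", "g1"])
        assert res.n_compared == 1 and res.n_dropped == 1

    def test_counts_partition_exactly(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(200)]
        a = {g: int(rng.integers(1, 6)) for g in genes}
        b = {g: int(rng.integers(1, 6)) for g in genes}
        res = correspondence_fractions(a, b, HPSC, genes)
        assert res.n_same + res.n_similar + res.n_neither == res.n_compared == 200

    def test_symmetric_under_dataset_swap(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(100)]
        a = {g: int(rng.integers(1, 6)) for g in genes}
        b = {g: int(rng.integers(1, 6)) for g in genes}
        r1 = correspondence_fractions(a, b, HPSC, genes)
        r2 = correspondence_fractions(b, a, HPSC, genes)
        assert r1.n_same == r2.n_same and r1.n_similar == r2.n_similar


class TestSchemes:
    def test_duplicate_cluster_in_scheme_rejected(self):
        with pytest.raises(ValueError, match="more than one group"):
            ClusterGroupScheme("bad", {
                "down": (frozenset({1, 2}), frozenset({1})),
                "up": (frozenset({2, 5}), frozenset({4, 5})),
            })

    def test_embryo_scheme_places_cluster3_up_on_embryo_side_only(self):
        scheme = SCHEMES["embryo_vs_hpsc"]
        assert scheme.group_of(3, 0) == "up"
        assert scheme.group_of(3, 1) is None


class TestDatasetCorrespondence:
    def test_invariant_under_cluster_renumbering(self, planted_profiles):
        prof, _ = planted_profiles
        mm_a = cluster_profiles(prof.profiles, 5, n_starts=5, seed=1)
        # same clustering with permuted ids
        perm = {1: 3, 2: 5, 3: 1, 4: 2, 5: 4}
        mm_b = MembershipMatrix(
            memberships=mm_a.memberships.rename(columns=perm)[list(range(1, 6))],
            centroids=mm_a.centroids.rename(index=perm).sort_index(),
            hard_assignment=mm_a.hard_assignment.map(perm),
            objective=mm_a.objective, n_iter=mm_a.n_iter, converged=True,
        )
        res = dataset_correspondence(mm_a, mm_b, HPSC)
        assert res.frac_same == 1.0


class TestCrossSpecies:
    def test_relabeled_copy_is_all_same(self, planted_profiles):
        prof, _ = planted_profiles
        mm_a = cluster_profiles(prof.profiles, 5, n_starts=5, seed=2)
        prof_b = prof.profiles.set_axis([f"B_{g}" for g in prof.profiles.index])
        mm_b = cluster_profiles(prof_b, 5, n_starts=5, seed=7)
        table = pd.DataFrame({"gene_a": list(prof.profiles.index),
                              "gene_b": [f"B_{g}" for g in prof.profiles.index]})
        res = cross_species_correspondence(mm_a, mm_b, table, HPSC)
        assert res.n_compared == len(prof.profiles)
        assert res.frac_same == 1.0

    def test_planted_split_recovers_analytic_fractions(self):
        """60% same / 25% similar / 15% opposite planted archetypes across
        species must land within the 95% binomial interval of 60% and 85%."""
        arch_a, arch_b, _ = sd.generate_correspondence_truth(500, 125, seed=9)
        tps = ["t0", "t1", "t2", "t3", "t4", "t5"]
        ma, sha, _ = sd.generate_timecourse_from_archetypes(arch_a, tps, 3, 1, 0.15, 21)
        arch_b_ns = {f"B_{g}": a for g, a in arch_b.items()}
        mb, shb, _ = sd.generate_timecourse_from_archetypes(arch_b_ns, tps, 3, 1, 0.15, 22)
        table = pd.DataFrame({"gene_a": list(arch_a),
                              "gene_b": [f"B_{g}" for g in arch_a]})
        mm_a = label_clusters(cluster_profiles(
            standardize_profiles(to_log2(ma), sha).profiles, 5, seed=1))
        mm_b = label_clusters(cluster_profiles(
            standardize_profiles(to_log2(mb), shb).profiles, 5, seed=2))
        shared = [g for g, a in arch_a.items() if a != "up_n_dn"]
        res = cross_species_correspondence(mm_a, mm_b, table, HPSC,
                                           shared_genes=shared)
        n = res.n_compared
        assert n == 500
        ci_same = 1.96 * np.sqrt(0.6 * 0.4 / n)
        ci_sim = 1.96 * np.sqrt(0.85 * 0.15 / n)
        assert abs(res.frac_same - 0.60) <= ci_same
        assert abs(res.frac_same_or_similar - 0.85) <= ci_sim

    def test_many_to_one_orthologs_excluded(self, planted_profiles):
        prof, _ = planted_profiles
        sub = prof.profiles.iloc[:100]
        mm_a = cluster_profiles(sub, 5, n_starts=5, seed=3)
        prof_b = sub.set_axis([f"B_{g}" for g in sub.index])
        mm_b = cluster_profiles(prof_b, 5, n_starts=5, seed=3)
        genes = list(sub.index)
        rows = [(g, f"B_{g}") for g in genes]
        rows.append((genes[0], "B_decoy"))  # genes[0] now maps twice
        table = pd.DataFrame(rows, columns=["gene_a", "gene_b"])
        res = cross_species_correspondence(mm_a, mm_b, table, HPSC)
        assert res.n_compared == 99
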