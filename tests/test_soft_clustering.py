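import math

import numpy as np
import pandas as pd
import pytest

from capacitrack import synthetic_data as sd
from capacitrack import to_log2
from capacitrack.errors import LabelingError
from capacitrack.soft_clustering import (
    cluster_profiles,
    cluster_set_enrichment,
    elbow_select_k,
    fuzzy_cmeans,
    hard_wss,
    label_clusters,
    read_membership,
    standardize_profiles,
    write_membership,
)
from conftest import archetype_agreement


def fcm_oracle(X, V0, m, n_iter):
    """Independent loop-based implementation of the fuzzy c-means update
    equations, run for a fixed number of iterations from a fixed init."""
    V = V0.copy().astype(float)
    n, k = X.shape[0], V.shape[0]
    U = np.zeros((n, k))
    for _ in range(n_iter):
        for g in range(n):
            d2 = [(float(np.sum((X[g] - V[c]) ** 2))) for c in range(k)]
            if min(d2) == 0:
                U[g] = 0.0
                U[g][d2.index(0)] = 1.0
                continue
            for c in range(k):
                U[g, c] = 1.0 / sum((d2[c] / d2[j]) ** (1.0 / (m - 1.0)) for j in range(k))
        for c in range(k):
            w = U[:, c] ** m
            V[c] = (w[:, None] * X).sum(axis=0) / w.sum()
    return U, V


class TestStandardize:
    def test_mean_zero_sd_one(self, small_timecourse):
        matrix, sheet, _ = small_timecourse
        prof = standardize_profiles(to_log2(matrix), sheet, cell_line="CL1")
        assert np.allclose(prof.profiles.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(prof.profiles.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_flat_genes_dropped(self, noiseless_timecourse):
        matrix, sheet, truth = noiseless_timecourse
        prof = standardize_profiles(to_log2(matrix), sheet, cell_line="CL1")
        background = {g for g, a in truth.gene_archetype.items() if a == "background"}
        assert set(prof.dropped) == background

    def test_affine_invariance(self, small_timecourse):
        matrix, sheet, _ = small_timecourse
        lg = to_log2(matrix)
        prof1 = standardize_profiles(lg, sheet, cell_line="CL1")
        scaled = type(lg)(lg.values * 3.0 + 11.0, "log2fpkm")
        prof2 = standardize_profiles(scaled, sheet, cell_line="CL1")
        pd.testing.assert_frame_equal(prof1.profiles, prof2.profiles)


class TestFuzzyCMeans:
    def _two_groups(self):
        # 6 hand-placed points in 2 tight groups in 2-D
        X = np.array([
            [0.0, 0.0], [0.1, 0.0], [0.0, 0.1],
            [5.0, 5.0], [5.1, 5.0], [5.0, 5.1],
        ])
        return pd.DataFrame(X, index=[f"g{i}" for i in range(6)], columns=["t0", "t1"])

    def test_matches_independent_oracle(self):
        prof = self._two_groups()
        X = prof.to_numpy()
        V0 = X[[0, 3]]
        mm = fuzzy_cmeans(prof, k=2, m=1.25, tol=0.0, max_iter=25,
                          init_centroids=V0)
        U_oracle, _ = fcm_oracle(X, V0, 1.25, 25)
        assert np.abs(mm.memberships.to_numpy() - U_oracle).max() < 1e-8

    def test_identical_genes_identical_memberships(self):
        prof = self._two_groups()
        prof.loc["g1"] = prof.loc["g0"]
        mm = fuzzy_cmeans(prof, 2, seed=0)
        assert np.allclose(mm.memberships.loc["g0"], mm.memberships.loc["g1"])

    def test_memberships_sum_to_one(self, planted_profiles):
        prof, _ = planted_profiles
        mm = fuzzy_cmeans(prof.profiles, 5, seed=1)
        assert np.allclose(mm.memberships.sum(axis=1), 1.0, atol=1e-9)

    def test_objective_non_increasing(self, planted_profiles):
        prof, _ = planted_profiles
        mm = fuzzy_cmeans(prof.profiles, 5, seed=2)
        path = np.asarray(mm.objective_path)
        assert (np.diff(path) <= 1e-8 * path[0]).all()

    def test_small_fuzzifier_approaches_hard_assignment(self, planted_profiles):
        prof, _ = planted_profiles
        mm = cluster_profiles(prof.profiles, 5, m=1.01, n_starts=5, seed=3)
        assert float(mm.memberships.max(axis=1).mean()) >= 0.99

    def test_k_larger_than_genes_rejected(self):
        prof = self._two_groups()
        with pytest.raises(ValueError, match="k="):
            fuzzy_cmeans(prof, 7)

    def test_cluster_recovery_planted_archetypes(self, planted_profiles):
        prof, truth = planted_profiles
        mm = cluster_profiles(prof.profiles, 5, m=1.25, n_starts=10, seed=5)
        assert archetype_agreement(mm, truth) >= 0.95


class TestElbow:
    def test_selects_planted_k(self, planted_profiles):
        prof, _ = planted_profiles
        res = elbow_select_k(prof.profiles, range(2, 10), m=1.25, n_starts=10, seed=0)
        assert res.k == 5 and not res.low_confidence

    def test_wss_non_increasing(self, planted_profiles):
        prof, _ = planted_profiles
        res = elbow_select_k(prof.profiles, range(2, 10), n_starts=10, seed=1)
        assert (np.diff(res.table["wss"]) <= 1e-9).all()

    def test_structureless_data_flagged_low_confidence(self):
        rng = np.random.default_rng(6)
        prof = pd.DataFrame(rng.normal(size=(300, 6)),
                            index=[f"g{i}" for i in range(300)])
        res = elbow_select_k(prof, range(2, 10), n_starts=5, seed=2)
        assert res.low_confidence

    def test_short_range_rejected(self, planted_profiles):
        prof, _ = planted_profiles
        with pytest.raises(ValueError, match="interior"):
            elbow_select_k(prof.profiles, [2, 3])


class TestLabeling:
    def _archetype_mm(self, flip=False):
        profiles = sd.archetype_level_profiles(6)
        rows = []
        for arch in sd.ARCHETYPES:
            p = profiles[arch]
            z = (p - p.mean()) / p.std(ddof=1)
            rows.append(-z if flip else z)
        C = pd.DataFrame(rows, index=range(1, 6), columns=[f"t{i}" for i in range(6)])
        from capacitrack.soft_clustering import MembershipMatrix
        genes = [f"g{i}" for i in range(5)]
        return MembershipMatrix(
            memberships=pd.DataFrame(np.eye(5), index=genes, columns=range(1, 6)),
            centroids=C,
            hard_assignment=pd.Series(range(1, 6), index=genes),
            objective=0.0, n_iter=1, converged=True,
        )

    def test_planted_centroids_labeled_exactly(self):
        mm = label_clusters(self._archetype_mm())
        assert [mm.labels[c] for c in range(1, 6)] == list(sd.ARCHETYPES)

    def test_sign_flip_swaps_up_down(self):
        mm = label_clusters(self._archetype_mm(flip=True))
        assert mm.labels[1] == "early_up"   # flipped early_down
        assert mm.labels[2] == "late_up"
        assert mm.labels[3] == "up_n_dn"
        assert mm.labels[4] == "early_down"
        assert mm.labels[5] == "late_down"

    def test_all_monotone_raises(self):
        mm = self._archetype_mm()
        C = mm.centroids.copy()
        C.loc[3] = np.linspace(-1, 1, 6)  # replace up_n_dn with a ramp
        from dataclasses import replace
        with pytest.raises(LabelingError, match="up-and-down"):
            label_clusters(replace(mm, centroids=C))

    def test_wrong_k_rejected(self, planted_profiles):
        prof, _ = planted_profiles
        mm = cluster_profiles(prof.profiles.iloc[:50], 4, seed=0)
        with pytest.raises(ValueError, match="k=5"):
            label_clusters(mm)

    def test_fitted_centroids_match_planted_archetypes(self, planted_profiles):
        prof, truth = planted_profiles
        mm = label_clusters(cluster_profiles(prof.profiles, 5, n_starts=10, seed=5))
        lab = mm.assignment_by_label()
        agree = np.mean([truth.gene_archetype[g] == lab[g] for g in lab.index])
        assert agree >= 0.95


def hypergeom_oracle(N, K, n, overlap):
    """Direct summation of hypergeometric upper-tail terms."""
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
        for i in range(overlap, min(K, n) + 1)
    )


class TestEnrichment:
    def _mm(self, assignment):
        from capacitrack.soft_clustering import MembershipMatrix
        genes = list(assignment)
        ks = sorted(set(assignment.values()))
        mem = pd.DataFrame(0.0, index=genes, columns=ks)
        for g, c in assignment.items():
            mem.loc[g, c] = 1.0
        return MembershipMatrix(
            memberships=mem,
            centroids=pd.DataFrame(np.zeros((len(ks), 3)), index=ks),
            hard_assignment=pd.Series(assignment),
            objective=0.0, n_iter=1, converged=True,
        )

    def test_exact_hand_value(self):
        # N=20 universe, cluster of n=4, set of K=5, overlap 3
        genes = [f"g{i}" for i in range(20)]
        assignment = {g: (1 if i < 4 else 2) for i, g in enumerate(genes)}
        mm = self._mm(assignment)
        gene_set = {"S": genes[:3] + genes[10:12]}  # 3 in cluster 1, K=5
        res = cluster_set_enrichment(mm, gene_set, genes)
        p = float(res[(res["cluster"] == 1)]["p"].iloc[0])
        assert p == pytest.approx(hypergeom_oracle(20, 5, 4, 3), abs=1e-12)
        assert p == pytest.approx(155 / 4845, abs=1e-12)

    def test_disjoint_set_p_one(self):
        genes = [f"g{i}" for i in range(10)]
        mm = self._mm({g: (1 if i < 5 else 2) for i, g in enumerate(genes)})
        res = cluster_set_enrichment(mm, {"S": genes[5:8]}, genes)
        assert float(res[res["cluster"] == 1]["p"].iloc[0]) == pytest.approx(
            hypergeom_oracle(10, 3, 5, 0)
        )

    def test_cluster_equals_set_is_minimal_p(self):
        genes = [f"g{i}" for i in range(12)]
        mm = self._mm({g: (1 if i < 4 else 2) for i, g in enumerate(genes)})
        sets = {"match": genes[:4], "other": genes[4:8], "mixed": genes[2:6]}
        res = cluster_set_enrichment(mm, sets, genes).set_index("gene_set")
        c1 = res[res["cluster"] == 1]
        assert c1.loc["match", "p"] == c1["p"].min()

    def test_empty_universe_rejected(self):
        mm = self._mm({"g0": 1, "g1": 2})
        with pytest.raises(ValueError, match="universe"):
            cluster_set_enrichment(mm, {"S": ["g0"]}, [])

    def test_enriched_synthetic_set_beats_uniform(self, planted_profiles):
        prof, truth = planted_profiles
        mm = label_clusters(cluster_profiles(prof.profiles, 5, n_starts=10, seed=5))
        genes = mm.gene_ids
        sets = sd.generate_gene_sets(
            genes, 4, 25, enriched_cluster="early_up",
            gene_archetype=truth.gene_archetype, seed=3,
        )
        res = cluster_set_enrichment(mm, sets, genes)
        canon = {lab: cid for cid, lab in mm.labels.items()}
        c = canon["early_up"]
        sub = res[res["cluster"] == c].set_index("gene_set")
        p_enriched = sub.loc["SET_ENRICHED_early_up", "p"]
        assert (p_enriched < sub.drop("SET_ENRICHED_early_up")["p"]).all()


def test_membership_round_trip(tmp_path, planted_profiles):
    prof, _ = planted_profiles
    # every 7th gene: a 143-gene subset still spanning all five archetypes
    mm = label_clusters(cluster_profiles(prof.profiles.iloc[::7], 5, seed=4))
    write_membership(mm, tmp_path / "m.tsv", tmp_path / "c.tsv")
    back = read_membership(tmp_path / "m.tsv", tmp_path / "c.tsv")
    assert back.labels == mm.labels
    assert (back.hard_assignment == mm.hard_assignment).all()
    assert np.allclose(back.centroids, mm.centroids)
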