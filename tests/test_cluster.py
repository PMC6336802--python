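"""Sparse k-means: exactness of the half-steps against hand/brute-force
oracles, objective monotonicity, the k-means limit, and two-level
stratification on separable data."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from fepstrat.cluster import (
    EmptyClusterError,
    HierarchicalKSparse,
    KSparseCluster,
    choose_sparsity,
    reconstruction_objective,
    standardize_items,
    wstep,
    ystep,
)
from fepstrat.panss import ITEM_NAMES
from fepstrat.simulate import SUBTYPES, SyntheticCohortConfig, generate_cohort

from conftest import strong_separation_signature


def two_blobs(n_per=30, d=10, informative=(2, 7), gap=4.0, noise=0.5, seed=0):
    """Two Gaussian blobs differing only on the informative items."""
    rng = np.random.default_rng(seed)
    X = rng.normal(4.0, noise, size=(2 * n_per, d))
    for j in informative:
        X[:n_per, j] += gap / 2
        X[n_per:, j] -= gap / 2
    labels = np.repeat([0, 1], n_per)
    return np.clip(X, 1, 7), labels


class TestStandardize:
    def test_zscoring_definition(self):
        Z = standardize_items(np.array([[1.0], [3.0], [5.0]]))
        assert Z.values.mean() == pytest.approx(0, abs=1e-10)
        assert Z.values.std() == pytest.approx(1, abs=1e-10)

    def test_constant_column_maps_to_zero(self):
        Z = standardize_items(np.array([[4.0, 1.0], [4.0, 2.0], [4.0, 3.0]]))
        assert (Z.values[:, 0] == 0).all()
        assert Z.standardization.constant[0]
        assert not Z.standardization.constant[1]

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(1, 7, size=(20, 5))
        Z = standardize_items(X)
        back = Z.standardization.inverse(Z.values)
        np.testing.assert_allclose(back, X, atol=1e-10)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            standardize_items(np.ones((1, 3)))


class TestWStep:
    def test_hand_computed_toy(self):
        # 4 patients x 3 items, clusters {0,1} and {2,3}; separation only on item 2
        Z = np.array(
            [
                [0.1, -0.2, 2.0],
                [-0.1, 0.2, 2.2],
                [0.1, 0.2, -2.0],
                [-0.1, -0.2, -2.2],
            ]
        )
        labels = np.array([0, 0, 1, 1])
        # hand computation: cluster means and explained SS per item
        means = np.stack([Z[:2].mean(0), Z[2:].mean(0)])  # 2 x 3
        delta = (2 * means**2).sum(axis=0)
        assert delta[2] > delta[0] and delta[2] > delta[1]
        W, sel = wstep(Z, labels, k=2, s=1)
        assert list(sel) == [2]
        np.testing.assert_allclose(W[2], means[:, 2])
        assert (W[[0, 1]] == 0).all()

    def test_k1_full_sparsity_gives_overall_means(self):
        rng = np.random.default_rng(0)
        Z = standardize_items(rng.uniform(1, 7, (15, 4))).values
        W, sel = wstep(Z, np.zeros(15, dtype=int), k=1, s=4)
        np.testing.assert_allclose(W[:, 0], Z.mean(0), atol=1e-12)
        np.testing.assert_allclose(W[:, 0], 0.0, atol=1e-10)

    def test_full_s_objective_is_within_cluster_ss(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(30, 6))
        labels = rng.integers(0, 3, 30)
        while len(np.unique(labels)) < 3:
            labels = rng.integers(0, 3, 30)
        W, sel = wstep(Z, labels, k=3, s=6)
        obj = reconstruction_objective(Z, labels, W)
        wss = sum(
            ((Z[labels == j] - Z[labels == j].mean(0)) ** 2).sum() for j in range(3)
        )
        assert obj == pytest.approx(wss, abs=1e-8)

    def test_selection_tie_breaks_to_lower_index(self):
        # items 0 and 1 identical: the tie must resolve to item 0
        Z = np.array([[1.0, 1.0, 0.0], [-1.0, -1.0, 0.0]])
        W, sel = wstep(Z, np.array([0, 1]), k=2, s=1)
        assert list(sel) == [0]

    def test_empty_cluster_raises(self):
        with pytest.raises(EmptyClusterError):
            wstep(np.zeros((3, 2)), np.array([0, 0, 0]), k=2, s=1)


class TestYStep:
    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(10, 5))
        W = rng.normal(size=(5, 3))
        sel = np.array([0, 2, 4])
        labels = ystep(Z, W, sel)
        for i in range(10):
            dists = [((Z[i, sel] - W[sel, j]) ** 2).sum() for j in range(3)]
            assert labels[i] == int(np.argmin(dists))

    def test_centroid_point_assigned_to_its_cluster(self):
        W = np.array([[1.0, -1.0], [2.0, -2.0]])
        Z = np.array([[1.0, 2.0]])
        assert ystep(Z, W, np.array([0, 1]))[0] == 0

    def test_equidistant_tie_goes_to_lowest_cluster(self):
        W = np.array([[1.0, -1.0]])
        Z = np.array([[0.0]])
        assert ystep(Z, W, np.array([0]))[0] == 0


class TestFit:
    def test_recovers_sparse_blobs_and_items(self):
        X, truth = two_blobs(seed=4)
        res = KSparseCluster(X, k=2, s=2).fit(n_starts=10, seed=0)
        assert adjusted_rand_score(truth, res.labels) == 1.0
        assert res.selected_items == ["x2", "x7"]

    def test_identical_rows_zero_objective(self):
        X = np.full((8, 4), 3.0)
        res = KSparseCluster(X, k=1, s=4).fit(n_starts=2, seed=0)
        assert res.objective == pytest.approx(0.0, abs=1e-12)

    def test_objective_path_monotone(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(1, 7, size=(60, 8))
        res = KSparseCluster(X, k=3, s=4).fit(n_starts=5, seed=1)
        path = np.array(res.objective_path)
        assert (np.diff(path) <= 1e-9).all()

    def test_full_s_matches_reference_kmeans(self):
        from sklearn.cluster import KMeans

        X, _ = two_blobs(seed=6)
        Z = standardize_items(X).values
        res = KSparseCluster(X, k=2, s=X.shape[1]).fit(n_starts=20, seed=0)
        km = KMeans(n_clusters=2, n_init=20, random_state=0).fit(Z)
        assert res.objective == pytest.approx(km.inertia_, abs=1e-6)

    def test_row_permutation_equivariance(self):
        X, truth = two_blobs(seed=7)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(X))
        res_a = KSparseCluster(X, k=2, s=2).fit(n_starts=10, seed=3)
        res_b = KSparseCluster(X[perm], k=2, s=2).fit(n_starts=10, seed=3)
        assert adjusted_rand_score(res_a.labels[perm], res_b.labels) == 1.0

    def test_solution_invariants(self):
        X, _ = two_blobs(seed=8)
        res = KSparseCluster(X, k=2, s=3).fit(n_starts=5, seed=0)
        nonzero_rows = np.flatnonzero((res.weights != 0).any(axis=1))
        assert set(nonzero_rows) <= set(res.selected_idx)
        assert len(res.selected_idx) == 3
        Z = standardize_items(X).values
        assert reconstruction_objective(Z, res.labels, res.weights) == pytest.approx(
            res.objective, abs=1e-8
        )

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            KSparseCluster(np.ones((2, 3)), k=3, s=1)


class TestChooseSparsity:
    def test_recovers_true_informative_count(self):
        # exactly two items carry signal (jointly clean, individually
        # ambiguous); the remaining items are constant, so every s >= 2
        # yields the same partition and the tie rule must settle on 2
        rng = np.random.default_rng(9)
        n_per = 100
        X = np.full((2 * n_per, 10), 4.0)
        for j in (2, 7):
            X[:, j] = rng.normal(4.0, 1.0, 2 * n_per)
            X[:n_per, j] += 1.1
            X[n_per:, j] -= 1.1
        X = np.clip(X, 1, 7)
        s = choose_sparsity(X, k=2, s_grid=range(1, 11), seed=0, n_starts=10)
        assert s == 2

    def test_singleton_grid(self):
        X, _ = two_blobs(seed=10)
        assert choose_sparsity(X, k=2, s_grid=[4], seed=0, n_starts=5) == 4

    def test_tie_breaks_to_smallest(self):
        # item 2 duplicates item 0: s=2 and s=3 give identical partitions,
        # hence identical silhouettes, and the tie resolves to s=2
        X, _ = two_blobs(d=3, informative=(0, 1), seed=11)
        X[:, 2] = X[:, 0]
        s = choose_sparsity(X, k=2, s_grid=[2, 3], seed=0, n_starts=10)
        assert s == 2


class TestHierarchical:
    def test_minimal_noise_free_recovery(self):
        sig = strong_separation_signature()
        cfg = SyntheticCohortConfig(
            n_patients=48,
            subtype_proportions={st: 0.25 for st in SUBTYPES},
            item_signature=sig,
            severity_sd=0.0,
            item_noise_sd=0.0,
            seed=20,
        )
        c = generate_cohort(cfg)
        res = HierarchicalKSparse(
            c.panss, s_level1=9, s_within={"C1": 8, "C2": 7}, n_starts=10
        ).fit(seed=0)
        assert (res.final_labels == c.true_subtype).all()
        assert res.per_split_s == {"level1": 9, "C1": 8, "C2": 7}

    def test_four_patients_exact_recovery(self):
        sig = strong_separation_signature()
        rows = sig.loc[list(SUBTYPES)].round().astype(int)
        res = HierarchicalKSparse(
            rows, s_level1=9, s_within={"C1": 8, "C2": 7}, n_starts=10
        ).fit(seed=0)
        assert list(res.final_labels) == list(SUBTYPES)

    def test_assign_new_self_consistency(self, separable_cohort):
        res = HierarchicalKSparse(
            separable_cohort.panss, s_level1=9, s_within={"C1": 8, "C2": 7}
        ).fit(seed=0)
        re_assigned = res.assign_new(separable_cohort.panss)
        assert (re_assigned == res.final_labels).all()

    def test_assign_new_item_mismatch_rejected(self, separable_cohort):
        res = HierarchicalKSparse(separable_cohort.panss, s_level1=9, s_within=7).fit(seed=0)
        bad = separable_cohort.panss.values.iloc[:5, :10]
        with pytest.raises(ValueError, match="item-name"):
            res.level1.assign_new(bad)

    def test_severity_based_naming(self, separable_cohort):
        res = HierarchicalKSparse(
            separable_cohort.panss, s_level1=9, s_within={"C1": 8, "C2": 7}
        ).fit(seed=0)
        totals = separable_cohort.panss.values.sum(axis=1).groupby(res.final_labels).mean()
        neg = separable_cohort.panss.values[[f"N{i}" for i in range(1, 8)]].sum(axis=1)
        neg_means = neg.groupby(res.final_labels.str[:2]).mean()
        assert neg_means["C1"] > neg_means["C2"]
        assert totals["C1A"] > totals["C1B"]
        assert totals["C2A"] > totals["C2B"]
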