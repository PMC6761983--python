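import numpy as np
import pytest

import chromclust.clustering as clustering
from chromclust import (
    GridSpec,
    PeakWeights,
    SyntheticSpec,
    adjusted_rand,
    cluster,
    grid_search,
    kmeans_cells,
    multinomial_loglik,
    simulate_dataset,
    weighted_pca,
)
from chromclust.io_formats import ChromatinMatrix

from conftest import make_matrix, random_binary_matrix


def unit_weights(n):
    return PeakWeights(
        is_proximal=np.zeros(n, bool),
        dhs_frequency=np.zeros(n),
        weight=np.ones(n),
    )


def pca_oracle(dense, weights, n_pc):
    """Dense full-SVD PCA with the same sign convention, written flat."""
    y = dense * weights[:, None]
    y = y - y.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(y, full_matrices=False)
    scores = vt.T[:, :n_pc] * s[:n_pc]
    for j in range(n_pc):
        csum = u[:, j].sum()
        if csum < 0 or (np.isclose(csum, 0) and u[np.argmax(np.abs(u[:, j]) > 0), j] < 0):
            scores[:, j] *= -1
    return scores


class TestWeightedPca:
    def test_unit_weights_match_dense_svd_oracle(self):
        rng = np.random.default_rng(11)
        m = random_binary_matrix(rng, 40, 30)
        got = weighted_pca(m, unit_weights(40), n_pc=6)
        want = pca_oracle(m.values.toarray().astype(float), np.ones(40), 6)
        assert np.max(np.abs(got - want)) < 1e-8

    def test_nonuniform_weights_match_oracle(self):
        rng = np.random.default_rng(12)
        m = random_binary_matrix(rng, 35, 25)
        w = rng.uniform(0.1, 1.0, 35)
        pw = PeakWeights(np.zeros(35, bool), np.zeros(35), w)
        got = weighted_pca(m, pw, n_pc=5)
        want = pca_oracle(m.values.toarray().astype(float), w, 5)
        assert np.max(np.abs(got - want)) < 1e-8

    def test_zero_weight_peak_equals_deletion(self):
        rng = np.random.default_rng(13)
        m = random_binary_matrix(rng, 30, 20)
        w = np.ones(30)
        w[7] = 0.0
        pw = PeakWeights(np.zeros(30, bool), np.zeros(30), w)
        got = weighted_pca(m, pw, n_pc=4)
        keep = np.delete(np.arange(30), 7)
        m_del = ChromatinMatrix(
            values=m.values[keep],
            peak_ids=m.peak_ids[keep],
            cell_ids=m.cell_ids,
        )
        want = weighted_pca(m_del, unit_weights(29), n_pc=4)
        assert np.max(np.abs(got - want)) < 1e-10

    def test_rank_one_matrix_single_component(self):
        row = np.array([1, 1, 0, 0, 1, 0, 1, 0])
        x = np.outer(np.array([1, 1, 1, 0, 0]), row)
        m = make_matrix(x)
        scores = weighted_pca(m, unit_weights(5), n_pc=1)
        # a rank-1 centered matrix: component 1 carries all variance
        y = x - x.mean(axis=1, keepdims=True)
        total_var = np.sum(y**2)
        assert np.sum(scores**2) == pytest.approx(total_var, rel=1e-10)

    def test_truncated_path_matches_dense(self, monkeypatch):
        rng = np.random.default_rng(14)
        m = random_binary_matrix(rng, 80, 40)
        dense = weighted_pca(m, unit_weights(80), n_pc=5)
        monkeypatch.setattr(clustering, "_DENSE_SVD_MAX_ENTRIES", 10)
        trunc = weighted_pca(m, unit_weights(80), n_pc=5)
        assert np.max(np.abs(dense - trunc)) < 1e-6

    def test_n_pc_too_large_rejected(self):
        m = make_matrix(np.eye(6, dtype=np.int8))
        with pytest.raises(ValueError, match="n_pc"):
            weighted_pca(m, unit_weights(6), n_pc=6)

    def test_all_zero_weights_rejected(self):
        m = make_matrix(np.eye(6, dtype=np.int8))
        pw = PeakWeights(np.zeros(6, bool), np.zeros(6), np.zeros(6))
        with pytest.raises(ValueError, match="zero"):
            weighted_pca(m, pw, n_pc=2)


class TestKmeansCells:
    def test_separated_clouds_recovered(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, (30, 3))
        b = rng.normal(200, 1, (20, 3))
        labels = kmeans_cells(np.vstack([a, b]), k=2, seed=0)
        # canonical numbering: bigger cluster is 1
        assert np.all(labels[:30] == 1) and np.all(labels[30:] == 2)

    def test_k_equal_one(self):
        labels = kmeans_cells(np.zeros((5, 2)), k=1, seed=0)
        assert np.array_equal(labels, np.ones(5, dtype=int))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(0, 1, (50, 4))
        a = kmeans_cells(pts, k=3, seed=9)
        b = kmeans_cells(pts, k=3, seed=9)
        assert np.array_equal(a, b)

    def test_k_exceeding_cells_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_cells(np.zeros((3, 2)), k=4)


@pytest.fixture(scope="module")
def small_dataset():
    return simulate_dataset(
        SyntheticSpec(n_peaks=400, cells_per_cluster=20, n_clusters=2, seed=21)
    )


class TestGridSearch:
    def test_singleton_grid_returns_that_point(self, small_dataset):
        ds = small_dataset
        grid = GridSpec(
            w_proximal_candidates=(0.5,),
            gamma_candidates=(1.0,),
            n_pc_candidates=(4,),
            k_range=(2,),
            seed=0,
        )
        res = grid_search(ds.matrix, ds.peaks, ds.tss, ds.dhs_track, grid)
        assert res.chosen == {"w_proximal": 0.5, "gamma": 1.0, "n_pc": 4, "k": 2}
        assert len(res.grid_trace) == 1

    def test_reported_loglik_matches_recomputation(self, small_dataset):
        ds = small_dataset
        grid = GridSpec(n_pc_candidates=(4, 6), k_range=(2,), seed=0)
        res = grid_search(ds.matrix, ds.peaks, ds.tss, ds.dhs_track, grid, alpha=1.0)
        assert res.loglik == pytest.approx(
            multinomial_loglik(ds.matrix, res.labels, 1.0).loglik
        )

    def test_deterministic_given_seed(self, small_dataset):
        ds = small_dataset
        grid = GridSpec(n_pc_candidates=(4, 6), k_range=(2,), seed=3)
        a = grid_search(ds.matrix, ds.peaks, ds.tss, ds.dhs_track, grid)
        b = grid_search(ds.matrix, ds.peaks, ds.tss, ds.dhs_track, grid)
        assert np.array_equal(a.labels, b.labels)
        assert a.chosen == b.chosen and a.loglik == b.loglik

    def test_needs_single_k(self, small_dataset):
        ds = small_dataset
        grid = GridSpec(k_range=(2, 3))
        with pytest.raises(ValueError, match="single k"):
            grid_search(ds.matrix, ds.peaks, ds.tss, ds.dhs_track, grid)


class TestClusterEndToEnd:
    def test_fixed_k_skips_elbow(self, small_dataset):
        ds = small_dataset
        grid = GridSpec(n_pc_candidates=(4,), k_range=(2,), seed=0)
        res = cluster(ds.matrix, ds.peaks, ds.tss, ds.dhs_track, grid)
        assert res.elbow is None
        assert res.chosen["k"] == 2

    def test_partition_stable_under_cell_permutation(self, small_dataset):
        ds = small_dataset
        grid = GridSpec(n_pc_candidates=(4,), gamma_candidates=(0.0, 2.0),
                        k_range=(2,), seed=0)
        res = cluster(ds.matrix, ds.peaks, ds.tss, ds.dhs_track, grid)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.matrix.n_cells)
        m_perm = ChromatinMatrix(
            values=ds.matrix.values[:, perm].tocsr(),
            peak_ids=ds.matrix.peak_ids,
            cell_ids=ds.matrix.cell_ids[perm],
        )
        res_perm = cluster(m_perm, ds.peaks, ds.tss, ds.dhs_track, grid)
        # same partition up to relabeling
        assert adjusted_rand(res_perm.labels, res.labels[perm]) == pytest.approx(1.0)

    def test_elbow_curve_reported_when_scanning(self, small_dataset):
        ds = small_dataset
        grid = GridSpec(
            w_proximal_candidates=(1.0,),
            gamma_candidates=(0.0, 2.0),
            n_pc_candidates=(4,),
            k_range=(1, 2, 3, 4),
            seed=0,
        )
        res = cluster(ds.matrix, ds.peaks, ds.tss, ds.dhs_track, grid)
        assert res.elbow is not None
        assert list(res.elbow.k_values) == [1, 2, 3, 4]
        assert res.elbow.chosen_k == res.chosen["k"]
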