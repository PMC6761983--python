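import numpy as np
import pytest

from chromclust import (
    export_gene_covariates,
    gene_specificity,
    map_peaks_to_genes,
    specificity_association,
)
from chromclust.enrichment import read_gene_covariates
from chromclust.io_formats import PeakSet, TssAnnotation

from conftest import make_matrix


def peak_set(intervals):
    return PeakSet(
        chrom=np.array(["chr1"] * len(intervals), dtype=object),
        start=np.array([s for s, _ in intervals]),
        end=np.array([e for _, e in intervals]),
        peak_id=np.array([f"p{i}" for i in range(len(intervals))], dtype=object),
    )


def tss_for(genes_positions):
    n = len(genes_positions)
    return TssAnnotation(
        chrom=np.array(["chr1"] * n, dtype=object),
        tss_position=np.array([p for _, p in genes_positions]),
        strand=np.array(["+"] * n, dtype=object),
        gene_id=np.array([g for g, _ in genes_positions], dtype=object),
    )


class TestMapPeaksToGenes:
    def test_peak_containing_tss_maps_to_gene(self):
        mapping = map_peaks_to_genes(
            peak_set([(1000, 1500)]), tss_for([("gA", 1200)]), 3000
        )
        assert mapping == {"p0": ["gA"]}

    def test_peak_near_two_genes_maps_to_both(self):
        mapping = map_peaks_to_genes(
            peak_set([(5000, 5400)]),
            tss_for([("gA", 4500), ("gB", 6000)]),
            3000,
        )
        assert mapping["p0"] == ["gA", "gB"]

    def test_isolated_peak_unmapped(self):
        mapping = map_peaks_to_genes(
            peak_set([(100_000, 100_300)]), tss_for([("gA", 1000)]), 3000
        )
        assert "p0" not in mapping

    def test_window_boundary_half_open(self):
        # gene TSS at 5000, window/2 = 1500: a peak starting at 6500
        # does not reach [3500, 6500)
        assert "p0" not in map_peaks_to_genes(
            peak_set([(6500, 6800)]), tss_for([("gA", 5000)]), 3000
        )
        assert "p0" in map_peaks_to_genes(
            peak_set([(6499, 6800)]), tss_for([("gA", 5000)]), 3000
        )


class TestGeneSpecificity:
    def test_cluster_exclusive_gene(self):
        # gene gA's only peak is open solely in cluster-1 cells
        m = make_matrix([[1, 1, 0, 0], [1, 1, 1, 1]])
        labels = np.array([1, 1, 2, 2])
        s = gene_specificity(m, labels, {"p0": ["gA"]})
        np.testing.assert_allclose(s.values, [[1.0, 0.0]])

    def test_uniform_accessibility_gives_uniform_specificity(self):
        m = make_matrix([[1, 1, 1, 1, 1, 1]])
        labels = np.array([1, 1, 2, 2, 3, 3])
        s = gene_specificity(m, labels, {"p0": ["gA"]})
        np.testing.assert_allclose(s.values, [[1 / 3, 1 / 3, 1 / 3]])

    def test_hand_computed_two_gene_fixture(self):
        # peaks x cells; clusters {c0,c1} and {c2,c3}
        #   p0 = (1,1,0,1): cluster means 1.0 and 0.5
        #   p1 = (0,1,1,1): cluster means 0.5 and 1.0
        # gA <- p0: s = (2/3, 1/3); gB <- p1: s = (1/3, 2/3)
        m = make_matrix([[1, 1, 0, 1], [0, 1, 1, 1]])
        labels = np.array([1, 1, 2, 2])
        s = gene_specificity(m, labels, {"p0": ["gA"], "p1": ["gB"]})
        assert list(s.gene_ids) == ["gA", "gB"]
        np.testing.assert_allclose(
            s.values, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]], atol=1e-12
        )

    def test_multi_peak_gene_sums_cluster_means(self):
        m = make_matrix([[1, 1, 0, 0], [0, 0, 1, 1]])
        labels = np.array([1, 1, 2, 2])
        s = gene_specificity(m, labels, {"p0": ["gA"], "p1": ["gA"]})
        np.testing.assert_allclose(s.values, [[0.5, 0.5]])

    def test_inaccessible_gene_dropped_with_warning(self, caplog):
        m = make_matrix([[1, 1, 1, 1], [0, 0, 0, 0]])
        labels = np.array([1, 1, 2, 2])
        import logging

        with caplog.at_level(logging.WARNING):
            s = gene_specificity(m, labels, {"p0": ["gA"], "p1": ["gB"]})
        assert list(s.gene_ids) == ["gA"]
        assert "dropping 1 gene" in caplog.text

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        m = make_matrix((rng.random((30, 12)) < 0.4).astype(np.int8))
        labels = rng.integers(1, 4, 12)
        labels[:3] = [1, 2, 3]
        mapping = {f"p{i}": [f"g{i % 7}"] for i in range(30)}
        s = gene_specificity(m, labels, mapping)
        np.testing.assert_allclose(s.values.sum(axis=1), 1.0, atol=1e-9)

    def test_merged_identical_clusters_add_mass(self):
        # clusters 2 and 3 hold cells with identical columns; merging
        # them should concentrate exactly the sum of their shares
        cols = np.array(
            [[1, 1, 0, 0, 0, 0], [0, 0, 1, 1, 1, 1]]
        )
        m = make_matrix(cols)
        labels_split = np.array([1, 1, 2, 2, 3, 3])
        labels_merged = np.array([1, 1, 2, 2, 2, 2])
        mapping = {"p0": ["gA"], "p1": ["gB"]}
        s_split = gene_specificity(m, labels_split, mapping)
        s_merged = gene_specificity(m, labels_merged, mapping)
        np.testing.assert_allclose(
            s_merged.values[:, 1], s_split.values[:, 1] + s_split.values[:, 2]
        )


class TestSpecificityAssociation:
    def test_perfectly_aligned_statistic_gives_minimal_p(self):
        rng = np.random.default_rng(1)
        s_col = rng.permutation(np.linspace(0.01, 0.99, 40))  # distinct values
        p = specificity_association(s_col, s_col.copy(), n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(2)
        s_col = rng.random(30)
        stats = rng.random(30)
        a = specificity_association(s_col, stats, n_perm=199, seed=5)
        b = specificity_association(s_col, stats, n_perm=199, seed=5)
        assert a == b

    def test_p_never_below_permutation_floor(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            p = specificity_association(
                rng.random(25), rng.random(25), n_perm=199, seed=0
            )
            assert p >= 1 / 200

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="10 shared genes"):
            specificity_association(np.ones(5), np.ones(5), n_perm=200)

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError, match="n_perm"):
            specificity_association(np.zeros(20), np.zeros(20), n_perm=50)


class TestCovariateExport:
    def test_round_trip_and_headers(self, tmp_path):
        m = make_matrix([[1, 1, 0, 1], [0, 1, 1, 1]])
        labels = np.array([1, 1, 2, 2])
        s = gene_specificity(m, labels, {"p0": ["gA"], "p1": ["gB"]})
        path = tmp_path / "covariates.tsv"
        export_gene_covariates(s, path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header == ["gene_id", "cluster_1", "cluster_2"]
        back = read_gene_covariates(path)
        assert list(back.gene_ids) == list(s.gene_ids)
        np.testing.assert_allclose(back.values, s.values)

    def test_dropped_genes_absent_from_export(self, tmp_path):
        m = make_matrix([[1, 1, 1, 1], [0, 0, 0, 0]])
        labels = np.array([1, 1, 2, 2])
        s = gene_specificity(m, labels, {"p0": ["gA"], "p1": ["gDead"]})
        path = tmp_path / "covariates.tsv"
        export_gene_covariates(s, path)
        assert "gDead" not in path.read_text()
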