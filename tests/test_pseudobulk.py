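"""Pseudobulk aggregation, normalization identities, UQ factors, markers."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from cardiocomm.io_qc import CountMatrix
from cardiocomm.pseudobulk import (aggregate_pseudobulk,
                                   average_expression_reference, marker_genes,
                                   normalize_pseudobulk, upper_quartile,
                                   upper_quartile_factors)
from conftest import random_count_matrix


def _setup(counts, clusters, datasets=None):
    counts = np.asarray(counts)
    genes = pd.Index([f"g{i}" for i in range(counts.shape[0])])
    barcodes = pd.Index([f"b{i}" for i in range(counts.shape[1])])
    m = CountMatrix(genes, barcodes, sparse.csr_matrix(counts))
    ann = pd.DataFrame({
        "cluster": clusters,
        "dataset": datasets or ["d1"] * len(barcodes),
        "condition": "PBS", "timepoint": 3,
    }, index=barcodes)
    return m, ann


class TestAggregate:
    def test_two_cell_mean_and_sum(self):
        m, ann = _setup([[3, 5]], ["A", "A"])
        pb = aggregate_pseudobulk(m, ann)
        assert pb.raw_mean.iloc[0, 0] == 4 and pb.raw_sum.iloc[0, 0] == 8

    def test_single_cell_group_identity(self):
        m, ann = _setup([[7], [0], [2]], ["solo"])
        pb = aggregate_pseudobulk(m, ann)
        assert list(pb.raw_mean.iloc[:, 0]) == [7, 0, 2]

    def test_all_zero_gene_zero_everywhere(self):
        m, ann = _setup([[1, 2, 3], [0, 0, 0]], ["A", "A", "B"])
        pb = aggregate_pseudobulk(m, ann)
        assert (pb.raw_mean.loc["g1"] == 0).all()

    def test_unannotated_barcode_raises(self):
        m, ann = _setup([[1, 2]], ["A", "A"])
        with pytest.raises(KeyError):
            aggregate_pseudobulk(m, ann.iloc[:1])

    def test_matches_dense_brute_force(self, rng):
        m = random_count_matrix(rng, n_genes=25, n_cells=60)
        clusters = rng.choice(["A", "B", "C"], size=60)
        datasets = rng.choice(["d1", "d2"], size=60)
        ann = pd.DataFrame({"cluster": clusters, "dataset": datasets},
                           index=m.barcodes)
        pb = aggregate_pseudobulk(m, ann)
        dense = np.asarray(m.counts.todense())
        for (c, d) in pb.groups:
            cells = (clusters == c) & (datasets == d)
            np.testing.assert_allclose(pb.raw_mean[(c, d)].to_numpy(),
                                       dense[:, cells].mean(axis=1))
        # raw_mean * n_cells == raw_sum
        np.testing.assert_allclose(
            pb.raw_mean.to_numpy() * pb.n_cells.to_numpy()[None, :],
            pb.raw_sum.to_numpy())

    def test_invariant_to_barcode_order(self, rng):
        m = random_count_matrix(rng, n_genes=15, n_cells=30)
        clusters = rng.choice(["A", "B"], size=30)
        ann = pd.DataFrame({"cluster": clusters, "dataset": "d1"},
                           index=m.barcodes)
        order = rng.permutation(30)
        m2 = m.subset_barcodes(m.barcodes[order])
        pb1 = aggregate_pseudobulk(m, ann)
        pb2 = aggregate_pseudobulk(m2, ann.iloc[order])
        pd.testing.assert_frame_equal(pb1.raw_mean, pb2.raw_mean)


class TestNormalize:
    def test_fractions_of_scale(self):
        m, ann = _setup([[8], [2]], ["A"])
        pb = normalize_pseudobulk(aggregate_pseudobulk(m, ann), scale=1e6)
        assert list(pb.norm.iloc[:, 0]) == [800000.0, 200000.0]

    def test_single_nonzero_gene_takes_full_scale(self):
        m, ann = _setup([[0], [9]], ["A"])
        pb = normalize_pseudobulk(aggregate_pseudobulk(m, ann), scale=1e4)
        assert list(pb.norm.iloc[:, 0]) == [0.0, 1e4]

    def test_columns_sum_to_scale(self, rng):
        m = random_count_matrix(rng, n_genes=30, n_cells=40)
        ann = pd.DataFrame({"cluster": rng.choice(["A", "B"], 40),
                            "dataset": "d1"}, index=m.barcodes)
        pb = normalize_pseudobulk(aggregate_pseudobulk(m, ann))
        np.testing.assert_allclose(pb.norm.sum(axis=0), 1e6, rtol=1e-12)

    def test_zero_total_group_error_names_group(self):
        m, ann = _setup([[0, 3]], ["empty", "full"])
        pb = aggregate_pseudobulk(m, ann)
        with pytest.raises(ValueError, match="empty"):
            normalize_pseudobulk(pb)


class TestUpperQuartile:
    def test_linear_interpolation_value(self):
        assert upper_quartile([1, 4, 10, 100]) == pytest.approx(32.5)

    def test_zeros_excluded(self):
        assert upper_quartile([0, 0, 1, 4, 10, 100]) == pytest.approx(32.5)

    def test_identical_samples_unit_factors(self):
        df = pd.DataFrame({"s1": [1, 5, 9], "s2": [1, 5, 9]})
        np.testing.assert_allclose(upper_quartile_factors(df), 1.0)

    def test_factors_relative_to_geometric_mean(self):
        df = pd.DataFrame({"s1": [20.0, 20.0], "s2": [80.0, 80.0]})
        factors = upper_quartile_factors(df)
        np.testing.assert_allclose(factors.to_numpy(), [0.5, 2.0])
        # dividing by factors equalizes the upper quartiles
        adj = df / factors
        assert adj["s1"].iloc[0] == adj["s2"].iloc[0]

    def test_all_zero_sample_errors(self):
        with pytest.raises(ValueError, match="s2"):
            upper_quartile_factors(pd.DataFrame({"s1": [1.0], "s2": [0.0]}))


class TestAverageExpressionReference:
    def test_grouped_by_cluster_and_timepoint(self):
        m, ann = _setup([[2, 4, 6]], ["A", "A", "A"])
        ann["timepoint"] = [1, 1, 7]
        ref = average_expression_reference(m, ann)
        assert ref[("A", 1)].iloc[0] == 3 and ref[("A", 7)].iloc[0] == 6


class TestMarkers:
    def _planted(self, rng, fold=8.0, n_in=200, n_out=800):
        n_genes = 40
        base = np.full(n_genes, 3.0)
        lam_in, lam_out = base.copy(), base.copy()
        lam_in[0] *= fold  # g0 is the marker
        Xin = rng.poisson(lam_in[:, None], (n_genes, n_in))
        Xout = rng.poisson(lam_out[:, None], (n_genes, n_out))
        counts = np.hstack([Xin, Xout])
        genes = pd.Index([f"g{i}" for i in range(n_genes)])
        barcodes = pd.Index([f"b{i}" for i in range(n_in + n_out)])
        m = CountMatrix(genes, barcodes, sparse.csr_matrix(counts))
        ann = pd.DataFrame({"cluster": ["in"] * n_in + ["out"] * n_out,
                            "dataset": "d1"}, index=barcodes)
        return m, ann

    def test_planted_eightfold_marker_recovered(self, rng):
        m, ann = self._planted(rng)
        table = marker_genes(m, ann, "in")
        assert "g0" in table.index
        assert table.loc["g0", "log2fc"] > 0
        assert table.index[0] == "g0"  # ranked first by fold change

    def test_low_detection_gene_excluded_pretest(self, rng):
        m, ann = self._planted(rng)
        counts = np.asarray(m.counts.todense())
        in_cells = (ann["cluster"] == "in").to_numpy()
        counts[1, :] = 0
        idx = np.flatnonzero(in_cells)[:30]  # 15% detection in cluster
        counts[1, idx] = 100
        m2 = CountMatrix(m.genes, m.barcodes, sparse.csr_matrix(counts))
        table = marker_genes(m2, ann, "in")
        assert "g1" not in table.index

    def test_identical_gene_not_retained(self):
        counts = np.full((5, 30), 4)
        genes = pd.Index([f"g{i}" for i in range(5)])
        barcodes = pd.Index([f"b{i}" for i in range(30)])
        m = CountMatrix(genes, barcodes, sparse.csr_matrix(counts))
        ann = pd.DataFrame({"cluster": ["A"] * 15 + ["B"] * 15,
                            "dataset": "d"}, index=barcodes)
        assert len(marker_genes(m, ann, "A")) == 0

    def test_absent_cluster_raises(self, rng):
        m, ann = self._planted(rng, n_in=10, n_out=10)
        with pytest.raises(KeyError):
            marker_genes(m, ann, "nope")
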