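import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from regdiscord.clustering import (
    ClusterAssignment,
    NormalizedMatrix,
    annotate_clusters,
    cluster_cells,
    normalize_log_cpm,
    select_focal_cells,
    select_hvg,
)
from regdiscord.datatypes import PipelineConfig, ValidationError
from tests.conftest import random_counts
from tests.test_qc import counts_from_dense


class TestNormalize:
    def test_zero_count_maps_to_zero_and_closed_form(self):
        cm = counts_from_dense([[10], [9990]])
        norm = normalize_log_cpm(cm)
        dense = norm.dense()
        assert dense[0, 0] == pytest.approx(np.log2(11))
        cm2 = counts_from_dense([[0, 1], [5, 5]])
        assert normalize_log_cpm(cm2).dense()[0, 0] == 0.0

    def test_zero_total_cell_is_error(self):
        cm = counts_from_dense([[0, 1], [0, 1]])
        with pytest.raises(ValidationError, match="zero-total"):
            normalize_log_cpm(cm)

    def test_matches_independent_recomputation(self):
        cm = random_counts(8, 6, seed=4, max_count=30)
        dense = np.asarray(cm.values.todense(), dtype=float)
        dense = dense[:, dense.sum(axis=0) > 0]
        cm = counts_from_dense(dense.astype(int))
        norm = normalize_log_cpm(cm)
        expect = np.log2(1 + 1e4 * dense / dense.sum(axis=0, keepdims=True))
        np.testing.assert_allclose(norm.dense(), expect, rtol=1e-12)


def norm_from_dense(vals, genes=None):
    vals = np.asarray(vals, dtype=float)
    genes = genes or [f"g{i}" for i in range(vals.shape[0])]
    return NormalizedMatrix(
        values=sp.csc_matrix(vals),
        gene_ids=np.array(genes, dtype=object),
        cell_ids=np.array([f"c{j}" for j in range(vals.shape[1])], dtype=object),
    )


class TestHvg:
    def test_constant_gene_never_beats_varying(self):
        rng = np.random.default_rng(0)
        vals = np.vstack([np.full(30, 2.0), rng.gamma(2, 1, size=(5, 30))])
        norm = norm_from_dense(vals)
        chosen = select_hvg(norm, 5)
        assert "g0" not in chosen

    def test_ties_break_lexicographically(self):
        # identical genes: identical dispersion everywhere, ties resolved by id
        rng = np.random.default_rng(1)
        row = rng.gamma(2, 1, 20)
        vals = np.vstack([row] * 4)
        norm = norm_from_dense(vals, genes=["gB", "gA", "gC", "gD"])
        assert select_hvg(norm, 1) == ["gA"]
        assert sorted(select_hvg(norm, 2)) == ["gA", "gB"]

    def test_planted_high_dispersion_genes_recovered(self):
        rng = np.random.default_rng(2)
        base = rng.gamma(5, 0.2, size=(40, 200))
        # mean-matched to the base genes (mean 1) but 25x the variance, so the
        # binned z-score must isolate dispersion, not expression level
        spikes = rng.gamma(0.2, 5.0, size=(5, 200))
        vals = np.vstack([spikes, base])
        genes = [f"spike{i}" for i in range(5)] + [f"g{i}" for i in range(40)]
        norm = norm_from_dense(vals, genes=genes)
        chosen = set(select_hvg(norm, 5))
        assert chosen == {f"spike{i}" for i in range(5)}


def two_blob_norm(n_per=200, n_genes=40, shift=5.0, seed=0, permute=None):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n_genes, n_per))
    b = rng.normal(0, 1, size=(n_genes, n_per))
    b[: n_genes // 2] += shift
    vals = np.abs(np.hstack([a, b]))
    cells = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
    if permute is not None:
        vals = vals[:, permute]
        cells = [cells[i] for i in permute]
    norm = norm_from_dense(vals)
    norm.cell_ids = np.array(cells, dtype=object)
    return norm


class TestClusterCells:
    CFG = PipelineConfig(rng_seed=0, n_hvg=40, n_pcs=10)

    def test_two_separated_blobs_recovered_exactly(self):
        norm = two_blob_norm()
        assign = cluster_cells(norm, self.CFG)
        labels = assign.labels
        assert labels.nunique() == 2
        a_labels = set(labels[labels.index.str.startswith("a")])
        b_labels = set(labels[labels.index.str.startswith("b")])
        assert a_labels.isdisjoint(b_labels)
        assert len(a_labels) == len(b_labels) == 1

    def test_single_blob_is_one_cluster_at_coarse_resolution(self):
        # modularity on a featureless kNN graph always finds some cut at high
        # resolution; a homogeneous blob is recognized as one community once
        # the resolution matches the (absent) structure scale
        norm = two_blob_norm(shift=0.0, seed=3)
        cfg = PipelineConfig(rng_seed=0, n_hvg=40, n_pcs=10, cluster_resolution=0.5)
        assert cluster_cells(norm, cfg).labels.nunique() == 1

    def test_partition_invariant_to_cell_order(self):
        rng = np.random.default_rng(7)
        perm = rng.permutation(400)
        a1 = cluster_cells(two_blob_norm(), self.CFG).labels
        a2 = cluster_cells(two_blob_norm(permute=perm), self.CFG).labels
        joint = pd.crosstab(a1.sort_index(), a2.sort_index())
        # one-to-one mapping between the two labelings
        assert (joint.gt(0).sum(axis=1) == 1).all()
        assert (joint.gt(0).sum(axis=0) == 1).all()

    def test_too_few_cells_advises_smaller_k(self):
        norm = two_blob_norm(n_per=5)
        with pytest.raises(ValidationError, match="knn_k"):
            cluster_cells(norm, self.CFG)


class TestAnnotate:
    def _assignment(self, cells, label="c0"):
        return ClusterAssignment(
            labels=pd.Series([label] * len(cells), index=pd.Index(cells))
        )

    def _two_cluster(self, n=20, seed=0):
        # first half of cells express typeA markers, second half typeB
        rng = np.random.default_rng(seed)
        vals = rng.normal(1, 0.05, size=(4, 2 * n))
        vals[0, :n] += 5
        vals[1, :n] += 4
        vals[2, n:] += 5
        vals[3, n:] += 4
        norm = norm_from_dense(np.abs(vals))
        labels = pd.Series(["cA"] * n + ["cB"] * n, index=pd.Index(norm.cell_ids))
        return norm, ClusterAssignment(labels=labels)

    def test_cluster_expressing_type_a_markers_is_type_a(self):
        norm, assign = self._two_cluster()
        markers = {"typeA": ["g0", "g1"], "typeB": ["g2", "g3"]}
        out = annotate_clusters(assign, norm, markers)
        assert out.cluster_types == {"cA": "typeA", "cB": "typeB"}

    def test_exact_tie_is_unassigned(self):
        vals = np.ones((2, 10))
        norm = norm_from_dense(vals)
        assign = self._assignment(list(norm.cell_ids))
        out = annotate_clusters(assign, norm, {"A": ["g0"], "B": ["g1"]})
        assert out.cluster_types == {"c0": "unassigned"}

    def test_absent_marker_skipped_with_warning(self, caplog):
        norm, assign = self._two_cluster(seed=1)
        markers = {"typeA": ["g0", "g1", "missing"], "typeB": ["g2", "g3"]}
        with caplog.at_level("WARNING", logger="regdiscord.clustering"):
            out = annotate_clusters(assign, norm, markers)
        assert out.cluster_types["cA"] == "typeA"
        assert any("missing" in r.message for r in caplog.records)

    def test_synthetic_default_types_all_recovered(self, default_run):
        res, truth, _ = default_run
        observed = res.cells.groupby("true_type")["cell_type"].agg(
            lambda s: s.value_counts().idxmax()
        )
        assert (observed.index == observed.values).all()


class TestFocalSelection:
    def _setup(self):
        vals = np.array(
            [[1, 0, 5, 2], [3, 3, 3, 3]]  # row 0 = focal gene
        )
        cm = counts_from_dense(vals, genes=["Satb2", "g1"])
        labels = pd.Series(
            ["c0", "c0", "c1", "c1"], index=pd.Index(cm.cell_ids)
        )
        assign = ClusterAssignment(
            labels=labels, cluster_types={"c0": "upper_layer", "c1": "interneuron"}
        )
        return cm, assign

    def test_type_and_count_gates(self):
        cm, assign = self._setup()
        focal = select_focal_cells(assign, cm, "Satb2", ("upper_layer",))
        # c0: count 1 -> focal; c1: count 0 -> excluded; c2/c3 wrong type
        assert focal == {"c0"}

    def test_empty_focal_set_is_error(self):
        cm, assign = self._setup()
        with pytest.raises(ValidationError, match="focal"):
            select_focal_cells(assign, cm, "Satb2", ("astrocyte",))

    def test_missing_focal_gene_is_error(self):
        cm, assign = self._setup()
        with pytest.raises(ValidationError, match="Foo"):
            select_focal_cells(assign, cm, "Foo", ("upper_layer",))
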