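import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from regdiscord.activity import (
    BinaryActivity,
    binarize_activity,
    compute_activity,
    differential_activity,
    genotype_separation,
    rank_genes_per_cell,
    rank_matrix,
    recluster_binary,
    score_regulon_auc,
)
from regdiscord.datatypes import PipelineConfig, Regulon, ValidationError, make_cell_table
from tests.test_qc import counts_from_dense


def bruteforce_auc(ranks: dict, targets, frac):
    """Direct recovery-curve enumeration oracle."""
    g = len(ranks)
    k = math.ceil(frac * g)
    present = [t for t in targets if t in ranks]
    ys = []
    for i in range(1, k + 1):
        ys.append(sum(1 for t in present if ranks[t] <= i))
    m = len(present)
    best = []
    for i in range(1, k + 1):
        best.append(min(i, m))
    return sum(ys) / sum(best)


class TestRanking:
    def test_simple_ordering(self):
        ranks = rank_genes_per_cell(
            np.array([[5.0], [0.0], [2.0]]), ["a", "b", "c"], ["c0"], seed=0
        )
        assert ranks[:, 0].tolist() == [1, 3, 2]

    def test_tie_break_stable_across_runs_and_row_order(self):
        vals = np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 1.0]])
        r1 = rank_genes_per_cell(vals, ["a", "b", "c"], ["x", "y"], seed=3)
        r2 = rank_genes_per_cell(vals, ["a", "b", "c"], ["x", "y"], seed=3)
        np.testing.assert_array_equal(r1, r2)
        # reorder rows: ranks must follow the identifiers
        r3 = rank_genes_per_cell(vals[[1, 0, 2]], ["b", "a", "c"], ["x", "y"], seed=3)
        np.testing.assert_array_equal(r1[0], r3[1])
        np.testing.assert_array_equal(r1[1], r3[0])

    def test_agrees_with_naive_sort_for_distinct_values(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(100).reshape(20, 5).astype(float)
        ranks = rank_genes_per_cell(vals, [f"g{i}" for i in range(20)], list("abcde"), 1)
        for j in range(5):
            order = np.argsort(-vals[:, j])
            expect = np.empty(20, dtype=int)
            expect[order] = np.arange(1, 21)
            np.testing.assert_array_equal(ranks[:, j], expect)


class TestAuc:
    def _ranks(self, mapping):
        return pd.Series(mapping)

    def test_targets_at_top_give_one(self):
        ranks = self._ranks({f"g{i}": i + 1 for i in range(20)})
        reg = Regulon("tf", frozenset({"g0", "g1"}))
        assert score_regulon_auc(ranks, reg, 0.25) == 1.0

    def test_no_target_in_top_gives_zero(self):
        ranks = self._ranks({f"g{i}": i + 1 for i in range(20)})
        reg = Regulon("tf", frozenset({"g18", "g19"}))
        assert score_regulon_auc(ranks, reg, 0.25) == 0.0

    def test_worked_example_eight_ninths(self):
        ranks = self._ranks({f"g{i}": i + 1 for i in range(20)})
        reg = Regulon("tf", frozenset({"g0", "g2"}))  # ranks 1 and 3
        assert score_regulon_auc(ranks, reg, 0.25) == pytest.approx(8 / 9)

    def test_no_targets_in_matrix_is_error_naming_regulon(self):
        ranks = self._ranks({"g0": 1, "g1": 2})
        reg = Regulon("tfX", frozenset({"absent"}))
        with pytest.raises(ValidationError, match="tfX"):
            score_regulon_auc(ranks, reg, 0.5)

    @pytest.mark.parametrize("frac", [0.05, 0.1, 0.25])
    def test_matches_bruteforce_on_random_instances(self, frac):
        rng = np.random.default_rng(int(frac * 100))
        for _ in range(70):
            g = rng.integers(5, 51)
            perm = rng.permutation(g) + 1
            ranks = self._ranks({f"g{i}": int(perm[i]) for i in range(g)})
            m = rng.integers(1, min(10, g) + 1)
            targets = rng.choice(g, size=m, replace=False)
            reg = Regulon("tf", frozenset({f"g{i}" for i in targets}))
            expect = bruteforce_auc(dict(ranks), reg.targets, frac)
            assert score_regulon_auc(ranks, reg, frac) == pytest.approx(expect, abs=1e-12)


class TestBinarize:
    def test_forced_mean_threshold(self):
        act = pd.DataFrame([[0.2, 0.4, 0.6, 0.8]], index=["r"], columns=list("abcd"))
        b = binarize_activity(act)
        assert b.thresholds["r"] == pytest.approx(0.5)
        assert b.states.loc["r"].tolist() == [0, 0, 1, 1]

    def test_constant_row_all_inactive(self):
        act = pd.DataFrame([[0.3, 0.3, 0.3]], index=["r"], columns=list("abc"))
        assert binarize_activity(act).states.loc["r"].sum() == 0

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(4)
        act = pd.DataFrame(rng.random((6, 30)))
        b1 = binarize_activity(act)
        b2 = binarize_activity(act)
        pd.testing.assert_frame_equal(b1.states, b2.states)
        # raising one cell's AUC never flips it active -> inactive
        act2 = act.copy()
        act2.iloc[2, 5] += 0.2
        b3 = binarize_activity(act2)
        assert b3.states.iloc[2, 5] >= b1.states.iloc[2, 5]

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(5)
        act = pd.DataFrame(rng.random((8, 40)))
        b = binarize_activity(act)
        expect = (act.values > act.values.mean(axis=1, keepdims=True)).astype(int)
        np.testing.assert_array_equal(b.states.values, expect)


def binary_from_states(states, cell_ids):
    df = pd.DataFrame(states, columns=cell_ids)
    df.index = [f"r{i}" for i in range(len(df))]
    return BinaryActivity(states=df.astype(np.int8), thresholds=pd.Series(0.5, index=df.index))


def geno_cells(n_wt, n_ko):
    ids = [f"w{i}" for i in range(n_wt)] + [f"k{i}" for i in range(n_ko)]
    df = make_cell_table(ids, ["s"] * len(ids), ["WT"] * n_wt + ["KO"] * n_ko)
    return ids, df


class TestDifferentialActivity:
    CFG = PipelineConfig()

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        ids, cells = geno_cells(10, 10)
        states = [[1] * 9 + [0] + [1] + [0] * 9]
        b = binary_from_states(states, ids)
        out = differential_activity(b, cells, set(ids), self.CFG)
        assert out.loc[0, "pvalue"] == pytest.approx(202 / 184756, abs=1e-15)
        assert out.loc[0, "delta"] == pytest.approx(0.8)
        assert out.loc[0, "category"] == "WT_ACTIVE"

    def test_balanced_table_non_differential(self):
        ids, cells = geno_cells(100, 100)
        states = [[1] * 50 + [0] * 50 + [1] * 50 + [0] * 50]
        out = differential_activity(binary_from_states(states, ids), cells, set(ids), self.CFG)
        assert out.loc[0, "delta"] == 0.0
        assert out.loc[0, "category"] == "NON_DIFFERENTIAL"

    def test_ko_active_symmetry(self):
        ids, cells = geno_cells(100, 100)
        states = [[0] * 100 + [1] * 90 + [0] * 10]
        out = differential_activity(binary_from_states(states, ids), cells, set(ids), self.CFG)
        assert out.loc[0, "category"] == "KO_ACTIVE"

    def test_antisymmetric_under_genotype_swap(self):
        rng = np.random.default_rng(6)
        ids, cells = geno_cells(40, 60)
        states = rng.integers(0, 2, size=(5, 100))
        b = binary_from_states(states, ids)
        out1 = differential_activity(b, cells, set(ids), self.CFG)
        flipped = cells.copy()
        flipped["genotype"] = np.where(flipped["genotype"] == "WT", "KO", "WT")
        out2 = differential_activity(b, flipped, set(ids), self.CFG)
        np.testing.assert_allclose(out1["delta"], -out2["delta"], atol=1e-12)
        np.testing.assert_allclose(out1["pvalue"], out2["pvalue"], atol=1e-12)
        mirror = {"WT_ACTIVE": "KO_ACTIVE", "KO_ACTIVE": "WT_ACTIVE",
                  "NON_DIFFERENTIAL": "NON_DIFFERENTIAL"}
        assert out2["category"].tolist() == [mirror[c] for c in out1["category"]]

    def test_empty_genotype_is_error(self):
        ids, cells = geno_cells(10, 0)
        cells["genotype"] = "WT"
        b = binary_from_states([[1] * 10], ids)
        with pytest.raises(ValidationError, match="genotype"):
            differential_activity(b, cells, set(ids), self.CFG)


class TestReclusterAndSeparation:
    CFG = PipelineConfig(knn_k=5)

    def _blocks(self, n=30):
        ids, cells = geno_cells(n, n)
        states = np.zeros((6, 2 * n), dtype=int)
        states[:3, :n] = 1
        states[3:, n:] = 1
        return binary_from_states(states, ids), cells

    def test_identical_profile_blocks_split_into_components(self):
        b, cells = self._blocks()
        graph, emb = recluster_binary(b, self.CFG)
        comps = list(nx.connected_components(graph))
        assert len(comps) == 2
        assert genotype_separation(graph, cells) == pytest.approx(1.0)

    def test_graph_invariant_to_cell_permutation(self):
        b, cells = self._blocks()
        rng = np.random.default_rng(0)
        perm = rng.permutation(b.states.shape[1])
        b2 = BinaryActivity(states=b.states.iloc[:, perm], thresholds=b.thresholds)
        g1, _ = recluster_binary(b, self.CFG)
        g2, _ = recluster_binary(b2, self.CFG)
        assert set(map(frozenset, g1.edges)) == set(map(frozenset, g2.edges))

    def test_shuffled_labels_give_chance_purity(self):
        rng = np.random.default_rng(1)
        ids, cells = geno_cells(100, 100)
        states = rng.integers(0, 2, size=(12, 200))
        b = binary_from_states(states, ids)
        perm = rng.permutation(200)
        cells["genotype"] = cells["genotype"].to_numpy()[perm]
        graph, _ = recluster_binary(b, PipelineConfig(knn_k=20))
        score = genotype_separation(graph, cells)
        assert 0.45 <= score <= 0.55
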