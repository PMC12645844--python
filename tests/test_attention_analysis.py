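"""Attention-derived networks, hub/attractor/core genes, differential attention."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from survformer.attention_analysis import (
    aggregate_attention_scores,
    build_network,
    core_genes,
    differential_attention,
    enrichment,
    find_hub_attractor,
    selection_counts,
)
from survformer.io_preprocess import GeneSetCollection
from survformer.synthetic_data import generate_attention_fixture


def toy_tensor(weights: np.ndarray) -> np.ndarray:
    """Wrap a (n, n) weight matrix as a 1-layer, 1-head attention tensor."""
    return weights[None, None, :, :]


class TestBuildNetwork:
    def test_three_gene_toy_counts_edges(self):
        w = np.array([[0.0, 0.5, 0.009], [0.02, 0.0, 0.0], [0.0, 0.0, 0.0]])
        net = build_network(toy_tensor(w), ["A", "B", "C"], threshold=0.01)
        # weights {0.5, 0.009, 0.02}: exactly 2 edges exceed 0.01
        assert net.graph.number_of_edges() == 2
        assert net.graph.has_edge("B", "A")  # key B -> query A, weight 0.5
        assert net.graph.has_edge("A", "B")
        assert net.graph["B"]["A"]["weight"] == pytest.approx(0.5)

    def test_uniform_weights_below_threshold_give_no_edges(self):
        n = 200
        w = np.full((n, n), 1.0 / n)  # 0.005 < 0.01
        net = build_network(toy_tensor(w), [f"G{i}" for i in range(n)])
        assert net.graph.number_of_edges() == 0

    def test_self_edges_excluded_by_default(self):
        w = np.array([[1.0]])
        net = build_network(toy_tensor(w), ["A"])
        assert net.graph.number_of_edges() == 0
        net_incl = build_network(toy_tensor(w), ["A"], include_self=True)
        assert net_incl.graph.has_edge("A", "A")

    def test_heads_union_by_max_weight(self):
        attn = np.zeros((1, 2, 2, 2))
        attn[0, 0, 0, 1] = 0.3
        attn[0, 1, 0, 1] = 0.7
        net = build_network(attn, ["A", "B"])
        assert net.graph["B"]["A"]["weight"] == pytest.approx(0.7)

    def test_edge_count_nonincreasing_in_threshold(self, rng):
        attn = rng.dirichlet(np.ones(10), size=(2, 3, 10)).reshape(2, 3, 10, 10)
        genes = [f"G{i}" for i in range(10)]
        counts = [
            build_network(attn, genes, threshold=t).graph.number_of_edges()
            for t in (0.001, 0.01, 0.05, 0.2)
        ]
        assert counts == sorted(counts, reverse=True)


class TestHubAttractor:
    def test_star_center_is_unique_hub(self):
        n = 51
        genes = [f"G{i}" for i in range(n)]
        w = np.zeros((n, n))
        w[1:, 0] = 0.5  # every query attends to key 0: edges 0 -> i (out-degree 50)
        net = build_network(toy_tensor(w), genes)
        hubs, attractors, stats = find_hub_attractor(net)
        assert hubs == {"G0"}
        assert stats.mu_out == pytest.approx(50 / 51)

    def test_reversed_star_center_is_unique_attractor(self):
        n = 51
        genes = [f"G{i}" for i in range(n)]
        w = np.zeros((n, n))
        w[0, 1:] = 0.5  # query 0 attends to all keys: edges i -> 0 (in-degree 50)
        net = build_network(toy_tensor(w), genes)
        hubs, attractors, _ = find_hub_attractor(net)
        assert attractors == {"G0"}

    def test_regular_graph_has_no_hubs(self):
        n = 6
        w = np.full((n, n), 0.5)
        np.fill_diagonal(w, 0.0)
        net = build_network(toy_tensor(w), [f"G{i}" for i in range(n)])
        hubs, attractors, stats = find_hub_attractor(net)
        assert stats.sd_out == 0.0
        assert hubs == set() and attractors == set()  # strict inequality

    def test_agrees_with_brute_force_degrees(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 15))
            w = rng.random((n, n)) * 0.05
            genes = [f"G{i}" for i in range(n)]
            net = build_network(toy_tensor(w), genes, threshold=0.01)
            out_deg = {g: 0 for g in genes}
            in_deg = {g: 0 for g in genes}
            for i in range(n):
                for j in range(n):
                    if i != j and w[i, j] > 0.01:
                        out_deg[genes[j]] += 1  # key j gains an out-edge
                        in_deg[genes[i]] += 1
            od = np.array([out_deg[g] for g in genes], dtype=float)
            idg = np.array([in_deg[g] for g in genes], dtype=float)
            hubs, attractors, _ = find_hub_attractor(net)
            assert hubs == {g for g, d in zip(genes, od) if d > od.mean() + 2 * od.std()}
            assert attractors == {g for g, d in zip(genes, idg) if d > idg.mean() + 2 * idg.std()}

    def test_empty_network_gives_empty_stats(self):
        net = build_network(toy_tensor(np.zeros((3, 3))), ["A", "B", "C"])
        hubs, attractors, stats = find_hub_attractor(net)
        assert hubs == set() and attractors == set()
        assert stats.mu_out == 0.0


class TestCoreGenes:
    def test_equal_proportions_never_core(self):
        genes = ["A", "B"]
        counts = pd.Series([5, 3], index=genes)
        df = core_genes(counts, 10, counts.copy(), 10)
        assert (df["core_group"] == "").all()
        assert np.allclose(df["ratio"], 1.0)

    def test_8_of_10_vs_1_of_10_matches_fisher_oracle(self):
        genes = ["A"]
        df = core_genes(pd.Series([8], index=genes), 10, pd.Series([1], index=genes), 10)
        # two-sided Fisher p by exhaustive hypergeometric enumeration
        table_p = hypergeom.pmf(np.arange(0, 10), 20, 9, 10)
        observed = hypergeom.pmf(8, 20, 9, 10)
        p_expected = table_p[table_p <= observed + 1e-12].sum()
        assert df["p"].iloc[0] == pytest.approx(p_expected, rel=1e-6)
        assert df["p_adj"].iloc[0] < 0.05
        assert df["core_group"].iloc[0] == "A"
        assert df["ratio"].iloc[0] > 2

    def test_gene_selected_nowhere_excluded(self):
        genes = ["A", "B"]
        df = core_genes(pd.Series([0, 4], index=genes), 10, pd.Series([0, 1], index=genes), 10)
        assert list(df["gene"]) == ["B"]

    def test_label_swap_symmetry(self):
        genes = list("ABCD")
        ca = pd.Series([9, 2, 5, 0], index=genes)
        cb = pd.Series([1, 8, 5, 3], index=genes)
        ab = core_genes(ca, 12, cb, 15)
        ba = core_genes(cb, 15, ca, 12)
        np.testing.assert_allclose(ab["p"], ba["p"], atol=1e-12)
        swap = {"A": "B", "B": "A", "": ""}
        assert [swap[g] for g in ab["core_group"]] == list(ba["core_group"])

    def test_zero_size_group_rejected(self):
        with pytest.raises(ValueError):
            core_genes(pd.Series([1], index=["A"]), 0, pd.Series([1], index=["A"]), 5)


class TestSelectionCounts:
    def test_counts_match_membership(self):
        sel = [{"A", "B"}, {"B"}, set()]
        counts = selection_counts(sel, ["A", "B", "C"])
        assert counts.tolist() == [1, 2, 0]


class TestDifferentialAttention:
    def test_identical_tensors_flag_nothing(self):
        a, _ = generate_attention_fixture(n_samples=20, n_genes=10, seed=0)
        df = differential_attention(a, a.copy(), [f"G{i}" for i in range(10)])
        assert (df["direction"] == "").all()

    def test_planted_shift_recovered_exactly(self):
        a, b = generate_attention_fixture(n_samples=50, n_genes=20, shift_gene=7, shift_sigmas=5.0, seed=1)
        genes = [f"G{i}" for i in range(20)]
        df = differential_attention(b, a, genes)
        flagged = set(df.loc[df["direction"] == "up", "gene"])
        assert flagged == {"G7"}

    def test_bh_adjustment_never_below_raw(self):
        a, b = generate_attention_fixture(n_samples=15, n_genes=12, seed=3)
        df = differential_attention(a, b, [f"G{i}" for i in range(12)])
        assert (df["p_adj"] >= df["p"] - 1e-15).all()

    def test_too_few_samples_rejected(self):
        a, b = generate_attention_fixture(n_samples=2, n_genes=5, seed=0)
        with pytest.raises(ValueError, match="3 samples"):
            differential_attention(a, b, [f"G{i}" for i in range(5)])

    def test_aggregate_modes(self, rng):
        attn = rng.dirichlet(np.ones(6), size=(4, 2, 3, 6)).reshape(4, 2, 3, 6, 6)
        inc = aggregate_attention_scores(attn, "incoming_mean")
        out = aggregate_attention_scores(attn, "outgoing_mean")
        sym = aggregate_attention_scores(attn, "symmetric_mean")
        np.testing.assert_allclose(sym, 0.5 * (inc + out), atol=1e-12)
        # outgoing means average softmax rows: exactly 1/n per gene
        np.testing.assert_allclose(out, 1.0 / 6, atol=1e-12)


class TestEnrichment:
    def test_query_equals_universe_gives_p_one(self):
        sets = GeneSetCollection({"S": ["A", "B", "C"]})
        df = enrichment(["A", "B", "C"], sets, ["A", "B", "C"])
        assert df["p"].iloc[0] == pytest.approx(1.0)

    def test_full_containment_matches_hypergeometric_tail(self):
        universe = [f"G{i}" for i in range(100)]
        query = universe[:5]
        sets = GeneSetCollection({"S": universe[:5]})
        df = enrichment(query, sets, universe)
        expect = hypergeom.sf(4, 100, 5, 5)
        assert df["p"].iloc[0] == pytest.approx(expect, rel=1e-9)

    def test_disjoint_overlap_zero_p_one(self):
        universe = [f"G{i}" for i in range(20)]
        sets = GeneSetCollection({"S": universe[10:]})
        df = enrichment(universe[:5], sets, universe)
        assert df["overlap"].iloc[0] == 0
        assert df["p"].iloc[0] == pytest.approx(1.0)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            enrichment([], GeneSetCollection({"S": ["A"]}), ["A"])
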