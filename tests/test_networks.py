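"""Networks: co-expression construction, aggregation, PPI extension, degrees."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from convergetrend.networks import (
    WeightedGeneNetwork,
    aggregate_networks,
    assortativity,
    build_coexpression_network,
    degree_profile,
    extend_ppi,
    read_edge_list,
)


def _toy_network():
    nodes = ("a", "b", "c", "d", "e")
    w = np.zeros((5, 5))
    pairs = {(0, 1): 1.0, (0, 2): 0.5, (1, 2): 0.25, (2, 3): 2.0, (3, 4): 0.75}
    for (i, j), v in pairs.items():
        w[i, j] = w[j, i] = v
    return WeightedGeneNetwork(nodes, w)


class TestCoexpression:
    def test_identical_profiles_get_max_weight(self):
        expr = pd.DataFrame(
            [[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]],
            index=["a", "b", "c"],
        )
        net = build_coexpression_network(expr)
        assert net.weight("a", "b") == pytest.approx(1.0)

    def test_matches_rank_standardized_spearman_oracle(self, rng):
        expr = pd.DataFrame(rng.normal(size=(4, 5)), index=list("abcd"))
        net = build_coexpression_network(expr)
        corr = np.round(stats.spearmanr(expr.to_numpy().T).statistic, 12)
        iu, ju = np.triu_indices(4, k=1)
        expected = stats.rankdata(corr[iu, ju]) / iu.size
        got = np.array([net.weights[i, j] for i, j in zip(iu, ju)])
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_constant_gene_edges_share_one_mid_rank(self):
        expr = pd.DataFrame(
            [[1, 2, 3, 4], [4, 2, 1, 3], [5, 5, 5, 5], [1, 3, 2, 4]],
            index=list("abcd"),
        )
        net = build_coexpression_network(expr)
        c_edges = [net.weight("c", g) for g in "abd"]
        assert len(set(np.round(c_edges, 12))) == 1

    def test_too_few_samples_rejected(self):
        expr = pd.DataFrame([[1, 2], [3, 4]], index=["a", "b"])
        with pytest.raises(ValueError, match="3 samples"):
            build_coexpression_network(expr)

    def test_nan_rejected(self):
        expr = pd.DataFrame([[1, 2, np.nan], [3, 4, 5]], index=["a", "b"])
        with pytest.raises(ValueError, match="NaN"):
            build_coexpression_network(expr)


class TestAggregation:
    def test_identity_and_idempotence(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 6)), index=list("abcde"))
        net = build_coexpression_network(expr)
        single = aggregate_networks([net])
        doubled = aggregate_networks([net, net])
        np.testing.assert_allclose(single.weights, net.weights, atol=1e-12)
        np.testing.assert_allclose(doubled.weights, net.weights, atol=1e-12)

    def test_permutation_invariance(self, rng):
        nets = [
            build_coexpression_network(
                pd.DataFrame(rng.normal(size=(5, 6)), index=list("abcde"))
            )
            for _ in range(3)
        ]
        a = aggregate_networks(nets)
        b = aggregate_networks(nets[::-1])
        np.testing.assert_allclose(a.weights, b.weights, atol=1e-12)

    def test_mean_then_rerank_oracle(self):
        nodes = ("a", "b", "c", "d")

        def from_upper(vals):
            w = np.zeros((4, 4))
            iu, ju = np.triu_indices(4, k=1)
            w[iu, ju] = vals
            return WeightedGeneNetwork(nodes, w + w.T)

        n1 = from_upper(stats.rankdata([3, 1, 2, 6, 5, 4]) / 6)
        n2 = from_upper(stats.rankdata([1, 2, 3, 4, 5, 6]) / 6)
        agg = aggregate_networks([n1, n2])
        iu, ju = np.triu_indices(4, k=1)
        mean = (n1.weights[iu, ju] + n2.weights[iu, ju]) / 2
        np.testing.assert_allclose(
            agg.weights[iu, ju], stats.rankdata(mean) / 6, atol=1e-12
        )

    def test_node_mismatch_rejected(self):
        a = WeightedGeneNetwork(("a", "b"), np.zeros((2, 2)))
        b = WeightedGeneNetwork(("a", "c"), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="node list"):
            aggregate_networks([a, b])


class TestExtendPpi:
    def test_path_graph_inverse_distances(self):
        net = extend_ppi([("A", "B"), ("B", "C"), ("C", "D")])
        assert net.weight("A", "B") == 1.0
        assert net.weight("A", "C") == 0.5
        assert net.weight("A", "D") == pytest.approx(1 / 3)

    def test_disconnected_and_beyond_cutoff_zero(self):
        chain = [(f"n{i}", f"n{i+1}") for i in range(7)] + [("x", "y")]
        net = extend_ppi(chain, max_hops=6)
        assert net.weight("n0", "n7") == 0.0  # distance 7 > cutoff
        assert net.weight("n0", "x") == 0.0  # disconnected

    def test_matches_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            g = nx.gnp_random_graph(20, 0.12, seed=int(rng.integers(1 << 30)))
            edges = [(f"v{a}", f"v{b}") for a, b in g.edges]
            if not edges:
                continue
            net = extend_ppi(edges, max_hops=6)
            lengths = dict(nx.all_pairs_shortest_path_length(g))
            for i, j in itertools.combinations(range(20), 2):
                a, b = f"v{i}", f"v{j}"
                if a not in net or b not in net:
                    continue
                d = lengths.get(i, {}).get(j)
                expected = 1.0 / d if d is not None and d <= 6 else 0.0
                assert net.weight(a, b) == pytest.approx(expected)

    def test_weight_value_set(self):
        rng = np.random.default_rng(1)
        g = nx.gnp_random_graph(25, 0.1, seed=5)
        net = extend_ppi([(f"v{a}", f"v{b}") for a, b in g.edges], max_hops=4)
        allowed = {0.0} | {1.0 / k for k in range(1, 5)}
        assert {round(float(v), 12) for v in np.unique(net.weights)} <= {
            round(v, 12) for v in allowed
        }

    def test_hop_one_recovers_input_edges(self):
        edges = {("A", "B"), ("B", "C"), ("A", "D")}
        net = extend_ppi(sorted(edges), max_hops=1)
        nonzero = {
            tuple(sorted((net.nodes[i], net.nodes[j])))
            for i, j in zip(*np.nonzero(np.triu(net.weights)))
        }
        assert nonzero == {tuple(sorted(e)) for e in edges}


class TestDegreeProfile:
    def test_singleton_internal_zero(self):
        prof = degree_profile(_toy_network(), {"a"})
        assert prof.internal_degree[0] == 0.0

    def test_full_set_internal_equals_global(self):
        net = _toy_network()
        prof = degree_profile(net, set(net.nodes))
        np.testing.assert_allclose(prof.internal_degree, prof.global_degree)

    def test_hand_computed_profile(self):
        prof = degree_profile(_toy_network(), {"a", "b", "c"})
        # genes ordered a, b, c
        np.testing.assert_allclose(prof.global_degree, [1.5, 1.25, 2.75])
        np.testing.assert_allclose(prof.internal_degree, [1.5, 1.25, 0.75])

    def test_internal_monotone_under_growth(self, rng):
        net = _toy_network()
        small = degree_profile(net, {"a", "b"})
        large = degree_profile(net, {"a", "b", "c", "d"})
        for g, v in zip(small.genes, small.internal_degree):
            idx = large.genes.index(g)
            assert large.internal_degree[idx] >= v - 1e-12

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="intersect"):
            degree_profile(_toy_network(), {"zz"})


class TestAssortativity:
    def test_star_graph_fully_disassortative(self):
        net = extend_ppi([("h", "a"), ("h", "b"), ("h", "c")], max_hops=1)
        assert assortativity(net) == pytest.approx(-1.0)

    def test_matches_networkx_on_random_graph(self):
        g = nx.gnp_random_graph(30, 0.15, seed=2)
        net = extend_ppi([(f"v{a}", f"v{b}") for a, b in g.edges], max_hops=1)
        expected = nx.degree_assortativity_coefficient(g)
        assert assortativity(net) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "edges",
        [
            [("a", "b"), ("b", "c"), ("c", "a")],  # cycle: regular
            [("a", "b"), ("c", "d")],  # disjoint edges: all degree 1
        ],
    )
    def test_degenerate_graphs_flagged_not_crashed(self, edges):
        net = extend_ppi(edges, max_hops=1)
        assert np.isnan(assortativity(net))


class TestIO:
    def test_edge_list_round_trip(self, tmp_path, rng):
        net = _toy_network()
        path = tmp_path / "edges.tsv"
        net.to_edge_list(path)
        back = read_edge_list(path)
        assert back.nodes == net.nodes
        np.testing.assert_allclose(back.weights, net.weights)

    def test_symmetry_validation(self):
        w = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            WeightedGeneNetwork(("a", "b"), w)
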