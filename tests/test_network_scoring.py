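import math

import networkx as nx
import numpy as np
import pytest

from ksp.network_scoring import (
    BetaVector,
    UnknownNodeError,
    build_affinity_graph,
    build_integrated_network,
    ks_terms,
    ksp_score,
    load_affinity_graph,
    load_network,
    punitive_factor,
    rank_kinases_network,
    save_affinity_graph,
    save_network,
)
from ksp.io_formats import PPIEdge

from .conftest import (
    literal_sum_oracle,
    make_pair,
    make_site,
    net_from_edges,
    random_connected_net,
    simple_path_oracle,
)


class TestBetaVector:
    def test_default_matches_printed_values(self):
        assert BetaVector().as_tuple() == (0.25, 0.225, 0.1875, 0.1875)

    def test_default_sum_is_085_and_not_renormalized(self):
        # the stated default is used verbatim even though it sums to 0.85
        assert math.isclose(sum(BetaVector().as_tuple()), 0.85)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            BetaVector(-0.1, 0.2, 0.3, 0.4)

    def test_from_string(self):
        assert BetaVector.from_string("1,0,0,0").as_tuple() == (1, 0, 0, 0)

    def test_normalized(self):
        assert math.isclose(sum(BetaVector().normalized().as_tuple()), 1.0)


class TestBuildIntegratedNetwork:
    def test_largest_component_kept(self):
        pairs = [make_pair("K1", "P1")]
        ppi = [PPIEdge("P1", "P2"), PPIEdge("P3", "P4")]
        net = build_integrated_network(pairs, ppi)
        assert net.nodes == {"K1", "P1", "P2"}

    def test_component_tie_broken_by_smallest_node(self):
        # two components of equal size: {A, B} and {K1, P1}
        pairs = [make_pair("K1", "P1")]
        ppi = [PPIEdge("A", "B")]
        net = build_integrated_network(pairs, ppi)
        assert net.nodes == {"A", "B"}

    def test_kinase_appearing_as_substrate_still_flagged_kinase(self):
        pairs = [make_pair("K1", "P1"), make_pair("K2", "K1", position=25)]
        net = build_integrated_network(pairs, [])
        assert "K1" in net.kinases
        assert net.proteins == {"P1"}

    def test_ks_edge_weight_counts_distinct_sites(self):
        pairs = [
            make_pair("K1", "P1", 10),
            make_pair("K1", "P1", 25, "CCCCCCCSDDDDDDD"),
            make_pair("K1", "P1", 40, "EEEEEEETFFFFFFF"),
        ]
        net = build_integrated_network(pairs, [])
        assert net.weight("K1", "P1") == 3.0

    def test_duplicate_position_not_double_counted(self):
        pairs = [make_pair("K1", "P1", 10), make_pair("K1", "P1", 10)]
        net = build_integrated_network(pairs, [])
        assert net.weight("K1", "P1") == 1.0

    def test_ks_and_ppi_support_takes_max(self):
        pairs = [make_pair("K1", "P1", 10), make_pair("K1", "P1", 25)]
        net = build_integrated_network(pairs, [PPIEdge("K1", "P1")])
        assert net.weight("K1", "P1") == 2.0

    def test_empty_inputs_hard_error(self):
        with pytest.raises(ValueError):
            build_integrated_network([], [])


class TestPunitiveFactor:
    def test_degree_le_2_returns_one(self):
        net = net_from_edges([("a", "b", 1), ("b", "c", 1)])
        assert punitive_factor(net, "a") == 1.0  # degree 1
        assert punitive_factor(net, "b") == 1.0  # degree 2

    def test_max_degree_node_gets_08(self):
        star = [("hub", f"leaf{i}", 1) for i in range(5)]
        net = net_from_edges(star)
        assert punitive_factor(net, "hub") == pytest.approx(0.8)

    def test_mid_degree_value(self):
        # construction with min degree 2, max degree 8 and a degree-4 node:
        # hub H linked to 8 nodes of a 10-cycle; one extra edge raises c0
        # to degree 4. p_d(c0) = 1 - 0.2*(log2 4 - log2 2)/(log2 8 - log2 2)
        edges = [(f"c{i}", f"c{(i + 1) % 10}", 1) for i in range(10)]
        edges += [("H", f"c{i}", 1) for i in range(8)]
        edges += [("c0", "c5", 1)]
        net = net_from_edges(edges)
        degrees = sorted({net.degree(v) for v in net.nodes})
        assert degrees[0] == 2 and degrees[-1] == 8
        assert net.degree("c0") == 4
        assert punitive_factor(net, "c0") == pytest.approx(0.9)

    def test_uniform_degree_network_degenerates_to_one(self):
        k5 = [(f"v{i}", f"v{j}", 1) for i in range(5) for j in range(i + 1, 5)]
        net = net_from_edges(k5)  # every degree is 4
        assert all(punitive_factor(net, v) == 1.0 for v in net.nodes)

    def test_image_and_monotonicity(self, rng):
        for _ in range(20):
            net = random_connected_net(rng)
            values = {v: punitive_factor(net, v) for v in net.nodes}
            assert all(0.8 <= p <= 1.0 for p in values.values())
            over2 = sorted(
                (net.degree(v), values[v]) for v in net.nodes if net.degree(v) > 2
            )
            for (d1, p1), (d2, p2) in zip(over2, over2[1:]):
                assert d1 > d2 or p1 >= p2 - 1e-12


class TestKsTerms:
    def test_direct_edge_only(self):
        net = net_from_edges([("k", "n", 3)])
        assert ks_terms(net, "k", "n") == (3.0, 0.0, 0.0, 0.0)

    def test_common_neighbor(self):
        net = net_from_edges([("k", "v", 2), ("v", "n", 5)])
        assert ks_terms(net, "k", "n") == (0.0, 10.0, 0.0, 0.0)

    def test_length3_path_simple(self):
        net = net_from_edges([("k", "a", 2), ("a", "b", 3), ("b", "n", 5)])
        assert ks_terms(net, "k", "n", mode="simple") == (0.0, 0.0, 30.0, 0.0)

    def test_length4_path_simple(self):
        net = net_from_edges(
            [("k", "a", 1), ("a", "c", 1), ("c", "b", 1), ("b", "n", 1)]
        )
        assert ks_terms(net, "k", "n", mode="simple") == (0.0, 0.0, 0.0, 1.0)

    def test_unknown_node(self):
        net = net_from_edges([("k", "n", 1)])
        with pytest.raises(UnknownNodeError):
            ks_terms(net, "k", "zzz")

    def test_same_node_rejected(self):
        net = net_from_edges([("k", "n", 1)])
        with pytest.raises(ValueError):
            ks_terms(net, "k", "k")

    def test_simple_mode_matches_path_oracle(self, rng):
        for _ in range(60):
            net = random_connected_net(rng)
            nodes = sorted(net.nodes)
            k, n = rng.choice(len(nodes), size=2, replace=False)
            k, n = nodes[int(k)], nodes[int(n)]
            assert ks_terms(net, k, n, mode="simple") == simple_path_oracle(
                net.graph, k, n
            )

    def test_literal_mode_matches_printed_sums(self, rng):
        for _ in range(60):
            net = random_connected_net(rng)
            nodes = sorted(net.nodes)
            k, n = rng.choice(len(nodes), size=2, replace=False)
            k, n = nodes[int(k)], nodes[int(n)]
            assert ks_terms(net, k, n, mode="literal") == pytest.approx(
                literal_sum_oracle(net.graph, k, n)
            )

    def test_simple_mode_is_symmetric(self, rng):
        for _ in range(20):
            net = random_connected_net(rng)
            nodes = sorted(net.nodes)
            k, n = rng.choice(len(nodes), size=2, replace=False)
            k, n = nodes[int(k)], nodes[int(n)]
            assert ks_terms(net, k, n) == ks_terms(net, n, k)

    def test_homogeneity_in_edge_weights(self, rng):
        # scaling all weights by c scales KS_l by c^(l+1)
        net = random_connected_net(rng)
        nodes = sorted(net.nodes)
        k, n = nodes[0], nodes[-1]
        base = ks_terms(net, k, n)
        c = 2.0
        g2 = net.graph.copy()
        for u, v in g2.edges:
            g2[u][v]["weight"] *= c
        from ksp.network_scoring import IntegratedNetwork

        net2 = IntegratedNetwork(g2, kinases=set())
        scaled = ks_terms(net2, k, n)
        for l, (a, b) in enumerate(zip(base, scaled)):
            assert b == pytest.approx(a * c ** (l + 1))


class TestKspScore:
    def test_two_node_default_beta(self):
        net = net_from_edges([("k", "n", 1)], kinases={"k"})
        assert ksp_score(net, "k", "n") == pytest.approx(0.25)

    def test_zero_terms_give_zero(self):
        # k and n farther than 4 edges apart
        chain = [(f"v{i}", f"v{i+1}", 1) for i in range(6)]
        net = net_from_edges(chain, kinases={"v0"})
        assert ksp_score(net, "v0", "v6") == 0.0

    def test_matches_oracle_with_punitive_factor(self, rng):
        beta = BetaVector()
        for _ in range(30):
            net = random_connected_net(rng)
            nodes = sorted(net.nodes)
            k, n = rng.choice(len(nodes), size=2, replace=False)
            k, n = nodes[int(k)], nodes[int(n)]
            oracle = simple_path_oracle(net.graph, k, n)
            expected = sum(
                b * t for b, t in zip(beta.as_tuple(), oracle)
            ) * punitive_factor(net, k)
            assert ksp_score(net, k, n, beta) == pytest.approx(expected)

    def test_non_negative(self, rng):
        for _ in range(20):
            net = random_connected_net(rng)
            nodes = sorted(net.nodes)
            k, n = nodes[0], nodes[-1]
            assert ksp_score(net, k, n) >= 0.0


class TestAffinityGraph:
    def test_two_node_graph(self):
        net = net_from_edges([("k", "n", 1)], kinases={"k"})
        graph = build_affinity_graph(net)
        assert graph.weights == {("k", "n"): pytest.approx(0.25)}

    def test_zero_scores_excluded(self):
        chain = [(f"v{i}", f"v{i+1}", 1) for i in range(6)]
        net = net_from_edges(chain, kinases={"v0"})
        graph = build_affinity_graph(net)
        assert ("v0", "v6") not in graph.weights
        assert ("v0", "v1") in graph.weights

    def test_edge_count_bound(self, rng):
        net = random_connected_net(rng)
        nodes = sorted(net.nodes)
        net.kinases = frozenset(nodes[:2])
        graph = build_affinity_graph(net)
        assert len(graph.weights) <= len(graph.kinases) * len(graph.proteins)

    def test_round_trip(self, tmp_path):
        net = net_from_edges(
            [("k", "n", 1), ("n", "p", 2)], kinases={"k"}
        )
        graph = build_affinity_graph(net)
        save_affinity_graph(graph, tmp_path / "aff.tsv")
        back = load_affinity_graph(tmp_path / "aff.tsv")
        assert back.weights == graph.weights


class TestRankKinasesNetwork:
    def make_graph(self, weights):
        from ksp.network_scoring import KinaseAffinityGraph

        kinases = frozenset(k for k, _ in weights)
        proteins = frozenset(p for _, p in weights)
        return KinaseAffinityGraph(kinases, proteins, dict(weights))

    def test_descending_order(self):
        graph = self.make_graph({("K1", "P1"): 0.5, ("K2", "P1"): 0.2})
        ranked = rank_kinases_network(graph, make_site("P1"), top_k=10)
        assert ranked == [("K1", 0.5), ("K2", 0.2)]

    def test_ties_broken_lexicographically(self):
        graph = self.make_graph({("KB", "P1"): 0.3, ("KA", "P1"): 0.3})
        ranked = rank_kinases_network(graph, make_site("P1"), top_k=10)
        assert [k for k, _ in ranked] == ["KA", "KB"]

    def test_top_k_truncation(self):
        weights = {(f"K{i:02d}", "P1"): float(i) for i in range(1, 15)}
        graph = self.make_graph(weights)
        assert len(rank_kinases_network(graph, make_site("P1"), top_k=10)) == 10

    def test_missing_substrate_warns_and_returns_empty(self):
        graph = self.make_graph({("K1", "P1"): 0.5})
        with pytest.warns(UserWarning, match="not in the affinity graph"):
            ranked = rank_kinases_network(graph, make_site("P9"), top_k=10)
        assert ranked == []

    def test_deterministic(self):
        graph = self.make_graph({("K1", "P1"): 0.5, ("K2", "P1"): 0.2})
        site = make_site("P1")
        assert rank_kinases_network(graph, site, 10) == rank_kinases_network(
            graph, site, 10
        )


class TestNetworkPersistence:
    def test_round_trip(self, tmp_path):
        pairs = [make_pair("K1", "P1", 10), make_pair("K1", "P1", 25)]
        net = build_integrated_network(pairs, [PPIEdge("P1", "P2")])
        save_network(net, tmp_path)
        back = load_network(tmp_path)
        assert back.nodes == net.nodes
        assert back.kinases == net.kinases
        assert nx.utils.graphs_equal(back.graph, net.graph)
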