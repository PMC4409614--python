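"""Centrality measures: hand-derived cases, oracle equivalence, invariants."""

from __future__ import annotations

import numpy as np
import pytest

from agonet.centrality import (
    MEASURE_COLUMNS,
    betweenness,
    centrality_table,
    closeness,
    degree,
)
from agonet.events import AgeLevel, PenRoster
from agonet.network import PenNetwork, build_network, undirected_projection
from conftest import adjacency_lengths, make_event, random_network
from oracles import brute_betweenness, brute_closeness, reverse_adj


def net_from_edges(edges, nodes, directed=True):
    net = PenNetwork("P1", AgeLevel.WEANED, nodes, directed=directed)
    for u, v, half in edges:
        net.add_half_weight(u, v, half)
    return net


def scale_weights(net: PenNetwork, factor: int) -> PenNetwork:
    out = PenNetwork(net.pen_id, net.age_level, net.nodes, directed=net.directed)
    for u, v, w in net.edges():
        out.add_half_weight(u, v, int(2 * w) * factor)
    return out


class TestDegree:
    def test_two_victims_one_attacker(self, small_roster):
        net = build_network([make_event("A", "B"), make_event("A", "C")], small_roster)
        assert degree(net, "out")["A"] == 2
        assert degree(net, "in")["A"] == 0
        assert degree(net, "in")["B"] == 1

    def test_standoff_contributes_half_per_direction(self, small_roster):
        events = [make_event("A", "B"), make_event("B", "C", standoff=True)]
        net = build_network(events, small_roster)
        assert degree(net, "total", weighted=True)["B"] == 2.0  # 1 + 0.5 + 0.5
        assert degree(net, "total", weighted=False)["B"] == 2  # two distinct opponents

    def test_isolated_animal_is_zero_in_all_modes(self, small_network):
        for mode in ("in", "out", "total"):
            for weighted in (False, True):
                assert degree(small_network, mode, weighted)["D"] == 0.0

    def test_reciprocal_dyad_counts_one_opponent(self, small_roster):
        net = build_network([make_event("A", "B"), make_event("B", "A")], small_roster)
        assert degree(net, "total")["A"] == 1
        assert degree(net, "total", weighted=True)["A"] == 2.0

    def test_standardized_degree_divides_by_n_minus_1(self, small_network):
        raw = degree(small_network, "total")
        std = degree(small_network, "total", standardized=True)
        n = small_network.n
        for animal in raw:
            assert std[animal] == pytest.approx(raw[animal] / (n - 1))


class TestBetweenness:
    def test_directed_path_center(self):
        net = net_from_edges([("A", "B", 2), ("B", "C", 2)], ["A", "B", "C"])
        bc = betweenness(net)
        assert bc == {"A": 0.0, "B": 0.5, "C": 0.0}

    def test_complete_graph_is_zero(self):
        nodes = ["A", "B", "C", "D"]
        edges = [(u, v, 2) for u in nodes for v in nodes if u != v]
        assert set(betweenness(net_from_edges(edges, nodes)).values()) == {0.0}

    def test_uniform_weights_match_binary(self):
        rng = np.random.default_rng(5)
        nodes = [f"n{i}" for i in range(6)]
        net = PenNetwork("P1", AgeLevel.WEANED, nodes)
        for u in nodes:
            for v in nodes:
                if u != v and rng.random() < 0.4:
                    net.add_half_weight(u, v, 4)  # all weights equal (2.0)
        binary = betweenness(net, weighted=False)
        weighted = betweenness(net, weighted=True)
        for v in nodes:
            assert weighted[v] == pytest.approx(binary[v], abs=1e-12)

    def test_tiny_networks_are_all_zero(self):
        net = net_from_edges([("A", "B", 2)], ["A", "B"])
        assert betweenness(net) == {"A": 0.0, "B": 0.0}


class TestCloseness:
    def test_directed_star_out_closeness(self):
        nodes = ["c", "l1", "l2", "l3"]
        net = net_from_edges([("c", l, 2) for l in nodes[1:]], nodes)
        out = closeness(net, "out")
        assert out["c"] == pytest.approx(1.0)
        assert out["l1"] == 0.0
        inn = closeness(net, "in")
        assert inn["c"] == 0.0
        assert inn["l1"] == pytest.approx((1 / 3) * 1.0)

    def test_two_nodes_weighted_edge_exceeds_one(self):
        net = net_from_edges([("A", "B", 4)], ["A", "B"])  # weight 2 -> length 0.5
        assert closeness(net, "out", weighted=True)["A"] == pytest.approx(2.0)

    def test_component_scaling_single_edge(self):
        net = net_from_edges([("A", "B", 2)], ["A", "B", "C", "D"])
        assert closeness(net, "out")["A"] == pytest.approx(1 / 3)

    def test_isolated_node_is_zero(self, small_network):
        for direction in ("in", "out", "undirected"):
            assert closeness(small_network, direction)["D"] == 0.0

    def test_scaling_off_reproduces_unscaled_ratio(self):
        net = net_from_edges([("A", "B", 2)], ["A", "B", "C", "D"])
        assert closeness(net, "out", scaling="off")["A"] == pytest.approx(1.0)


class TestOracleEquivalence:
    """Random small networks against explicit path enumeration and networkx."""

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_brute_force(self, weighted):
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(2, 8))
            net = random_network(rng, n, edge_p=0.4)
            adj = adjacency_lengths(net, weighted)
            bc = betweenness(net, weighted=weighted)
            expected_bc = brute_betweenness(list(net.nodes), adj)
            out = closeness(net, "out", weighted=weighted)
            expected_out = brute_closeness(list(net.nodes), adj)
            inn = closeness(net, "in", weighted=weighted)
            expected_in = brute_closeness(list(net.nodes), reverse_adj(adj))
            for v in net.nodes:
                assert bc[v] == pytest.approx(expected_bc[v], abs=1e-9)
                assert out[v] == pytest.approx(expected_out[v], abs=1e-9)
                assert inn[v] == pytest.approx(expected_in[v], abs=1e-9)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_networkx(self, weighted):
        # dyadic weights keep all path-length sums exact in floats, so the
        # package's tolerance-based tie rule and networkx's exact-equality
        # rule recognize the same tied shortest paths
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(3, 10))
            net = PenNetwork("R", AgeLevel.WEANED, [f"n{i}" for i in range(n)])
            for u in net.nodes:
                for v in net.nodes:
                    if u != v and rng.random() < 0.35:
                        net.add_half_weight(u, v, int(2 ** rng.integers(0, 4)))
            g = nx.DiGraph()
            g.add_nodes_from(net.nodes)
            for u, v, w in net.edges():
                g.add_edge(u, v, dist=1.0 / w)
            dist_attr = "dist" if weighted else None
            nx_bc = nx.betweenness_centrality(g, normalized=True, weight=dist_attr)
            nx_in = nx.closeness_centrality(g, distance=dist_attr)
            nx_out = nx.closeness_centrality(g.reverse(), distance=dist_attr)
            bc = betweenness(net, weighted=weighted)
            inn = closeness(net, "in", weighted=weighted)
            out = closeness(net, "out", weighted=weighted)
            for v in net.nodes:
                assert bc[v] == pytest.approx(nx_bc[v], abs=1e-9)
                assert inn[v] == pytest.approx(nx_in[v], abs=1e-9)
                assert out[v] == pytest.approx(nx_out[v], abs=1e-9)


class TestInvariants:
    def test_degree_conservation(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            net = random_network(rng, int(rng.integers(3, 9)), edge_p=0.5)
            win = degree(net, "in", weighted=True)
            wout = degree(net, "out", weighted=True)
            assert sum(win.values()) == pytest.approx(net.total_weight)
            assert sum(wout.values()) == pytest.approx(net.total_weight)

    def test_adding_an_edge_never_decreases_binary_degree(self):
        rng = np.random.default_rng(13)
        net = random_network(rng, 6, edge_p=0.3)
        before = degree(net, "total")
        free = [
            (u, v)
            for u in net.nodes
            for v in net.nodes
            if u != v and net.half_weight(u, v) == 0
        ]
        u, v = free[0]
        net.add_half_weight(u, v, 2)
        after = degree(net, "total")
        assert all(after[x] >= before[x] for x in net.nodes)

    def test_weight_scaling_leaves_binary_fixed_and_scales_weighted_closeness(self):
        rng = np.random.default_rng(17)
        net = random_network(rng, 6, edge_p=0.5)
        doubled = scale_weights(net, 2)
        assert betweenness(net) == betweenness(doubled)
        assert degree(net, "total") == degree(doubled, "total")
        c1 = closeness(net, "out", weighted=True)
        c2 = closeness(doubled, "out", weighted=True)
        for v in net.nodes:
            assert c2[v] == pytest.approx(2 * c1[v])

    def test_binary_measures_normalized_to_unit_interval(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            net = random_network(rng, int(rng.integers(2, 10)), edge_p=rng.uniform(0.1, 0.9))
            for vals in (
                betweenness(net),
                closeness(net, "in"),
                closeness(net, "out"),
                closeness(net, "undirected"),
            ):
                assert all(0.0 <= x <= 1.0 + 1e-12 for x in vals.values())


class TestCentralityTable:
    def test_one_row_per_animal_with_all_measures(self, small_network):
        tab = centrality_table([small_network])
        assert len(tab) == 4
        assert set(MEASURE_COLUMNS) <= set(tab.columns)
        assert (tab["n_pen"] == 4).all()

    def test_empty_network_gives_all_zero_records(self):
        roster = PenRoster("E1", AgeLevel.GILT, frozenset(["X", "Y", "Z"]))
        tab = centrality_table([build_network([], roster)])
        assert (tab[MEASURE_COLUMNS].to_numpy() == 0).all()

    def test_table_agrees_with_standalone_functions(self, small_network):
        tab = centrality_table([small_network]).set_index("animal_id")
        assert tab["out_degree_binary"].to_dict() == degree(small_network, "out")
        assert tab["betweenness_weighted"].to_dict() == pytest.approx(
            betweenness(small_network, weighted=True)
        )
        assert tab["in_closeness_binary"].to_dict() == pytest.approx(
            closeness(small_network, "in")
        )
        assert tab["closeness_weighted"].to_dict() == pytest.approx(
            closeness(small_network, "undirected", weighted=True)
        )

    def test_rows_ordered_by_level_pen_animal(self):
        rosters = [
            PenRoster("g-01", AgeLevel.GILT, frozenset(["b", "a"])),
            PenRoster("w-01", AgeLevel.WEANED, frozenset(["d", "c"])),
        ]
        tab = centrality_table([build_network([], r) for r in rosters])
        assert list(tab["animal_id"]) == ["c", "d", "a", "b"]
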