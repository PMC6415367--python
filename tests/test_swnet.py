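"""Class graphs, optimal-path selection and characteristic path length."""

import itertools

import networkx as nx
import numpy as np
import pytest

from gagnet.swnet import (
    ClassGraph,
    PathSizeError,
    build_energy_graph,
    build_length_graph,
    build_number_graph,
    characteristic_path_length,
    max_weight_simple_path,
    select_path,
)
from gagnet.topology import Species, SiteClass, SystemTopology, build_polymer

from conftest import make_observations


def _graph(edges, nodes=None, weight_type="number", scope="HA"):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for a, b, w in edges:
        g.add_edge(a, b, weight=float(w))
    all_nodes = sorted(g.nodes)
    return ClassGraph(g, weight_type, scope, all_nodes, None)


def _complete(nodes, w=1.0, weight_type="number"):
    return _graph([(a, b, w) for a, b in itertools.combinations(nodes, 2)],
                  weight_type=weight_type)


def brute_force_best_path(g, s, t):
    """Exhaustive simple-path enumeration oracle for max-weight paths."""
    best = None
    middles = [n for n in g if n not in (s, t)]
    for k in range(len(middles) + 1):
        for perm in itertools.permutations(middles, k):
            path = (s, *perm, t)
            if all(g.has_edge(path[i], path[i + 1]) for i in range(len(path) - 1)):
                w = sum(g[path[i]][path[i + 1]]["weight"]
                        for i in range(len(path) - 1))
                key = (w, -(len(path) - 1), tuple(reversed(path)))
                cand = (w, -(len(path) - 1), path)
                if best is None or (cand[0], cand[1]) > (best[0], best[1]) or (
                    (cand[0], cand[1]) == (best[0], best[1]) and path < best[2]
                ):
                    best = cand
    return None if best is None else (best[2], best[0])


class TestGraphConstruction:
    def test_length_edge_is_mean_member_distance(self):
        classes = (SiteClass("O5", "acceptor", ("O5",)),
                   SiteClass("O8", "acceptor", ("O8",)))
        mol = build_polymer(Species.HA, 1, classes)
        system = SystemTopology([mol])
        frames = np.repeat(system.template_coords[None], 3, axis=0)
        cg = build_length_graph(frames, system, "HA")
        # two single-atom classes one group-spacing apart along x
        assert cg.graph["O5"]["O8"]["weight"] == pytest.approx(4.5)

    def test_energy_edge_is_mean_absolute_energy(self, small_system):
        rows = [(0, 1, 2, 10.0, 1.8, "intra-HA", "O2H", "O8"),
                (1, 1, 2, 20.0, 1.8, "intra-HA", "O2H", "O8")]
        cg = build_energy_graph(make_observations(rows), small_system, "HA")
        assert cg.graph["O2H"]["O8"]["weight"] == pytest.approx(15.0)

    def test_number_edge_is_mean_contacts_per_frame(self, small_system):
        rows = [(t, 1, 2, 10.0, 1.8, "intra-HA", "O2H", "O8") for t in range(50)]
        cg = build_number_graph(make_observations(rows), small_system, "HA",
                                n_frames=100)
        assert cg.graph["O2H"]["O8"]["weight"] == pytest.approx(0.5)

    def test_bipartite_graph_has_only_intermolecular_edges(self, small_system,
                                                           small_traj):
        cg = build_length_graph(small_traj.coords[:5], small_system, "HA-CS")
        for a, b in cg.graph.edges:
            assert {a.split(":")[0], b.split(":")[0]} == {"HA", "CS"}
        assert cg.graph.number_of_edges() == 121

    def test_self_pairs_never_become_edges(self, small_system):
        rows = [(0, 1, 2, 10.0, 1.8, "intra-HA", "O8", "O8")]
        cg = build_energy_graph(make_observations(rows), small_system, "HA")
        assert cg.graph.number_of_edges() == 0


class TestPathSelection:
    def test_length_path_takes_the_cheap_detour(self):
        cg = _graph([("A", "B", 1), ("B", "C", 1), ("A", "C", 10)],
                    weight_type="length")
        entry = select_path(cg, "A", "C")
        assert entry.path == ("A", "B", "C")
        assert entry.weight == pytest.approx(2.0)
        assert entry.hops == 2

    def test_equal_weight_triangle_detours_for_weight(self):
        cg = _complete("ABC")
        for s, t in itertools.combinations("ABC", 2):
            assert select_path(cg, s, t).hops == 2

    def test_two_node_graph_is_a_direct_hop(self):
        for wt in ("length", "number"):
            cg = _graph([("A", "B", 2.0)], weight_type=wt)
            assert select_path(cg, "A", "B").hops == 1

    def test_path_graph_has_unique_path(self):
        cg = _graph([("A", "B", 1), ("B", "C", 1)])
        path, weight = max_weight_simple_path(cg.graph, "A", "C")
        assert path == ["A", "B", "C"]
        assert weight == pytest.approx(2.0)

    def test_disconnected_pair_is_excluded_not_an_error(self):
        cg = _graph([("A", "B", 1)], nodes=["A", "B", "C"])
        assert select_path(cg, "A", "C") is None

    def test_dp_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            nodes = [chr(65 + i) for i in range(n)]
            g = nx.Graph()
            g.add_nodes_from(nodes)
            for a, b in itertools.combinations(nodes, 2):
                if rng.random() < 0.6:
                    g.add_edge(a, b, weight=float(np.round(rng.random() * 10, 3)))
            got = max_weight_simple_path(g, nodes[0], nodes[1])
            want = brute_force_best_path(g, nodes[0], nodes[1])
            if want is None:
                assert got is None
            else:
                assert got[1] == pytest.approx(want[1])
                assert tuple(got[0]) == want[0]

    def test_branch_and_bound_agrees_with_dp(self):
        rng = np.random.default_rng(5)
        nodes = list("ABCDEFG")
        g = nx.Graph()
        for a, b in itertools.combinations(nodes, 2):
            if rng.random() < 0.7:
                g.add_edge(a, b, weight=float(rng.random()))
        dp = max_weight_simple_path(g, "A", "B")
        bnb = max_weight_simple_path(g, "A", "B", method="branch-and-bound")
        assert dp[1] == pytest.approx(bnb[1])

    def test_oversized_component_raises_with_guidance(self):
        cg = _complete("ABCDEF")
        with pytest.raises(PathSizeError, match="branch-and-bound"):
            max_weight_simple_path(cg.graph, "A", "B", node_limit=4)

    def test_bipartite_equal_weights_alternate_sides(self):
        ha = [f"HA:{i}" for i in range(3)]
        cs = [f"CS:{i}" for i in range(3)]
        g = nx.Graph()
        for a in ha:
            for b in cs:
                g.add_edge(a, b, weight=1.0)
        path, weight = max_weight_simple_path(g, ha[0], cs[0])
        assert len(path) == 6  # all nodes used when parity allows
        sides = [p.split(":")[0] for p in path]
        assert all(x != y for x, y in zip(sides, sides[1:]))
        assert weight == pytest.approx(5.0)


class TestCharacteristicPathLength:
    def test_all_direct_shortest_paths_give_unity(self):
        cg = _graph([("A", "B", 1), ("B", "C", 1), ("A", "C", 1)],
                    weight_type="length")
        assert characteristic_path_length(cg).value == pytest.approx(1.0)

    def test_three_node_length_example(self):
        cg = _graph([("A", "B", 1), ("B", "C", 1), ("A", "C", 10)],
                    weight_type="length")
        assert characteristic_path_length(cg).value == pytest.approx(4.0 / 3.0)

    def test_complete_equal_number_graph_is_near_hamiltonian(self):
        cpl4 = characteristic_path_length(_complete("ABCD"))
        assert cpl4.value == pytest.approx(3.0)
        cpl5 = characteristic_path_length(_complete("ABCDE"))
        assert cpl5.value == pytest.approx(4.0)

    def test_length_cpl_invariant_under_weight_scaling(self):
        rng = np.random.default_rng(17)
        edges = [(a, b, float(rng.random() + 0.1))
                 for a, b in itertools.combinations("ABCDEF", 2)
                 if rng.random() < 0.8]
        base = characteristic_path_length(_graph(edges, weight_type="length"))
        scaled = characteristic_path_length(
            _graph([(a, b, 7.3 * w) for a, b, w in edges], weight_type="length")
        )
        assert scaled.value == pytest.approx(base.value)
        assert [e.path for e in scaled.attributions] == \
            [e.path for e in base.attributions]

    def test_cpl_bounds_hold_on_random_graphs(self):
        rng = np.random.default_rng(23)
        for wt in ("length", "number"):
            for _ in range(10):
                n = int(rng.integers(2, 8))
                nodes = [chr(65 + i) for i in range(n)]
                edges = [(a, b, float(rng.random() + 0.05))
                         for a, b in itertools.combinations(nodes, 2)
                         if rng.random() < 0.7]
                cg = _graph(edges, nodes=nodes, weight_type=wt)
                cpl = characteristic_path_length(cg)
                if cpl.n_pairs:
                    assert 1.0 <= cpl.value <= n - 1

    def test_densification_raises_number_cpl(self):
        """Adding edges to an equal-weight graph lengthens the best simple
        paths, pushing the value toward the node count minus one."""
        nodes = list("ABCDEFG")
        chain = _graph([(a, b, 1.0) for a, b in zip(nodes, nodes[1:])])
        chords = _graph([(a, b, 1.0) for a, b in zip(nodes, nodes[1:])] +
                        [("A", "D", 1.0), ("B", "F", 1.0), ("C", "G", 1.0)])
        full = _complete(nodes)
        v1 = characteristic_path_length(chain).value
        v2 = characteristic_path_length(chords).value
        v3 = characteristic_path_length(full).value
        assert v1 < v2 < v3
        assert v3 == pytest.approx(len(nodes) - 1)

    def test_edgeless_graph_excludes_every_pair(self):
        cg = _graph([], nodes=["A", "B", "C"])
        cpl = characteristic_path_length(cg)
        assert np.isnan(cpl.value)
        assert cpl.n_pairs == 0
        assert len(cpl.excluded) == 3

    def test_bipartite_mean_runs_over_cross_pairs_only(self):
        ha = ["HA:x", "HA:y"]
        cs = ["CS:x", "CS:y"]
        g = nx.Graph()
        g.add_nodes_from(ha + cs)
        for a in ha:
            for b in cs:
                g.add_edge(a, b, weight=1.0)
        cg = ClassGraph(g, "number", "HA-CS", ha, cs)
        cpl = characteristic_path_length(cg)
        assert cpl.n_pairs == 4
        assert cpl.value == pytest.approx(3.0)  # best paths use all 4 nodes
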