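from __future__ import annotations

import json
from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhpcbn.graph_core import (
    DirectedGraph,
    GraphError,
    PartialDAG,
    d_separated,
    essential_graph,
    random_dag,
    true_node_sets,
)

from .oracles import (
    dsep_by_path_enumeration,
    equivalence_class_dags,
    essential_graph_by_enumeration,
    is_markov_blanket,
)


class TestDirectedGraph:
    def test_rejects_self_loop(self):
        with pytest.raises(GraphError):
            DirectedGraph(["A"], [("A", "A")])

    def test_rejects_cycle(self):
        with pytest.raises(GraphError):
            DirectedGraph(["A", "B"], [("A", "B"), ("B", "A")])

    def test_rejects_unknown_node(self):
        with pytest.raises(GraphError):
            DirectedGraph(["A"], [("A", "B")])

    def test_duplicate_edges_collapse(self):
        g = DirectedGraph(["A", "B"], [("A", "B"), ("A", "B")])
        assert len(g.edges) == 1

    def test_parents_children(self, spouse_graph):
        assert spouse_graph.parents("T") == {"A", "B"}
        assert spouse_graph.children("T") == {"C"}
        assert spouse_graph.neighbors("C") == {"T", "D"}

    def test_topological_order_respects_edges(self, dag_suite):
        for g in dag_suite:
            pos = {n: i for i, n in enumerate(g.topological_order())}
            assert all(pos[u] < pos[v] for u, v in g.edges)

    def test_v_structures(self, spouse_graph):
        assert spouse_graph.v_structures() == {("A", "T", "B"), ("D", "C", "T")}


class TestDSeparation:
    def test_chain_blocked_by_mediator(self, chain_abc):
        assert d_separated(chain_abc, "A", "C", {"B"})
        assert not d_separated(chain_abc, "A", "C", set())

    def test_collider_activation(self, collider_abc):
        assert d_separated(collider_abc, "A", "C", set())
        assert not d_separated(collider_abc, "A", "C", {"B"})

    def test_descendant_of_collider_activates(self):
        g = DirectedGraph("ABCD", [("A", "B"), ("C", "B"), ("B", "D")])
        assert not d_separated(g, "A", "C", {"D"})

    def test_unknown_node_raises(self, chain_abc):
        with pytest.raises(GraphError):
            d_separated(chain_abc, "A", "Z", set())

    def test_x_in_z_raises(self, chain_abc):
        with pytest.raises(GraphError):
            d_separated(chain_abc, "A", "C", {"A"})

    def test_matches_path_enumeration_oracle(self, dag_suite):
        for g in dag_suite:
            if len(g.nodes) > 8:
                continue
            for x, y in combinations(g.nodes, 2):
                others = [n for n in g.nodes if n not in (x, y)]
                for size in range(min(3, len(others)) + 1):
                    for z in combinations(others, size):
                        got = d_separated(g, x, y, set(z))
                        want = dsep_by_path_enumeration(g, x, y, set(z))
                        assert got == want, (g, x, y, z)

    def test_symmetry(self, dag_suite):
        for g in dag_suite[:8]:
            for x, y in combinations(g.nodes, 2):
                for z in ([], [n for n in g.nodes if n not in (x, y)][:2]):
                    assert d_separated(g, x, y, set(z)) == d_separated(g, y, x, set(z))


class TestTrueNodeSets:
    def test_spouse_graph(self, spouse_graph):
        ns = true_node_sets(spouse_graph, "T")
        assert ns.pc == {"A", "B", "C"}
        assert ns.spouses == {"D"}
        assert ns.mb == {"A", "B", "C", "D"}

    def test_isolated_node(self):
        g = DirectedGraph(["T", "X"], [])
        ns = true_node_sets(g, "T")
        assert ns.pc == ns.spouses == ns.mb == frozenset()

    def test_unknown_node(self, chain_abc):
        with pytest.raises(GraphError):
            true_node_sets(chain_abc, "Z")

    def test_mb_equals_pc_union_spouses(self, dag_suite):
        for g in dag_suite:
            for t in g.nodes:
                ns = true_node_sets(g, t)
                assert ns.mb == ns.pc | ns.spouses
                assert t not in ns.mb

    def test_blanket_property_under_dsep(self, dag_suite):
        for g in dag_suite:
            for t in g.nodes:
                mb = set(true_node_sets(g, t).mb)
                for x in g.nodes:
                    if x != t and x not in mb:
                        assert d_separated(g, t, x, mb)

    def test_boundary_minimality_small_graphs(self, dag_suite):
        for g in dag_suite:
            if len(g.nodes) > 8:
                continue
            for t in g.nodes:
                mb = set(true_node_sets(g, t).mb)
                assert is_markov_blanket(g, t, mb)
                for drop in mb:
                    assert not is_markov_blanket(g, t, mb - {drop})


class TestEssentialGraph:
    def test_collider_fully_compelled(self, collider_abc):
        eg = essential_graph(collider_abc)
        assert eg.directed == {("A", "B"), ("C", "B")}
        assert not eg.undirected

    def test_chain_fully_undirected(self, chain_abc):
        eg = essential_graph(chain_abc)
        assert not eg.directed
        assert eg.undirected == {frozenset("AB"), frozenset("BC")}

    def test_matches_enumeration_oracle(self, dag_suite):
        for g in dag_suite:
            if len(g.nodes) > 6 or len(g.edges) > 10:
                continue
            assert essential_graph(g) == essential_graph_by_enumeration(g)

    def test_same_skeleton_and_v_structures(self, dag_suite):
        for g in dag_suite:
            eg = essential_graph(g)
            assert eg.skeleton_edges() == g.skeleton_edges()
            for x, z, y in g.v_structures():
                assert (x, z) in eg.directed and (y, z) in eg.directed

    def test_invariant_across_equivalence_class(self, dag_suite):
        for g in dag_suite:
            if len(g.nodes) > 6 or len(g.edges) > 9:
                continue
            ref = essential_graph(g)
            for member in equivalence_class_dags(g):
                assert essential_graph(member) == ref


class TestRandomDag:
    def test_zero_edges(self):
        g = random_dag(3, 0, 2, seed=0)
        assert len(g.nodes) == 3 and not g.edges

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_deterministic(self, seed):
        a = random_dag(8, 10, 5, seed=seed)
        b = random_dag(8, 10, 5, seed=seed)
        assert a.edges == b.edges

    def test_edge_count_and_degree_cap(self):
        for seed in range(10):
            g = random_dag(12, 18, 4, seed=seed)
            assert len(g.edges) == 18
            assert max(g.degree(n) for n in g.nodes) <= 4

    def test_insulin_like_dimensions(self):
        g = random_dag(35, 52, 13, seed=7, hub_degree=13)
        assert len(g.nodes) == 35
        assert len(g.edges) == 52
        assert max(g.degree(n) for n in g.nodes) == 13

    def test_infeasible_raises(self):
        with pytest.raises(GraphError):
            random_dag(3, 4, 2, seed=0)
        with pytest.raises(GraphError):
            random_dag(10, 30, 2, seed=0)


class TestPartialDAG:
    def test_rejects_pair_in_both_sets(self):
        with pytest.raises(GraphError):
            PartialDAG("AB", [("A", "B")], [("A", "B")])

    def test_rejects_directed_cycle(self):
        with pytest.raises(GraphError):
            PartialDAG("ABC", [("A", "B"), ("B", "C"), ("C", "A")], [])

    def test_json_roundtrip(self):
        p = PartialDAG("ABC", [("A", "B")], [("B", "C")])
        assert PartialDAG.from_json(p.to_json()) == p
        doc = json.loads(p.to_json())
        assert set(doc) == {"nodes", "directed", "undirected"}

    def test_dot_marks_undirected(self):
        p = PartialDAG("AB", [], [("A", "B")])
        assert "dir=none" in p.to_dot()
        weighted = p.to_dot(edge_weights={frozenset("AB"): 0.5})
        assert "penwidth" in weighted
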