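"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the library's own algorithms: d-separation is
decided by enumerating every simple path and applying the blocking rules,
and the essential graph by enumerating every DAG in the equivalence class.
"""

from __future__ import annotations

from itertools import product

from rhpcbn.graph_core import DirectedGraph, PartialDAG


def dsep_by_path_enumeration(g: DirectedGraph, x: str, y: str, z: set[str]) -> bool:
    """d-separation decided by checking the blocking rules on every simple
    undirected path between x and y."""
    zset = set(z)
    adj: dict[str, set[str]] = {n: set() for n in g.nodes}
    for u, v in g.edges:
        adj[u].add(v)
        adj[v].add(u)

    def descendants(n: str) -> set[str]:
        out, stack = set(), [n]
        while stack:
            m = stack.pop()
            if m in out:
                continue
            out.add(m)
            stack.extend(c for (p, c) in g.edges if p == m)
        return out

    def path_active(path: list[str]) -> bool:
        for i in range(1, len(path) - 1):
            a, b, c = path[i - 1], path[i], path[i + 1]
            collider = g.has_edge(a, b) and g.has_edge(c, b)
            if collider:
                if not (descendants(b) & zset):
                    return False
            else:
                if b in zset:
                    return False
        return True

    stack: list[list[str]] = [[x]]
    while stack:
        path = stack.pop()
        last = path[-1]
        if last == y:
            if path_active(path):
                return False
            continue
        for nxt in adj[last]:
            if nxt not in path:
                stack.append(path + [nxt])
    return True


def equivalence_class_dags(g: DirectedGraph) -> list[DirectedGraph]:
    """All DAGs sharing g's skeleton and v-structures (brute force)."""
    skel = sorted(tuple(sorted(e)) for e in g.skeleton_edges())
    target_v = g.v_structures()
    out = []
    for bits in product([0, 1], repeat=len(skel)):
        edges = [(u, v) if b == 0 else (v, u) for (u, v), b in zip(skel, bits)]
        try:
            cand = DirectedGraph(g.nodes, edges)
        except Exception:
            continue
        if cand.v_structures() == target_v:
            out.append(cand)
    return out


def essential_graph_by_enumeration(g: DirectedGraph) -> PartialDAG:
    """Essential graph as the unanimous orientation over the equivalence
    class enumerated by brute force."""
    members = equivalence_class_dags(g)
    assert members, "equivalence class must contain g itself"
    directed = set.intersection(*(m.edges for m in members))
    compelled_pairs = {frozenset(d) for d in directed}
    undirected = {e for e in g.skeleton_edges() if e not in compelled_pairs}
    return PartialDAG(g.nodes, directed, undirected)


def is_markov_blanket(g: DirectedGraph, t: str, blanket: set[str]) -> bool:
    """Check the blanket property by d-separation path enumeration."""
    rest = [n for n in g.nodes if n != t and n not in blanket]
    return all(dsep_by_path_enumeration(g, t, x, set(blanket)) for x in rest)


def exact_marginals(bn) -> dict[str, list[float]]:
    """Per-node marginal distributions by full joint enumeration."""
    import numpy as np

    nodes = bn.graph.topological_order()
    marg = {n: np.zeros(bn.arities[n]) for n in nodes}
    for assign in product(*[range(bn.arities[n]) for n in nodes]):
        state = dict(zip(nodes, assign))
        p = 1.0
        for n in nodes:
            idx = tuple(state[par] for par in bn.parent_order[n])
            p *= bn.cpts[n][idx + (state[n],)]
        for n in nodes:
            marg[n][state[n]] += p
    return {n: list(v) for n, v in marg.items()}
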