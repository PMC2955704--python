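"""Graph primitives: DAGs, partially directed graphs, d-separation, Markov
boundaries, essential graphs and random-DAG generation.

These structures underpin every other module: the independence oracle is
d-separation on a :class:`DirectedGraph`, the learners emit a
:class:`PartialDAG`, and the benchmark generator draws structures with
:func:`random_dag`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import numpy as np

__all__ = [
    "DirectedGraph",
    "PartialDAG",
    "NodeSets",
    "d_separated",
    "true_node_sets",
    "essential_graph",
    "meek_propagate",
    "random_dag",
]


class GraphError(ValueError):
    """Raised on malformed graph input (unknown node, cycle, self-loop)."""


# ---------------------------------------------------------------------------
# Data structures
# ---------------------------------------------------------------------------


class DirectedGraph:
    """A directed acyclic graph over named nodes.

    Parameters
    ----------
    nodes
        Iterable of node names. Order is preserved (first occurrence wins).
    edges
        Iterable of ``(u, v)`` pairs meaning ``u -> v``.

    Raises
    ------
    GraphError
        On self-loops, unknown endpoints or directed cycles.
    """

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()) -> None:
        self.nodes: list[str] = list(dict.fromkeys(nodes))
        node_set = set(self.nodes)
        self._parents: dict[str, set[str]] = {n: set() for n in self.nodes}
        self._children: dict[str, set[str]] = {n: set() for n in self.nodes}
        self.edges: set[tuple[str, str]] = set()
        for u, v in edges:
            if u == v:
                raise GraphError(f"self-loop on {u!r}")
            if u not in node_set or v not in node_set:
                raise GraphError(f"edge ({u!r}, {v!r}) references unknown node")
            if (u, v) in self.edges:
                continue
            self.edges.add((u, v))
            self._parents[v].add(u)
            self._children[u].add(v)
        self._topo_order = self._topological_order()  # raises on cycles

    # -- basic queries ------------------------------------------------------

    def parents(self, n: str) -> set[str]:
        self._check(n)
        return set(self._parents[n])

    def children(self, n: str) -> set[str]:
        self._check(n)
        return set(self._children[n])

    def neighbors(self, n: str) -> set[str]:
        """Skeleton neighbours: parents union children."""
        self._check(n)
        return self._parents[n] | self._children[n]

    def degree(self, n: str) -> int:
        return len(self.neighbors(n))

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in self.edges

    def adjacent(self, u: str, v: str) -> bool:
        return (u, v) in self.edges or (v, u) in self.edges

    def ancestors(self, seeds: Iterable[str]) -> set[str]:
        """All ancestors of ``seeds``, including the seeds themselves."""
        out: set[str] = set()
        stack = list(seeds)
        while stack:
            n = stack.pop()
            if n in out:
                continue
            out.add(n)
            stack.extend(self._parents[n])
        return out

    def descendants(self, n: str) -> set[str]:
        """Descendants of ``n`` including ``n``."""
        out: set[str] = set()
        stack = [n]
        while stack:
            m = stack.pop()
            if m in out:
                continue
            out.add(m)
            stack.extend(self._children[m])
        return out

    def topological_order(self) -> list[str]:
        return list(self._topo_order)

    def skeleton_edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.edges}

    def v_structures(self) -> set[tuple[str, str, str]]:
        """Uncoupled colliders as ``(x, z, y)`` with x < y and x->z<-y."""
        out = set()
        for z in self.nodes:
            ps = sorted(self._parents[z])
            for x, y in combinations(ps, 2):
                if not self.adjacent(x, y):
                    out.add((x, z, y))
        return out

    def _check(self, n: str) -> None:
        if n not in self._parents:
            raise GraphError(f"unknown node {n!r}")

    def _topological_order(self) -> list[str]:
        indeg = {n: len(self._parents[n]) for n in self.nodes}
        ready = sorted(n for n in self.nodes if indeg[n] == 0)
        order: list[str] = []
        while ready:
            n = ready.pop(0)
            order.append(n)
            for c in sorted(self._children[n]):
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if len(order) != len(self.nodes):
            raise GraphError("graph contains a directed cycle")
        return order

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DirectedGraph):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and self.edges == other.edges

    def __repr__(self) -> str:
        return f"DirectedGraph({len(self.nodes)} nodes, {len(self.edges)} edges)"


class PartialDAG:
    """A partially directed acyclic graph (mix of directed and undirected edges).

    Invariants enforced at construction: no self-loops, a skeleton pair may be
    either directed or undirected but not both, and the directed part is
    acyclic.
    """

    def __init__(
        self,
        nodes: Iterable[str],
        directed: Iterable[tuple[str, str]] = (),
        undirected: Iterable[tuple[str, str] | frozenset[str]] = (),
    ) -> None:
        self.nodes: list[str] = list(dict.fromkeys(nodes))
        node_set = set(self.nodes)
        self.directed: set[tuple[str, str]] = set()
        self.undirected: set[frozenset[str]] = set()
        for u, v in directed:
            if u == v:
                raise GraphError(f"self-loop on {u!r}")
            if u not in node_set or v not in node_set:
                raise GraphError(f"edge ({u!r}, {v!r}) references unknown node")
            self.directed.add((u, v))
        for e in undirected:
            u, v = tuple(e)
            if u == v:
                raise GraphError(f"self-loop on {u!r}")
            if u not in node_set or v not in node_set:
                raise GraphError(f"edge ({u!r}, {v!r}) references unknown node")
            self.undirected.add(frozenset((u, v)))
        for u, v in self.directed:
            if frozenset((u, v)) in self.undirected:
                raise GraphError(f"pair ({u!r}, {v!r}) is both directed and undirected")
            if (v, u) in self.directed:
                raise GraphError(f"pair ({u!r}, {v!r}) directed both ways")
        # acyclicity of the directed part
        DirectedGraph(self.nodes, self.directed)

    def skeleton_edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.directed} | set(self.undirected)

    def adjacent(self, u: str, v: str) -> bool:
        return frozenset((u, v)) in self.skeleton_edges()

    def neighbors(self, n: str) -> set[str]:
        out = set()
        for e in self.skeleton_edges():
            if n in e:
                (other,) = e - {n}
                out.add(other)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PartialDAG):
            return NotImplemented
        return (
            set(self.nodes) == set(other.nodes)
            and self.directed == other.directed
            and self.undirected == other.undirected
        )

    def __repr__(self) -> str:
        return (
            f"PartialDAG({len(self.nodes)} nodes, {len(self.directed)} directed, "
            f"{len(self.undirected)} undirected)"
        )

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "nodes": list(self.nodes),
            "directed": sorted([u, v] for u, v in self.directed),
            "undirected": sorted(sorted(e) for e in self.undirected),
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PartialDAG":
        doc = json.loads(text)
        return cls(doc["nodes"], [tuple(e) for e in doc["directed"]],
                   [tuple(e) for e in doc["undirected"]])

    def to_dot(self, edge_weights: dict | None = None) -> str:
        """Render as DOT; undirected edges carry ``dir=none``.

        ``edge_weights`` maps ordered pairs (or frozensets) to a float used
        for ``penwidth`` so that consensus confidence shows as line thickness.
        """
        lines = ["digraph pdag {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')

        def _attrs(key, base: list[str]) -> str:
            attrs = list(base)
            if edge_weights and key in edge_weights:
                w = float(edge_weights[key])
                attrs.append(f"penwidth={1 + 4 * w:.2f}")
                attrs.append(f'label="{w:.2f}"')
            return f' [{", ".join(attrs)}]' if attrs else ""

        for u, v in sorted(self.directed):
            lines.append(f'  "{u}" -> "{v}"{_attrs((u, v), [])};')
        for e in sorted(self.undirected, key=sorted):
            u, v = sorted(e)
            lines.append(f'  "{u}" -> "{v}"{_attrs(frozenset((u, v)), ["dir=none"])};')
        lines.append("}")
        return "\n".join(lines)


@dataclass(frozen=True)
class NodeSets:
    """Parents-children, spouses and Markov boundary of a target node."""

    pc: frozenset[str]
    spouses: frozenset[str]
    mb: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        if not self.mb:
            object.__setattr__(self, "mb", self.pc | self.spouses)


# ---------------------------------------------------------------------------
# d-separation
# ---------------------------------------------------------------------------


def d_separated(g: DirectedGraph, x: str, y: str, z: Iterable[str]) -> bool:
    """Decide whether ``x`` and ``y`` are d-separated given ``z`` in ``g``.

    Implemented by the ancestral-moralization criterion: ``x`` and ``y`` are
    d-separated by ``z`` iff they are disconnected in the moral graph of the
    ancestral subgraph of ``{x, y} | z`` after deleting ``z``.
    """
    zset = frozenset(z)
    g._check(x)
    g._check(y)
    for n in zset:
        g._check(n)
    if x == y:
        raise GraphError("x and y must differ")
    if x in zset or y in zset:
        raise GraphError("x and y must not appear in z")

    anc = g.ancestors({x, y} | zset)
    # moral graph restricted to anc, minus z
    adj: dict[str, set[str]] = {n: set() for n in anc}
    for u, v in g.edges:
        if u in anc and v in anc:
            adj[u].add(v)
            adj[v].add(u)
    for n in anc:
        ps = [p for p in g._parents[n] if p in anc]
        for a, b in combinations(ps, 2):
            adj[a].add(b)
            adj[b].add(a)
    # BFS from x to y avoiding z
    seen = {x}
    stack = [x]
    while stack:
        n = stack.pop()
        if n == y:
            return False
        for m in adj[n]:
            if m not in seen and m not in zset:
                seen.add(m)
                stack.append(m)
    return True


def true_node_sets(g: DirectedGraph, t: str) -> NodeSets:
    """Read PC, spouse and Markov-boundary sets of ``t`` off the DAG."""
    g._check(t)
    pc = g.parents(t) | g.children(t)
    spouses: set[str] = set()
    for c in g.children(t):
        spouses |= g.parents(c)
    spouses -= {t} | pc
    return NodeSets(pc=frozenset(pc), spouses=frozenset(spouses))


# ---------------------------------------------------------------------------
# Essential graph (DAG pattern) machinery
# ---------------------------------------------------------------------------


def _meek_apply(
    nodes: list[str],
    directed: set[tuple[str, str]],
    undirected: set[frozenset[str]],
) -> None:
    """Apply the four Meek orientation rules in place until fixpoint."""

    def adjacent(a: str, b: str) -> bool:
        return (a, b) in directed or (b, a) in directed or frozenset((a, b)) in undirected

    def orient(a: str, b: str) -> bool:
        e = frozenset((a, b))
        if e in undirected:
            undirected.discard(e)
            directed.add((a, b))
            return True
        return False

    changed = True
    while changed:
        changed = False
        for e in sorted(undirected, key=sorted):
            a, b = sorted(e)
            for u, v in ((a, b), (b, a)):
                # R1: w -> u, u - v, w and v non-adjacent  =>  u -> v
                if any((w, u) in directed and not adjacent(w, v)
                       for w in nodes if w not in (u, v)):
                    changed |= orient(u, v)
                    break
                # R2: u -> w -> v and u - v  =>  u -> v
                if any((u, w) in directed and (w, v) in directed
                       for w in nodes if w not in (u, v)):
                    changed |= orient(u, v)
                    break
                # R3: u - c, u - d, c -> v, d -> v, c and d non-adjacent  =>  u -> v
                spoke = [c for c in nodes
                         if c not in (u, v)
                         and frozenset((u, c)) in undirected and (c, v) in directed]
                if any(not adjacent(c, d) for c, d in combinations(spoke, 2)):
                    changed |= orient(u, v)
                    break
                # R4: u - d, d -> c, c -> v, u adjacent to c, d and v non-adjacent  =>  u -> v
                done = False
                for d in nodes:
                    if d in (u, v) or not frozenset((u, d)) in undirected:
                        continue
                    if adjacent(d, v):
                        continue
                    for c in nodes:
                        if c in (u, v, d):
                            continue
                        if (d, c) in directed and (c, v) in directed and adjacent(u, c):
                            changed |= orient(u, v)
                            done = True
                            break
                    if done:
                        break
                if done:
                    break


def meek_propagate(pdag: PartialDAG) -> PartialDAG:
    """Return the closure of ``pdag`` under the four Meek rules."""
    directed = set(pdag.directed)
    undirected = set(pdag.undirected)
    _meek_apply(pdag.nodes, directed, undirected)
    return PartialDAG(pdag.nodes, directed, undirected)


def essential_graph(g: DirectedGraph) -> PartialDAG:
    """Compute the essential graph (DAG pattern / CPDAG) of ``g``.

    Orients the v-structures of ``g``, then propagates compelled edges with
    the Meek rules; every other edge stays undirected.
    """
    directed: set[tuple[str, str]] = set()
    for x, z, y in g.v_structures():
        directed.add((x, z))
        directed.add((y, z))
    undirected = {frozenset((u, v)) for u, v in g.edges
                  if (u, v) not in directed and (v, u) not in directed}
    _meek_apply(g.nodes, directed, undirected)
    return PartialDAG(g.nodes, directed, undirected)


# ---------------------------------------------------------------------------
# Random DAG generation
# ---------------------------------------------------------------------------


def _node_names(n: int) -> list[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"X{i:0{width}d}" for i in range(n)]


def random_dag(
    n_nodes: int,
    n_edges: int,
    max_degree: int,
    seed: int,
    hub_degree: int | None = None,
    max_parents: int | None = None,
) -> DirectedGraph:
    """Sample a uniform-ish random DAG with bounded skeleton degree.

    A random topological order is drawn first and only forward edges are
    added, which guarantees acyclicity. If ``hub_degree`` is given, one node
    is first connected to exactly that many neighbours (a mix of parents and
    children) before the remaining edges are filled in. ``max_parents``
    additionally bounds the in-degree.

    Deterministic for a fixed ``seed``.
    """
    if n_nodes < 1:
        raise GraphError("n_nodes must be positive")
    if n_edges > n_nodes * (n_nodes - 1) // 2:
        raise GraphError("too many edges for a DAG on this many nodes")
    if n_edges > n_nodes * max_degree // 2:
        raise GraphError("edge count infeasible under max_degree")
    if hub_degree is not None and (hub_degree > max_degree or hub_degree > n_edges
                                   or hub_degree > n_nodes - 1):
        raise GraphError("hub_degree infeasible")

    rng = np.random.default_rng(seed)
    names = _node_names(n_nodes)
    order = list(rng.permutation(n_nodes))
    rank = {names[node]: i for i, node in enumerate(order)}

    degree = {n: 0 for n in names}
    n_parents = {n: 0 for n in names}
    edges: set[tuple[str, str]] = set()

    def add(u: str, v: str) -> None:
        # orient along the sampled order
        if rank[u] > rank[v]:
            u, v = v, u
        edges.add((u, v))
        degree[u] += 1
        degree[v] += 1
        n_parents[v] += 1

    if hub_degree is not None:
        # keep the hub away from the ends of the order so it can have both
        # parents and children
        mid = [names[node] for node in order[n_nodes // 4: 3 * n_nodes // 4]]
        hub = mid[rng.integers(len(mid))]
        others = [n for n in names if n != hub]
        picks = rng.choice(len(others), size=hub_degree, replace=False)
        for i in picks:
            add(hub, others[i])

    candidates = [(names[order[i]], names[order[j]])
                  for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    rng.shuffle(candidates)
    for u, v in candidates:
        if len(edges) >= n_edges:
            break
        if (u, v) in edges or (v, u) in edges:
            continue
        if degree[u] >= max_degree or degree[v] >= max_degree:
            continue
        if max_parents is not None and n_parents[v] >= max_parents:
            continue
        if hub_degree is not None and hub_degree == max_degree and hub in (u, v):
            continue  # hub already saturated
        add(u, v)
    if len(edges) != n_edges:
        raise GraphError("could not place the requested number of edges; "
                         "relax max_degree or lower n_edges")
    return DirectedGraph(names, edges)
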