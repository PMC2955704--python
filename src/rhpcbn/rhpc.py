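"""Whole-network structure learning: HPC on every node, v-structure
orientation from cached separating sets, and Meek-rule propagation of the
compelled edges. The output is an estimate of the essential graph.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Iterable

from .ci_tests import CITest, Dataset, MemoizedTest
from .graph_core import GraphError, PartialDAG, meek_propagate
from .hpc import SepsetCache, hpc

__all__ = ["learn_skeleton", "orient_v_structures", "rhpc"]

log = logging.getLogger(__name__)


def learn_skeleton(
    data: Dataset | None,
    test: CITest,
    alpha: float = 0.05,
    columns: Iterable[str] | None = None,
    combine: str = "or",
) -> tuple[PartialDAG, SepsetCache]:
    """Run HPC on every column and assemble the undirected skeleton.

    ``combine`` picks the symmetrization rule: ``"or"`` keeps an edge when
    either endpoint claims the other (rescues false negatives, the default),
    ``"and"`` requires both.
    """
    if columns is None:
        if data is None:
            raise ValueError("columns must be given when data is None")
        columns = list(data.column_names)
    columns = sorted(columns)
    if len(columns) < 2 and data is not None and len(columns) < 1:
        raise ValueError("need at least one column")
    if combine not in ("or", "and"):
        raise ValueError("combine must be 'or' or 'and'")

    claims: dict[str, set[str]] = {}
    cache = SepsetCache()
    memo = MemoizedTest(test)  # per-node runs revisit the same pairs
    for t in columns:
        pc, local_cache = hpc(t, data, memo, alpha, columns)
        claims[t] = pc
        cache.merge(local_cache)
        log.info("node %s: |PC|=%d (tests so far: %d unique, %d cached hits)",
                 t, len(pc), len(memo), memo.hits)

    edges: set[frozenset[str]] = set()
    for x, y in combinations(columns, 2):
        claimed = (y in claims[x], x in claims[y])
        keep = any(claimed) if combine == "or" else all(claimed)
        if keep:
            edges.add(frozenset((x, y)))
    return PartialDAG(columns, (), edges), cache


def _find_sepset(
    x: str,
    y: str,
    skeleton: PartialDAG,
    data: Dataset | None,
    test: CITest | None,
    alpha: float,
    max_size: int = 2,
) -> frozenset[str] | None:
    """Search size-<=2 subsets of either endpoint's neighbourhood for a
    separating set; used when the OR rule left a non-adjacent pair untested."""
    if test is None:
        return None
    for base in (skeleton.neighbors(x) - {y}, skeleton.neighbors(y) - {x}):
        pool = sorted(base)
        for size in range(min(max_size, len(pool)) + 1):
            for z in combinations(pool, size):
                if test(data, x, y, frozenset(z), alpha).independent:
                    return frozenset(z)
    return None


def orient_v_structures(
    skeleton: PartialDAG,
    cache: SepsetCache,
    data: Dataset | None = None,
    test: CITest | None = None,
    alpha: float = 0.05,
) -> PartialDAG:
    """Orient every uncoupled triple x - z - y with z outside dSep(x, y).

    Pairs missing from the cache get a late separating-set search over the
    endpoints' learned neighbourhoods (sets of size <= 2); if that fails the
    triple stays unoriented. Conflicting orientations revert the affected
    edge to undirected so the PDAG invariants always hold.
    """
    nodes = list(skeleton.nodes)
    undirected = set(skeleton.undirected)
    arrows: set[tuple[str, str]] = set()

    sepsets: dict[frozenset[str], frozenset[str]] = {}
    for x, y in combinations(sorted(nodes), 2):
        if skeleton.adjacent(x, y):
            continue
        if (x, y) in cache:
            sepsets[frozenset((x, y))] = cache.get(x, y)
        else:
            found = _find_sepset(x, y, skeleton, data, test, alpha)
            if found is not None:
                sepsets[frozenset((x, y))] = found

    for x, y in combinations(sorted(nodes), 2):
        pair = frozenset((x, y))
        if skeleton.adjacent(x, y) or pair not in sepsets:
            continue
        dsep = sepsets[pair]
        for z in sorted(skeleton.neighbors(x) & skeleton.neighbors(y)):
            if z not in dsep:
                arrows.add((x, z))
                arrows.add((y, z))

    directed: set[tuple[str, str]] = set()
    for u, v in arrows:
        if (v, u) in arrows:
            continue  # conflict: leave undirected
        directed.add((u, v))
        undirected.discard(frozenset((u, v)))

    # directed cycles can arise from inconsistent tests; drop arrows until
    # the directed part is acyclic (deterministic order)
    while True:
        try:
            return PartialDAG(nodes, directed, undirected)
        except GraphError:
            u, v = sorted(directed)[-1]
            directed.discard((u, v))
            undirected.add(frozenset((u, v)))


def rhpc(
    data: Dataset | None,
    test: CITest,
    alpha: float = 0.05,
    columns: Iterable[str] | None = None,
    combine: str = "or",
) -> PartialDAG:
    """Learn an essential-graph estimate: skeleton, v-structures, Meek rules.

    With the d-separation oracle test on a faithful DAG the output equals
    the essential graph of the generating DAG.
    """
    skeleton, cache = learn_skeleton(data, test, alpha, columns, combine)
    oriented = orient_v_structures(skeleton, cache, data, test, alpha)
    try:
        return meek_propagate(oriented)
    except GraphError:
        # inconsistent tests can make the propagated arrows cyclic; fall back
        # to the v-structure-only orientation, which is always a valid PDAG
        return oriented
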