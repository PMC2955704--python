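from __future__ import annotations

import numpy as np
import pytest

from rhpcbn.graph_core import DirectedGraph, random_dag


@pytest.fixture
def chain_abc() -> DirectedGraph:
    return DirectedGraph(["A", "B", "C"], [("A", "B"), ("B", "C")])


@pytest.fixture
def collider_abc() -> DirectedGraph:
    return DirectedGraph(["A", "B", "C"], [("A", "B"), ("C", "B")])


@pytest.fixture
def spouse_graph() -> DirectedGraph:
    """A -> T <- B, T -> C, D -> C: pc(T)={A,B,C}, spouses(T)={D}."""
    return DirectedGraph(
        ["A", "B", "C", "D", "T"],
        [("A", "T"), ("B", "T"), ("T", "C"), ("D", "C")],
    )


def small_random_dags(n_graphs: int = 25, max_nodes: int = 10, seed0: int = 500):
    """The shared random-DAG suite: 5..max_nodes nodes, moderate density."""
    out = []
    for i in range(n_graphs):
        n = 5 + i % (max_nodes - 4)
        e = min(n * (n - 1) // 2, int(1.5 * n))
        out.append(random_dag(n, e, max_degree=n - 1, seed=seed0 + i))
    return out


@pytest.fixture(scope="session")
def dag_suite():
    return small_random_dags()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
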