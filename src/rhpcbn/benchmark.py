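"""Benchmarking against known networks: forward sampling, the
precision/recall structure-recovery distance, and the experiment runner
comparing HPC with the weak learner on a hub node.

Also houses :class:`BayesNet` with plain-text BIF reading and writing, plus
deterministic synthetic fixtures (a 35-node / 52-edge network with a
degree-13 hub mirroring the dimensions of a published benchmark network, and
a simple chain network for consensus smoke tests).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .ci_tests import CITest, Dataset, MemoizedTest, g2_test
from .graph_core import DirectedGraph, random_dag, true_node_sets
from .hpc import hpc as hpc_learner
from .weak_learner import inter_iapc

__all__ = [
    "BayesNet",
    "PRDistance",
    "RecoveryResult",
    "forward_sample",
    "pc_distance",
    "run_recovery_experiment",
    "load_insulin_like_fixture",
    "chain_bn",
    "read_bif",
    "write_bif",
]

INSULIN_LIKE_SEED = 20100928  # frozen: the fixture must be bit-stable


# ---------------------------------------------------------------------------
# BayesNet
# ---------------------------------------------------------------------------


@dataclass
class BayesNet:
    """A discrete Bayesian network: DAG, per-node arities and CPTs.

    ``cpts[n]`` has shape ``(*parent arities, arity of n)`` with parent axes
    following ``parent_order[n]``. Every row is a probability vector.
    """

    graph: DirectedGraph
    arities: dict[str, int]
    cpts: dict[str, np.ndarray]
    parent_order: dict[str, tuple[str, ...]] = field(default_factory=dict)
    state_names: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for n in self.graph.nodes:
            if n not in self.parent_order:
                self.parent_order[n] = tuple(sorted(self.graph.parents(n)))
            if n not in self.state_names:
                self.state_names[n] = [str(i) for i in range(self.arities[n])]
            expect = tuple(self.arities[p] for p in self.parent_order[n]) + (self.arities[n],)
            cpt = np.asarray(self.cpts[n], dtype=float)
            if cpt.shape != expect:
                raise ValueError(f"CPT for {n!r} has shape {cpt.shape}, expected {expect}")
            if (cpt < 0).any() or not np.allclose(cpt.sum(axis=-1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows for {n!r} must be nonnegative and sum to 1")
            self.cpts[n] = cpt

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def max_degree_node(self) -> str:
        return max(self.graph.nodes, key=lambda n: (self.graph.degree(n), n))


# ---------------------------------------------------------------------------
# Forward (ancestral) sampling
# ---------------------------------------------------------------------------


def forward_sample(bn: BayesNet, n_rows: int, seed: int) -> Dataset:
    """Sample ``n_rows`` joint observations by ancestral sampling."""
    rng = np.random.default_rng(seed)
    cols = {n: np.empty(n_rows, dtype=np.int64) for n in bn.nodes}
    for n in bn.graph.topological_order():
        parents = bn.parent_order[n]
        cpt = bn.cpts[n].reshape(-1, bn.arities[n])
        if parents:
            idx = np.zeros(n_rows, dtype=np.int64)
            for p in parents:
                idx = idx * bn.arities[p] + cols[p]
        else:
            idx = np.zeros(n_rows, dtype=np.int64)
        cum = np.cumsum(cpt, axis=1)
        u = rng.random(n_rows)
        # find the first state whose cumulative mass exceeds u, per row
        cols[n] = (u[:, None] >= cum[idx]).sum(axis=1).astype(np.int64)
        np.clip(cols[n], 0, bn.arities[n] - 1, out=cols[n])
    names = list(bn.nodes)
    values = np.column_stack([cols[n] for n in names])
    return Dataset(names, values, {n: bn.arities[n] for n in names})


# ---------------------------------------------------------------------------
# Recovery metric
# ---------------------------------------------------------------------------


class PRDistance(NamedTuple):
    precision: float
    recall: float
    distance: float


@dataclass(frozen=True)
class RecoveryResult:
    algorithm: str
    sample_size: int
    replicate: int
    precision: float
    recall: float
    distance: float


def pc_distance(output: Iterable[str], truth: Iterable[str]) -> PRDistance:
    """Squared distance from perfect precision and recall.

    ``distance = (1 - precision)^2 + (1 - recall)^2`` where precision is the
    fraction of the output that is correct (1 by convention for an empty
    output) and recall the fraction of the truth that was found. The value is
    reported unrooted, in [0, 2].
    """
    out = set(output)
    tru = set(truth)
    if not tru:
        raise ValueError("truth set must be non-empty")
    tp = len(out & tru)
    precision = tp / len(out) if out else 1.0
    recall = tp / len(tru)
    return PRDistance(precision, recall, (1 - precision) ** 2 + (1 - recall) ** 2)


_ALGORITHMS = {
    "hpc": lambda t, data, test, alpha: hpc_learner(t, data, test, alpha)[0],
    "inter_iapc": lambda t, data, test, alpha: inter_iapc(t, data, test, alpha),
}


def run_recovery_experiment(
    bn: BayesNet,
    target: str,
    sample_sizes: Sequence[int],
    n_datasets: int,
    algorithms: Sequence[str] = ("hpc", "inter_iapc"),
    seed: int = 0,
    alpha: float = 0.05,
    test: CITest = g2_test,
) -> list[RecoveryResult]:
    """Full factorial recovery experiment on one target node.

    For every sample size and replicate, one dataset is sampled and every
    algorithm learns the target's PC set from it; results are scored against
    the true PC set read off the generating DAG.
    """
    if target not in bn.graph.nodes:
        raise ValueError(f"unknown target {target!r}")
    for a in algorithms:
        if a not in _ALGORITHMS:
            raise ValueError(f"unknown algorithm {a!r}")
    truth = set(true_node_sets(bn.graph, target).pc)
    results: list[RecoveryResult] = []
    for size in sample_sizes:
        for rep in range(n_datasets):
            # deterministic and order-independent: keyed by (seed, size, rep)
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(size, rep))
            data = forward_sample(bn, size, int(ss.generate_state(1)[0]))
            memo = MemoizedTest(test)  # pure cache: identical results, less work
            for alg in algorithms:
                out = _ALGORITHMS[alg](target, data, memo, alpha)
                pr = pc_distance(out, truth)
                results.append(RecoveryResult(alg, size, rep, pr.precision,
                                              pr.recall, pr.distance))
    return results


def results_frame(results: Sequence[RecoveryResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def _random_cpts(
    graph: DirectedGraph,
    arities: dict[str, int],
    rng: np.random.Generator,
    concentration: float = 0.5,
    uniform_mix: float = 0.1,
) -> dict[str, np.ndarray]:
    """Dirichlet-style CPTs mixed with a slice of uniform so no row is
    deterministic (and none is exactly uniform, keeping edges detectable)."""
    cpts = {}
    for n in graph.nodes:
        parents = tuple(sorted(graph.parents(n)))
        shape = tuple(arities[p] for p in parents) + (arities[n],)
        raw = rng.dirichlet([concentration] * arities[n],
                            size=int(np.prod(shape[:-1], dtype=int))).reshape(shape)
        cpt = (1 - uniform_mix) * raw + uniform_mix / arities[n]
        cpts[n] = cpt / cpt.sum(axis=-1, keepdims=True)
    return cpts


def load_insulin_like_fixture() -> BayesNet:
    """Deterministic benchmark stand-in: 35 nodes, 52 edges, one hub with 13
    skeleton neighbours, binary/ternary variables, non-degenerate CPTs."""
    graph = random_dag(35, 52, max_degree=13, seed=INSULIN_LIKE_SEED, hub_degree=13)
    rng = np.random.default_rng(INSULIN_LIKE_SEED + 1)
    arities = {n: int(rng.integers(2, 4)) for n in graph.nodes}
    cpts = _random_cpts(graph, arities, rng)
    return BayesNet(graph=graph, arities=arities, cpts=cpts)


def chain_bn(n_nodes: int = 5, arity: int = 2, flip: float = 0.1) -> BayesNet:
    """A chain X0 -> X1 -> ... with strong copy-with-noise CPTs."""
    names = [f"X{i}" for i in range(n_nodes)]
    edges = [(names[i], names[i + 1]) for i in range(n_nodes - 1)]
    graph = DirectedGraph(names, edges)
    arities = {n: arity for n in names}
    root = np.full(arity, 1.0 / arity)
    copy = np.full((arity, arity), flip / (arity - 1))
    np.fill_diagonal(copy, 1.0 - flip)
    cpts = {names[0]: root}
    for i in range(1, n_nodes):
        cpts[names[i]] = copy.copy()
    return BayesNet(graph=graph, arities=arities, cpts=cpts)


# ---------------------------------------------------------------------------
# BIF reading and writing
# ---------------------------------------------------------------------------

_VAR_RE = re.compile(
    r"variable\s+(\S+)\s*\{[^}]*?type\s+discrete\s*\[\s*(\d+)\s*\]\s*\{([^}]*)\}",
    re.S,
)
_PROB_RE = re.compile(r"probability\s*\(\s*([^)]*)\)\s*\{(.*?)\}", re.S)


def read_bif(source: str | Path) -> BayesNet:
    """Parse a (plain-text) BIF network definition into a :class:`BayesNet`."""
    if isinstance(source, Path) or ("\n" not in str(source) and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)

    arities: dict[str, int] = {}
    states: dict[str, list[str]] = {}
    for name, card, state_blob in _VAR_RE.findall(text):
        labels = [s.strip() for s in state_blob.split(",") if s.strip()]
        arities[name] = int(card)
        if len(labels) != int(card):
            raise ValueError(f"variable {name!r}: {len(labels)} states declared, "
                             f"cardinality {card}")
        states[name] = labels

    edges: list[tuple[str, str]] = []
    parent_order: dict[str, tuple[str, ...]] = {}
    cpts: dict[str, np.ndarray] = {}
    for header, body in _PROB_RE.findall(text):
        if "|" in header:
            child_part, parent_part = header.split("|", 1)
            child = child_part.strip()
            parents = tuple(p.strip() for p in parent_part.split(","))
        else:
            child = header.strip()
            parents = ()
        for p in parents:
            edges.append((p, child))
        parent_order[child] = parents
        shape = tuple(arities[p] for p in parents) + (arities[child],)
        cpt = np.zeros(shape)
        if not parents:
            m = re.search(r"table\s+([^;]+);", body)
            if not m:
                raise ValueError(f"no table for root variable {child!r}")
            cpt[:] = [float(v) for v in m.group(1).split(",")]
        else:
            for m in re.finditer(r"\(([^)]*)\)\s*([^;]+);", body):
                labels = [s.strip() for s in m.group(1).split(",")]
                idx = tuple(states[p].index(lab) for p, lab in zip(parents, labels))
                cpt[idx] = [float(v) for v in m.group(2).split(",")]
        cpts[child] = cpt

    graph = DirectedGraph(list(arities), edges)
    return BayesNet(graph=graph, arities=arities, cpts=cpts,
                    parent_order=parent_order, state_names=states)


def write_bif(bn: BayesNet, path: str | Path | None = None) -> str:
    """Serialize a :class:`BayesNet` to BIF text; optionally write to disk."""
    lines = ["network unknown {", "}"]
    for n in bn.nodes:
        state_list = ", ".join(bn.state_names[n])
        lines += [
            f"variable {n} {{",
            f"  type discrete [ {bn.arities[n]} ] {{ {state_list} }};",
            "}",
        ]
    for n in bn.nodes:
        parents = bn.parent_order[n]
        if not parents:
            values = ", ".join(f"{v:.10g}" for v in bn.cpts[n])
            lines += [f"probability ( {n} ) {{", f"  table {values};", "}"]
        else:
            lines.append(f"probability ( {n} | {', '.join(parents)} ) {{")
            cpt = bn.cpts[n]
            for idx in np.ndindex(*cpt.shape[:-1]):
                labels = ", ".join(bn.state_names[p][i] for p, i in zip(parents, idx))
                values = ", ".join(f"{v:.10g}" for v in cpt[idx])
                lines.append(f"  ({labels}) {values};")
            lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
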