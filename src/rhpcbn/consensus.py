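"""Bootstrap consensus networks.

Structure learning on a single small sample is unstable; resampling the rows
with replacement, relearning, and keeping only the edges that recur often
enough yields a more robust consensus PDAG. Directed edges in a replicate
support only their own direction; undirected edges support both. Edges whose
confidence exceeds the threshold in both directions come out undirected.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ci_tests import CITest, Dataset
from .graph_core import PartialDAG
from .rhpc import rhpc

__all__ = [
    "ConfidenceTable",
    "bootstrap_resample",
    "edge_confidences",
    "consensus_pdag",
    "bootstrap_learn",
]

DEFAULT_N_REPLICATES = 200
DEFAULT_THRESHOLD = 0.25


@dataclass
class ConfidenceTable:
    """Directional edge-support counts over a set of learned PDAGs."""

    nodes: list[str]
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    n_replicates: int = 0

    def confidence(self, x: str, y: str) -> float:
        if self.n_replicates == 0:
            return 0.0
        return self.counts.get((x, y), 0) / self.n_replicates

    def ordered_pairs(self) -> list[tuple[str, str]]:
        out = []
        for x in self.nodes:
            for y in self.nodes:
                if x != y:
                    out.append((x, y))
        return out

    def to_csv(self, fh: io.TextIOBase | None = None, include_zero: bool = False) -> str:
        buf = fh or io.StringIO()
        w = csv.writer(buf)
        w.writerow(["from", "to", "confidence"])
        for x, y in self.ordered_pairs():
            c = self.confidence(x, y)
            if c > 0 or include_zero:
                w.writerow([x, y, f"{c:.6g}"])
        return buf.getvalue() if fh is None else ""


def bootstrap_resample(data: Dataset, seed: int) -> Dataset:
    """Resample the rows of ``data`` i.i.d. with replacement."""
    if data.n_rows < 1:
        raise ValueError("cannot resample an empty dataset")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, data.n_rows, size=data.n_rows)
    return Dataset(list(data.column_names), data.values[idx],
                   dict(data.arities) if data.arities is not None else None)


def edge_confidences(pdags: Sequence[PartialDAG]) -> ConfidenceTable:
    """Count directional support for every edge across replicate PDAGs."""
    if not pdags:
        raise ValueError("need at least one PDAG")
    node_set = set(pdags[0].nodes)
    for p in pdags[1:]:
        if set(p.nodes) != node_set:
            raise ValueError("all PDAGs must share the same node set")
    table = ConfidenceTable(nodes=sorted(node_set), n_replicates=len(pdags))
    for p in pdags:
        for u, v in p.directed:
            table.counts[(u, v)] = table.counts.get((u, v), 0) + 1
        for e in p.undirected:
            u, v = sorted(e)
            table.counts[(u, v)] = table.counts.get((u, v), 0) + 1
            table.counts[(v, u)] = table.counts.get((v, u), 0) + 1
    return table


def consensus_pdag(conf: ConfidenceTable, threshold: float = DEFAULT_THRESHOLD) -> PartialDAG:
    """Threshold a confidence table into a consensus PDAG.

    An ordered pair whose confidence strictly exceeds the threshold becomes a
    directed edge, unless the reverse direction also exceeds it — then the
    edge is undirected.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    directed: set[tuple[str, str]] = set()
    undirected: set[frozenset[str]] = set()
    nodes = conf.nodes
    for i, x in enumerate(nodes):
        for y in nodes[i + 1:]:
            fwd = conf.confidence(x, y) > threshold
            rev = conf.confidence(y, x) > threshold
            if fwd and rev:
                undirected.add(frozenset((x, y)))
            elif fwd:
                directed.add((x, y))
            elif rev:
                directed.add((y, x))
    return PartialDAG(nodes, directed, undirected)


def bootstrap_learn(
    data: Dataset,
    n_replicates: int = DEFAULT_N_REPLICATES,
    threshold: float = DEFAULT_THRESHOLD,
    alpha: float = 0.05,
    test: CITest | None = None,
    seed: int = 0,
    combine: str = "or",
) -> tuple[PartialDAG, ConfidenceTable]:
    """Learn a consensus PDAG from bootstrap replicates of ``data``.

    Each replicate is learned with :func:`rhpc.rhpc`; replicate seeds derive
    from the master seed through a fixed counter scheme, so the whole run is
    reproducible.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    if test is None:
        from .ci_tests import fisher_z_test, g2_test
        test = g2_test if data.is_discrete else fisher_z_test
    root = np.random.SeedSequence(seed)
    replicate_seeds = [int(s.generate_state(1)[0]) for s in root.spawn(n_replicates)]
    pdags = []
    for rep_seed in replicate_seeds:
        sample = bootstrap_resample(data, rep_seed)
        pdags.append(rhpc(sample, test, alpha, combine=combine))
    table = edge_confidences(pdags)
    return consensus_pdag(table, threshold), table
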