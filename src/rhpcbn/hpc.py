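"""The Hybrid Parents and Children (HPC) local learner.

HPC estimates the parents-and-children set of a target in three stages:

1. :func:`de_pcs` — a data-efficient superset of PC, obtained by removing
   variables separable from the target with conditioning sets of size 0 or 1;
2. :func:`de_sps` — a data-efficient superset of the spouses, found by
   collider activation through each member of the PC superset;
3. a run of the weak learner on the union, followed by a decentralized
   search that rescues every superset member whose own weak-learner PC set
   contains the target.

All conditioning sets used by the two superset routines have size at most 2,
which keeps the individual independence tests well supported even on small
samples. Separating sets discovered along the way are cached for the later
v-structure orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .ci_tests import CITest, CITestResult, Dataset
from .weak_learner import inter_iapc

__all__ = ["SepsetCache", "InstrumentedTest", "de_pcs", "de_sps", "hpc"]


class SepsetCache:
    """Map from unordered node pairs to a separating set found by the tests."""

    def __init__(self) -> None:
        self._entries: dict[frozenset[str], frozenset[str]] = {}

    def put(self, x: str, y: str, z: Iterable[str]) -> None:
        zset = frozenset(z)
        if x in zset or y in zset:
            raise ValueError("separating set must not contain its endpoints")
        self._entries[frozenset((x, y))] = zset

    def get(self, x: str, y: str) -> frozenset[str]:
        return self._entries[frozenset((x, y))]

    def __contains__(self, pair: tuple[str, str] | frozenset[str]) -> bool:
        return frozenset(pair) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()

    def merge(self, other: "SepsetCache") -> None:
        """Adopt entries from ``other`` for pairs not yet cached."""
        for pair, z in other._entries.items():
            self._entries.setdefault(pair, z)


@dataclass
class InstrumentedTest:
    """Wrap a test function, counting calls and the largest |z| seen."""

    test: CITest
    n_tests: int = 0
    max_cond_size: int = 0
    _sizes: list[int] = field(default_factory=list, repr=False)

    def __call__(self, data: Dataset | None, x: str, y: str,
                 z: Iterable[str] = (), alpha: float = 0.05) -> CITestResult:
        zset = frozenset(z)
        self.n_tests += 1
        self.max_cond_size = max(self.max_cond_size, len(zset))
        return self.test(data, x, y, zset, alpha)


def de_pcs(
    t: str,
    data: Dataset | None,
    test: CITest,
    alpha: float = 0.05,
    columns: Iterable[str] | None = None,
) -> tuple[set[str], SepsetCache]:
    """Data-Efficient Parents and Children Superset of ``t``.

    Pass 1 removes every variable marginally independent of ``t`` (caching
    the empty separating set); pass 2 repeatedly removes variables separable
    by a single survivor, scanning in sorted order until a fixpoint. The
    result contains PC_t whenever the tests are reliable.
    """
    if columns is None:
        if data is None:
            raise ValueError("columns must be given when data is None")
        columns = data.column_names
    cache = SepsetCache()
    pcs: list[str] = []
    for x in sorted(columns):
        if x == t:
            continue
        if test(data, t, x, frozenset(), alpha).independent:
            cache.put(t, x, ())
        else:
            pcs.append(x)

    changed = True
    while changed:
        changed = False
        for x in list(pcs):
            for z in pcs:
                if z == x:
                    continue
                if test(data, t, x, frozenset((z,)), alpha).independent:
                    cache.put(t, x, (z,))
                    pcs.remove(x)
                    changed = True
                    break
    return set(pcs), cache


def de_sps(
    t: str,
    pcs: set[str],
    cache: SepsetCache,
    data: Dataset | None,
    test: CITest,
    alpha: float = 0.05,
    columns: Iterable[str] | None = None,
) -> set[str]:
    """Data-Efficient Spouses Superset of ``t``.

    A variable ``y`` outside the PC superset is a spouse candidate via
    ``x in pcs`` when conditioning on ``x`` re-activates the dependence that
    ``dSep(t, y)`` had removed (collider activation). A second pass prunes
    ``y`` if another candidate via the same ``x`` separates it from ``t``
    jointly with ``x``. All conditioning sets have size at most 2.
    """
    if columns is None:
        if data is None:
            raise ValueError("columns must be given when data is None")
        columns = data.column_names
    outside = [y for y in sorted(columns) if y != t and y not in pcs]
    sps: set[str] = set()
    for x in sorted(pcs):
        candidates: list[str] = []
        for y in outside:
            if (t, y) not in cache:
                raise RuntimeError(
                    f"sepset cache has no entry for ({t!r}, {y!r}); "
                    "de_sps requires the cache produced by de_pcs")
            dsep = cache.get(t, y)
            if not test(data, t, y, dsep | {x}, alpha).independent:
                candidates.append(y)
        # prune candidates against each other within the same collider path
        kept = []
        for y in candidates:
            removed = False
            for z in candidates:
                if z == y:
                    continue
                if test(data, t, y, frozenset((x, z)), alpha).independent:
                    removed = True
                    break
            if not removed:
                kept.append(y)
        sps.update(kept)
    return sps


def hpc(
    t: str,
    data: Dataset | None,
    test: CITest,
    alpha: float = 0.05,
    columns: Iterable[str] | None = None,
) -> tuple[set[str], SepsetCache]:
    """Estimate the parents-and-children set of ``t``; return it with the
    sepset cache accumulated by the superset phase.

    After the weak learner runs on the union of the two supersets, the
    decentralized search adds back every superset variable whose own
    weak-learner PC estimate (restricted to the supersets plus ``t``)
    contains ``t`` — rescuing false negatives of a single centralized run.
    """
    if columns is None:
        if data is None:
            raise ValueError("columns must be given when data is None")
        columns = list(data.column_names)
    columns = list(columns)

    pcs, cache = de_pcs(t, data, test, alpha, columns)
    sps = de_sps(t, pcs, cache, data, test, alpha, columns)
    superset = pcs | sps

    pc = inter_iapc(t, data, test, alpha, candidates=superset, sepsets=cache)
    for x in sorted(superset - pc):
        cand_x = (superset | {t}) - {x}
        if t in inter_iapc(x, data, test, alpha, candidates=cand_x, sepsets=cache):
            pc.add(x)
    return pc, cache
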