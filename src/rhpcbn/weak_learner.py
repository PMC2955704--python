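"""Markov-boundary and parents-children weak learners.

:func:`inter_iamb` estimates the Markov boundary of a target by interleaving
a greedy forward phase (add the most strongly associated candidate) with a
backward pruning phase. :func:`inter_iapc` then strips the spouses from that
boundary by exhaustive subset search, leaving the parents-and-children set.
Under a reliable (oracle) test on a faithful distribution both are exact.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable

from .ci_tests import CITest, CITestResult, Dataset

__all__ = ["inter_iamb", "inter_iapc"]


def _dependent(res: CITestResult) -> bool:
    # tests fold the insufficient-data rule into `independent` (an unreliable
    # discrete test reports independence), so the flag alone decides
    return not res.independent


def _association_key(name: str, res: CITestResult) -> tuple:
    # smaller p first, then larger statistic, then name order
    return (res.p_value, -res.statistic, name)


def inter_iamb(
    t: str,
    data: Dataset | None,
    test: CITest,
    alpha: float = 0.05,
    candidates: Iterable[str] | None = None,
) -> set[str]:
    """Estimate the Markov boundary of ``t`` within ``candidates``.

    Forward phase: among candidates found dependent on ``t`` given the
    current estimate, add the one with the strongest association. Backward
    phase (interleaved after every addition): drop any member that the test
    declares independent of ``t`` given the rest of the estimate.
    """
    if candidates is None:
        if data is None:
            raise ValueError("candidates must be given when data is None")
        candidates = [c for c in data.column_names if c != t]
    pool = sorted(set(candidates))
    if t in pool:
        raise ValueError("target must not be a candidate")

    mb: list[str] = []
    seen_states: set[frozenset[str]] = {frozenset()}
    while True:
        best: str | None = None
        best_key = None
        ctx = frozenset(mb)
        for c in pool:
            if c in ctx:
                continue
            res = test(data, t, c, ctx, alpha)
            if not _dependent(res):
                continue
            key = _association_key(c, res)
            if best_key is None or key < best_key:
                best, best_key = c, key
        if best is None:
            break
        mb.append(best)
        # interleaved backward pass over earlier members
        for y in sorted(mb):
            rest = frozenset(m for m in mb if m != y)
            if not _dependent(test(data, t, y, rest, alpha)):
                mb.remove(y)
        # noisy tests can oscillate (backward undoes forward and the same
        # candidate is re-added); stop on the first repeated state
        state = frozenset(mb)
        if state in seen_states:
            break
        seen_states.add(state)
    return set(mb)


def inter_iapc(
    t: str,
    data: Dataset | None,
    test: CITest,
    alpha: float = 0.05,
    candidates: Iterable[str] | None = None,
    max_subset_size: int | None = None,
    sepsets=None,
) -> set[str]:
    """Estimate the parents-and-children set of ``t`` within ``candidates``.

    Learns the Markov boundary first, then removes every member that can be
    separated from ``t`` by some subset of the remaining boundary (those are
    the spouses). ``max_subset_size`` optionally caps the subset search;
    boundaries are small so the default searches exhaustively.

    ``sepsets`` may be a :class:`rhpcbn.hpc.SepsetCache` (anything with a
    ``put(x, y, z)`` method): each separating set found by the removal search
    is recorded there, which is what later makes v-structure orientation
    possible for pairs whose minimal separator is larger than the superset
    routines' |Z| <= 2 budget.
    """
    mb = inter_iamb(t, data, test, alpha, candidates)
    pc = set(mb)
    for x in sorted(mb):
        others = sorted(mb - {x})
        cap = len(others) if max_subset_size is None else min(max_subset_size, len(others))
        separator: frozenset[str] | None = None
        for size in range(cap + 1):
            for z in combinations(others, size):
                res = test(data, t, x, frozenset(z), alpha)
                if res.independent:
                    separator = frozenset(z)
                    break
            if separator is not None:
                break
        if separator is not None:
            pc.discard(x)
            if sepsets is not None:
                sepsets.put(t, x, separator)
    return pc
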