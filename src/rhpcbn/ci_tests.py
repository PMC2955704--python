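"""Conditional-independence decision procedures.

Three interchangeable tests share one calling convention
``test(data, x, y, z, alpha) -> CITestResult``:

* :func:`g2_test` — likelihood-ratio G² (or Pearson χ²) on discrete data,
* :func:`fisher_z_test` — Fisher z-transform of the partial correlation on
  continuous data,
* :func:`oracle_test` — the idealized reliable test that answers with
  d-separation in a known DAG (used for validation and sample-limit checks).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd
import yaml
from scipy import special

from .graph_core import DirectedGraph, d_separated

__all__ = [
    "Dataset",
    "CITestResult",
    "CITest",
    "g2_test",
    "pearson_chi2_test",
    "fisher_z_test",
    "oracle_test",
    "MemoizedTest",
    "read_csv",
]

#: rows required per degree of freedom for a discrete test to be trusted
DEFAULT_RELIABILITY_RATIO = 10.0


@dataclass(frozen=True)
class CITestResult:
    statistic: float
    dof: int
    p_value: float
    independent: bool
    reliable: bool


@dataclass
class Dataset:
    """Fully observed tabular data: discrete category codes or reals.

    ``arities`` is present iff the data are discrete; codes must then lie in
    ``[0, arity)`` per column. No missing values are allowed.
    """

    column_names: list[str]
    values: np.ndarray  # (n_rows, n_cols)
    arities: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_names):
            raise ValueError("values must be n_rows x n_cols matching column_names")
        if np.issubdtype(self.values.dtype, np.floating) and not np.isfinite(self.values).all():
            raise ValueError("dataset contains missing or non-finite values")
        if self.arities is not None:
            self.values = np.ascontiguousarray(self.values, dtype=np.int64)
            for j, name in enumerate(self.column_names):
                r = self.arities[name]
                col = self.values[:, j]
                if col.size and (col.min() < 0 or col.max() >= r):
                    raise ValueError(f"column {name!r} has codes outside [0, {r})")
        self._col_index = {name: j for j, name in enumerate(self.column_names)}

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def is_discrete(self) -> bool:
        return self.arities is not None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self._index(name)]

    def _index(self, name: str) -> int:
        try:
            return self._col_index[name]
        except KeyError:
            raise KeyError(f"unknown column {name!r}") from None

    def arity(self, name: str) -> int:
        if self.arities is None:
            raise TypeError("continuous dataset has no arities")
        return self.arities[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)


CITest = Callable[[Dataset, str, str, frozenset], CITestResult]


# ---------------------------------------------------------------------------
# Discrete tests
# ---------------------------------------------------------------------------


def _contingency(data: Dataset, x: str, y: str, z: Iterable[str]):
    """Return observed counts as an array of shape (n_strata, r_x, r_y)."""
    xs = data.column(x)
    ys = data.column(y)
    rx, ry = data.arity(x), data.arity(y)
    n_strata = 1
    flat = xs * ry + ys
    for zc in sorted(z):
        rz = data.arity(zc)
        flat = data.column(zc) * (n_strata * rx * ry) + flat
        n_strata *= rz
    counts = np.bincount(flat, minlength=n_strata * rx * ry)
    return counts.reshape(n_strata, rx, ry), rx, ry, n_strata


def _discrete_test(
    data: Dataset,
    x: str,
    y: str,
    z: Iterable[str],
    alpha: float,
    statistic_kind: str,
    reliability_ratio: float,
) -> CITestResult:
    if not data.is_discrete:
        raise TypeError("discrete test requires a discrete dataset")
    zset = frozenset(z)
    if x == y or x in zset or y in zset:
        raise ValueError("x, y and z must be distinct")
    rx, ry = data.arity(x), data.arity(y)
    full_dof = (rx - 1) * (ry - 1)
    for zc in zset:
        full_dof *= data.arity(zc)

    if reliability_ratio and data.n_rows < reliability_ratio * full_dof:
        # insufficient data: refuse to reject independence
        return CITestResult(statistic=0.0, dof=full_dof, p_value=1.0,
                            independent=True, reliable=False)

    obs, rx, ry, _ = _contingency(data, x, y, zset)
    rows = obs.sum(axis=2, keepdims=True).astype(float)   # (s, rx, 1)
    cols = obs.sum(axis=1, keepdims=True).astype(float)   # (s, 1, ry)
    n_s = obs.sum(axis=(1, 2), keepdims=True).astype(float)

    # zero-margin strata (x or y constant within the stratum) carry no
    # information: they add nothing to the statistic or the dof
    ok = (np.count_nonzero(rows[:, :, 0], axis=1) >= 2) & \
         (np.count_nonzero(cols[:, 0, :], axis=1) >= 2)
    dof = int(ok.sum()) * (rx - 1) * (ry - 1)
    if dof == 0:
        return CITestResult(statistic=0.0, dof=0, p_value=1.0,
                            independent=True, reliable=False)

    with np.errstate(divide="ignore", invalid="ignore"):
        expected = rows * cols / n_s
        if statistic_kind == "g2":
            term = obs * np.log(obs / expected)
            term[obs == 0] = 0.0
            stat = 2.0 * term[ok].sum()
        else:
            term = (obs - expected) ** 2 / expected
            term[expected == 0] = 0.0
            stat = term[ok].sum()
    stat = float(max(stat, 0.0))
    p = float(special.chdtrc(dof, stat))
    return CITestResult(statistic=stat, dof=dof, p_value=p,
                        independent=p > alpha, reliable=True)


def g2_test(
    data: Dataset,
    x: str,
    y: str,
    z: Iterable[str] = (),
    alpha: float = 0.05,
    reliability_ratio: float = DEFAULT_RELIABILITY_RATIO,
) -> CITestResult:
    """Likelihood-ratio G² test of ``x`` independent of ``y`` given ``z``.

    The statistic is ``2 * sum(observed * ln(observed / expected))`` over the
    x-by-y cells of every stratum of ``z``; zero cells contribute nothing.
    When fewer than ``reliability_ratio`` rows per degree of freedom are
    available the test is deemed unreliable and returns independence.
    """
    return _discrete_test(data, x, y, z, alpha, "g2", reliability_ratio)


def pearson_chi2_test(
    data: Dataset,
    x: str,
    y: str,
    z: Iterable[str] = (),
    alpha: float = 0.05,
    reliability_ratio: float = DEFAULT_RELIABILITY_RATIO,
) -> CITestResult:
    """Pearson χ² variant of the discrete conditional-independence test."""
    return _discrete_test(data, x, y, z, alpha, "chi2", reliability_ratio)


# ---------------------------------------------------------------------------
# Continuous test
# ---------------------------------------------------------------------------


def fisher_z_test(
    data: Dataset,
    x: str,
    y: str,
    z: Iterable[str] = (),
    alpha: float = 0.05,
) -> CITestResult:
    """Fisher z test of zero partial correlation of ``x``, ``y`` given ``z``."""
    if data.is_discrete:
        raise TypeError("fisher_z_test requires a continuous dataset")
    zset = frozenset(z)
    if x == y or x in zset or y in zset:
        raise ValueError("x, y and z must be distinct")
    n = data.n_rows
    k = len(zset)
    if n <= k + 3:
        raise ValueError("need n_rows > |z| + 3")

    cols = [x, y] + sorted(zset)
    mat = np.column_stack([data.column(c) for c in cols]).astype(float)
    corr = np.corrcoef(mat, rowvar=False)
    if not np.isfinite(corr).all():
        return CITestResult(statistic=np.inf, dof=0, p_value=0.0,
                            independent=False, reliable=False)
    try:
        prec = np.linalg.pinv(corr)
        r = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
    except np.linalg.LinAlgError:
        r = 1.0
    if abs(r) >= 1.0 - 1e-12:
        return CITestResult(statistic=np.inf, dof=0, p_value=0.0,
                            independent=False, reliable=False)
    zstat = np.sqrt(n - k - 3) * 0.5 * np.log((1 + r) / (1 - r))
    p = float(special.erfc(abs(zstat) / np.sqrt(2)))
    return CITestResult(statistic=float(abs(zstat)), dof=0, p_value=p,
                        independent=p > alpha, reliable=True)


# ---------------------------------------------------------------------------
# Oracle test
# ---------------------------------------------------------------------------


def oracle_test(g: DirectedGraph) -> CITest:
    """Return a reliable test function answering with d-separation in ``g``.

    The returned callable has the standard test signature; the dataset
    argument is ignored (``None`` is accepted).
    """

    def test(data: Dataset | None, x: str, y: str, z: Iterable[str] = (),
             alpha: float = 0.05) -> CITestResult:
        indep = d_separated(g, x, y, frozenset(z))
        return CITestResult(statistic=0.0 if indep else np.inf, dof=0,
                            p_value=1.0 if indep else 0.0,
                            independent=indep, reliable=True)

    return test


class MemoizedTest:
    """Cache test results per (pair, conditioning set, alpha).

    Tests are symmetric in x and y and deterministic for a fixed dataset, so
    a whole-network learner (which revisits the same pair from both
    endpoints) can safely share results. Use one instance per dataset.
    """

    def __init__(self, test: CITest) -> None:
        self.test = test
        self.hits = 0
        self._cache: dict[tuple, CITestResult] = {}

    def __call__(self, data: Dataset | None, x: str, y: str,
                 z: Iterable[str] = (), alpha: float = 0.05) -> CITestResult:
        zset = frozenset(z)
        key = (frozenset((x, y)), zset, alpha)
        res = self._cache.get(key)
        if res is None:
            res = self.test(data, x, y, zset, alpha)
            self._cache[key] = res
        else:
            self.hits += 1
        return res

    def __len__(self) -> int:
        return len(self._cache)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_csv(path: str | Path | io.TextIOBase, schema: str | Path | dict | None = None) -> Dataset:
    """Read a headered CSV into a :class:`Dataset`.

    Without a schema, a table whose columns are all integer-valued is treated
    as discrete (arity = max code + 1 per column); otherwise as continuous.
    A YAML schema may declare per-column ``{discrete: <arity>}`` or
    ``continuous`` to override detection.
    """
    df = pd.read_csv(path)
    if df.isna().any().any():
        raise ValueError("dataset contains missing values")
    names = [str(c) for c in df.columns]

    decl: dict = {}
    if schema is not None:
        if isinstance(schema, dict):
            decl = schema
        else:
            decl = yaml.safe_load(Path(schema).read_text())

    if decl:
        kinds = set()
        for name in names:
            spec = decl.get(name, "continuous")
            kinds.add("continuous" if spec == "continuous" else "discrete")
        if kinds == {"discrete"}:
            arities = {}
            for name in names:
                spec = decl[name]
                arities[name] = int(spec["discrete"]) if isinstance(spec, dict) \
                    else int(df[name].max()) + 1
            return Dataset(names, df.to_numpy(dtype=np.int64), arities)
        if kinds == {"continuous"}:
            return Dataset(names, df.to_numpy(dtype=float), None)
        raise ValueError("mixed discrete/continuous datasets are not supported")

    all_int = all(pd.api.types.is_integer_dtype(df[c]) for c in df.columns)
    if all_int:
        arities = {name: int(df[name].max()) + 1 for name in names}
        return Dataset(names, df.to_numpy(dtype=np.int64), arities)
    return Dataset(names, df.to_numpy(dtype=float), None)
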