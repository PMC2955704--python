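from __future__ import annotations

import io
import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from rhpcbn.ci_tests import (
    Dataset,
    fisher_z_test,
    g2_test,
    oracle_test,
    pearson_chi2_test,
    read_csv,
)
from rhpcbn.graph_core import d_separated

from .oracles import dsep_by_path_enumeration

# hand-computed oracle for the 2x2 table [[10, 20], [20, 10]], n = 60:
# margins are 30/30 each way so every expected cell is 15
# G2   = 2 * (2 * 10 ln(10/15) + 2 * 20 ln(20/15))
# chi2 = 4 * (5^2 / 15) = 20/3
G2_2X2 = 2 * (2 * 10 * math.log(10 / 15) + 2 * 20 * math.log(20 / 15))
CHI2_2X2 = 20 / 3


def table_2x2() -> Dataset:
    rows = [[0, 0]] * 10 + [[0, 1]] * 20 + [[1, 0]] * 20 + [[1, 1]] * 10
    return Dataset(["x", "y"], np.array(rows), {"x": 2, "y": 2})


class TestDataset:
    def test_rejects_out_of_range_codes(self):
        with pytest.raises(ValueError):
            Dataset(["a"], np.array([[3]]), {"a": 2})

    def test_rejects_nan(self):
        with pytest.raises(ValueError):
            Dataset(["a"], np.array([[np.nan]]), None)

    def test_shape_check(self):
        with pytest.raises(ValueError):
            Dataset(["a", "b"], np.zeros((3, 1)), None)


class TestG2:
    def test_perfect_dependence(self, rng):
        x = rng.integers(0, 2, size=1000)
        d = Dataset(["x", "y"], np.column_stack([x, x]), {"x": 2, "y": 2})
        res = g2_test(d, "x", "y")
        assert not res.independent
        assert res.p_value < 1e-12

    def test_hand_computed_2x2(self):
        res = g2_test(table_2x2(), "x", "y", alpha=0.05)
        assert res.statistic == pytest.approx(G2_2X2, rel=1e-12)
        assert res.dof == 1
        assert not res.independent
        assert res.p_value == pytest.approx(stats.chi2.sf(G2_2X2, 1), rel=1e-12)

    def test_pearson_matches_hand_oracle(self):
        res = pearson_chi2_test(table_2x2(), "x", "y", alpha=0.05)
        assert res.statistic == pytest.approx(CHI2_2X2, rel=1e-12)
        assert res.p_value == pytest.approx(0.0098, abs=2e-4)
        assert not res.independent

    def test_symmetric_in_x_y(self, rng):
        v = rng.integers(0, 3, size=(400, 3))
        d = Dataset(["a", "b", "c"], v, {"a": 3, "b": 3, "c": 3})
        r1 = g2_test(d, "a", "b", ("c",))
        r2 = g2_test(d, "b", "a", ("c",))
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.independent == r2.independent

    def test_relabeling_invariance(self, rng):
        v = rng.integers(0, 2, size=(500, 2))
        d1 = Dataset(["a", "b"], v, {"a": 2, "b": 2})
        d2 = Dataset(["a", "b"], np.column_stack([1 - v[:, 0], v[:, 1]]),
                     {"a": 2, "b": 2})
        assert g2_test(d1, "a", "b").statistic == pytest.approx(
            g2_test(d2, "a", "b").statistic)

    def test_dof_formula(self, rng):
        v = np.column_stack([
            rng.integers(0, 2, 4000), rng.integers(0, 3, 4000),
            rng.integers(0, 2, 4000), rng.integers(0, 3, 4000),
        ])
        d = Dataset(list("wxyz"), v, {"w": 2, "x": 3, "y": 2, "z": 3})
        res = g2_test(d, "w", "x", ("y", "z"))
        assert res.dof == (2 - 1) * (3 - 1) * 2 * 3

    def test_insufficient_data_rule(self, rng):
        # 5 rows against dof 1 -> unreliable, forced independent
        v = rng.integers(0, 2, size=(5, 2))
        d = Dataset(["a", "b"], v, {"a": 2, "b": 2})
        res = g2_test(d, "a", "b")
        assert not res.reliable
        assert res.independent

    def test_type_error_on_continuous(self, rng):
        d = Dataset(["a", "b"], rng.normal(size=(50, 2)), None)
        with pytest.raises(TypeError):
            g2_test(d, "a", "b")

    def test_type_one_error_calibration(self, rng):
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            v = rng.integers(0, 2, size=(1000, 2))
            d = Dataset(["a", "b"], v, {"a": 2, "b": 2})
            hits += not g2_test(d, "a", "b", alpha=0.05).independent
        # 99% binomial envelope around alpha
        half = 2.576 * math.sqrt(0.05 * 0.95 / n_rep)
        assert abs(hits / n_rep - 0.05) < half


class TestFisherZ:
    def test_linear_dependence(self, rng):
        x = rng.normal(size=500)
        y = x + 0.1 * rng.normal(size=500)
        d = Dataset(["x", "y"], np.column_stack([x, y]), None)
        assert not fisher_z_test(d, "x", "y").independent

    def test_common_cause_screened_off(self, rng):
        x = rng.normal(size=1000)
        y = x + rng.normal(size=1000)
        w = x + rng.normal(size=1000)
        d = Dataset(["x", "y", "w"], np.column_stack([x, y, w]), None)
        assert not fisher_z_test(d, "y", "w").independent
        assert fisher_z_test(d, "y", "w", ("x",)).independent

    def test_collinear_flagged_unreliable(self, rng):
        x = rng.normal(size=100)
        d = Dataset(["x", "y"], np.column_stack([x, 2 * x]), None)
        res = fisher_z_test(d, "x", "y")
        assert not res.independent
        assert res.p_value == 0.0
        assert not res.reliable

    def test_type_error_on_discrete(self, rng):
        v = rng.integers(0, 2, size=(50, 2))
        d = Dataset(["a", "b"], v, {"a": 2, "b": 2})
        with pytest.raises(TypeError):
            fisher_z_test(d, "a", "b")

    def test_needs_enough_rows(self, rng):
        d = Dataset(["a", "b", "c"], rng.normal(size=(4, 3)), None)
        with pytest.raises(ValueError):
            fisher_z_test(d, "a", "b", ("c",))

    def test_type_one_error_calibration(self, rng):
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            v = rng.normal(size=(1000, 2))
            d = Dataset(["a", "b"], v, None)
            hits += not fisher_z_test(d, "a", "b", alpha=0.05).independent
        half = 2.576 * math.sqrt(0.05 * 0.95 / n_rep)
        assert abs(hits / n_rep - 0.05) < half


class TestOracle:
    def test_collider_and_chain(self, collider_abc, chain_abc):
        orc = oracle_test(collider_abc)
        assert orc(None, "A", "C", frozenset()).independent
        orc2 = oracle_test(chain_abc)
        assert not orc2(None, "A", "C", frozenset()).independent
        assert orc2(None, "A", "C", frozenset("B")).p_value == 1.0

    def test_matches_dsep_everywhere(self, dag_suite):
        for g in dag_suite[:10]:
            orc = oracle_test(g)
            for x, y in combinations(g.nodes, 2):
                others = [n for n in g.nodes if n not in (x, y)]
                for size in range(min(2, len(others)) + 1):
                    for z in combinations(others, size):
                        res = orc(None, x, y, frozenset(z))
                        assert res.independent == d_separated(g, x, y, set(z))
                        assert res.independent == dsep_by_path_enumeration(
                            g, x, y, set(z))
                        assert res.reliable


class TestReadCsv:
    def test_integer_columns_detected_discrete(self):
        csv = "a,b\n0,1\n1,0\n2,1\n"
        d = read_csv(io.StringIO(csv))
        assert d.is_discrete
        assert d.arities == {"a": 3, "b": 2}

    def test_float_columns_detected_continuous(self):
        csv = "a,b\n0.5,1.25\n-1.0,0.0\n"
        d = read_csv(io.StringIO(csv))
        assert not d.is_discrete

    def test_schema_overrides_arity(self, tmp_path):
        data = tmp_path / "d.csv"
        data.write_text("a,b\n0,1\n1,0\n")
        schema = tmp_path / "s.yaml"
        schema.write_text("a: {discrete: 4}\nb: {discrete: 2}\n")
        d = read_csv(data, schema)
        assert d.arities == {"a": 4, "b": 2}

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            read_csv(io.StringIO("a,b\n1,\n0,1\n"))
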