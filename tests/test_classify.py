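"""Relevance filters, cell typing, quartiles, quadrants, and curve fits."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from celltyper.classify import (
    CellTypeDefinition,
    Constraint,
    RelevanceFilter,
    apply_filters,
    classify_cells,
    fit_curve,
    quadrant_counts,
    quartile_thresholds,
)


def _table(**cols):
    n = len(next(iter(cols.values())))
    d = {"cell_id": np.arange(1, n + 1)}
    d.update(cols)
    return pd.DataFrame(d)


class TestFilters:
    def test_area_minimum_excludes_small_cells(self):
        t = apply_filters(
            _table(**{"M1.area": [3.0, 5.0, 12.0]}),
            [RelevanceFilter("M1.area", min=5)],
        )
        assert t["relevant"].tolist() == [False, True, True]

    def test_no_filters_keeps_everything(self):
        t = apply_filters(_table(**{"M1.area": [1.0, 2.0]}), [])
        assert t["relevant"].all()

    def test_point_interval_is_inclusive(self):
        t = apply_filters(
            _table(**{"M1.area": [4.0, 5.0, 6.0]}),
            [RelevanceFilter("M1.area", min=5, max=5)],
        )
        assert t["relevant"].tolist() == [False, True, False]

    def test_unknown_feature_lists_valid_names(self):
        with pytest.raises(ValueError, match="M1.area"):
            apply_filters(_table(**{"M1.area": [1.0]}), [RelevanceFilter("M1.bogus")])


class TestClassify:
    def _foci_table(self):
        return _table(**{
            "M1.mean": [50.0, 50.0, 50.0],
            "M2.mean": [80.0, 80.0, 40.0],
            "M2.foci_count": [9.0, 7.0, 12.0],
        })

    def test_foci_rule_rejects_seven_foci(self):
        types = [CellTypeDefinition("positive", [
            Constraint(left_feature="M2.mean", relation=">", right_feature="M1.mean"),
            Constraint(feature="M2.foci_count", min=8),
        ])]
        out = classify_cells(self._foci_table(), types)
        assert out["cell_type"].tolist() == ["positive", "unknown", "unknown"]

    def test_no_types_means_all_unknown(self):
        out = classify_cells(self._foci_table(), [])
        assert (out["cell_type"] == "unknown").all()

    def test_first_matching_type_wins_and_diagnostics_list_all(self):
        t = _table(**{"M1.area": [10.0]})
        types = [
            CellTypeDefinition("A", [Constraint(feature="M1.area", min=5)]),
            CellTypeDefinition("B", [Constraint(feature="M1.area", min=1)]),
        ]
        out = classify_cells(t, types)
        assert out.loc[0, "cell_type"] == "A"
        assert out.loc[0, "all_matching_types"] == "A|B"

    def test_irrelevant_cells_are_excluded(self):
        t = apply_filters(
            _table(**{"M1.area": [1.0, 10.0]}), [RelevanceFilter("M1.area", min=5)]
        )
        out = classify_cells(t, [CellTypeDefinition("A", [Constraint(feature="M1.area", min=0)])])
        assert out["cell_type"].tolist() == ["excluded", "A"]

    def test_constraint_on_missing_column_rejected(self):
        with pytest.raises(ValueError, match="unknown feature"):
            classify_cells(
                _table(**{"M1.area": [1.0]}),
                [CellTypeDefinition("A", [Constraint(feature="M3.mean", min=0)])],
            )

    def test_brute_force_equivalence_on_random_tables(self):
        """First-match classification agrees with a naive cells x types x
        constraints triple loop on 200 randomized tables/configs."""
        rng = np.random.default_rng(99)
        cols = ["M1.area", "M1.circularity", "M2.mean", "M2.foci_count"]
        rels = ["<", "<=", ">", ">="]
        for trial in range(200):
            n = int(rng.integers(1, 15))
            t = _table(**{c: rng.uniform(0, 100, n).round(1) for c in cols})
            t["relevant"] = rng.random(n) > 0.2
            types = []
            for k in range(int(rng.integers(0, 4))):
                constraints = []
                for _ in range(int(rng.integers(1, 4))):
                    if rng.random() < 0.3:
                        a, b = rng.choice(cols, 2, replace=False)
                        constraints.append(Constraint(
                            left_feature=a, relation=str(rng.choice(rels)), right_feature=b,
                        ))
                    else:
                        lo, hi = np.sort(rng.uniform(0, 100, 2).round(1))
                        constraints.append(Constraint(feature=str(rng.choice(cols)), min=lo, max=hi))
                types.append(CellTypeDefinition(f"T{k}", constraints))
            out = classify_cells(t, types)

            # naive evaluator
            ops = {"<": lambda a, b: a < b, "<=": lambda a, b: a <= b,
                   ">": lambda a, b: a > b, ">=": lambda a, b: a >= b}
            for i, row in t.iterrows():
                if not row["relevant"]:
                    expect = "excluded"
                else:
                    expect = "unknown"
                    for ty in types:
                        sat = True
                        for c in ty.constraints:
                            if c.is_comparison:
                                sat &= ops[c.relation](row[c.left_feature], row[c.right_feature])
                            else:
                                sat &= c.min <= row[c.feature] <= c.max
                            if not sat:
                                break
                        if sat:
                            expect = ty.name
                            break
                assert out.loc[i, "cell_type"] == expect, f"trial {trial} cell {i}"

            # partition invariant
            counts = out["cell_type"].value_counts()
            assert counts.sum() == len(t)

    def test_adding_constraints_and_filters_is_monotone(self):
        rng = np.random.default_rng(17)
        t = _table(**{"M1.area": rng.uniform(0, 100, 50)})
        base = [Constraint(feature="M1.area", min=20)]
        more = base + [Constraint(feature="M1.area", max=70)]
        n_base = (classify_cells(t, [CellTypeDefinition("A", base)])["cell_type"] == "A").sum()
        n_more = (classify_cells(t, [CellTypeDefinition("A", more)])["cell_type"] == "A").sum()
        assert n_more <= n_base
        r0 = apply_filters(t, [])["relevant"].sum()
        r1 = apply_filters(t, [RelevanceFilter("M1.area", min=10)])["relevant"].sum()
        assert r1 <= r0


class TestQuartiles:
    def test_q1_q3_of_1_to_100(self):
        t = _table(v=np.arange(1.0, 101.0))
        q1, q2, q3 = quartile_thresholds(t, "v")
        assert q1 == pytest.approx(25.75)
        assert q3 == pytest.approx(75.25)
        # Q4 membership: value >= Q3
        assert 80 >= q3

    def test_degenerate_all_equal(self):
        t = _table(v=[5.0] * 8)
        q1, q2, q3 = quartile_thresholds(t, "v")
        assert q1 == q2 == q3 == 5.0
        assert 5.0 >= q3  # that value is "in Q4" under inclusive bounds

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="4 relevant cells"):
            quartile_thresholds(_table(v=[1.0, 2.0, 3.0]), "v")

    def test_only_relevant_cells_enter(self):
        t = _table(v=np.arange(1.0, 9.0))
        t["relevant"] = [True] * 4 + [False] * 4
        q1, q2, q3 = quartile_thresholds(t, "v")
        assert q3 == pytest.approx(np.quantile([1, 2, 3, 4], 0.75))


class TestQuadrants:
    def test_one_cell_per_quadrant(self):
        t = _table(x=[1.0, 1.0, 9.0, 9.0], y=[1.0, 9.0, 1.0, 9.0])
        q = quadrant_counts(t, "x", "y", 5, 5)
        assert q.counts == (1, 1, 1, 1)

    def test_all_below_both(self):
        t = _table(x=[1.0, 2.0, 3.0], y=[1.0, 2.0, 3.0])
        assert quadrant_counts(t, "x", "y", 10, 10).counts == (3, 0, 0, 0)

    def test_value_at_threshold_counts_high(self):
        t = _table(x=[5.0], y=[1.0])
        q = quadrant_counts(t, "x", "y", 5, 5)
        assert q.n_hl == 1

    def test_counts_sum_to_relevant_under_random_thresholds(self):
        rng = np.random.default_rng(21)
        t = _table(x=rng.uniform(0, 10, 40), y=rng.uniform(0, 10, 40))
        t["relevant"] = rng.random(40) > 0.3
        for _ in range(20):
            tx, ty = rng.uniform(-1, 11, 2)
            q = quadrant_counts(t, "x", "y", tx, ty)
            assert sum(q.counts) == t["relevant"].sum()


class TestFitCurve:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        fit = fit_curve(x, 2 * x + 1, "linear")
        assert fit["params"]["slope"] == pytest.approx(2.0)
        assert fit["params"]["intercept"] == pytest.approx(1.0)
        assert fit["r_squared"] == pytest.approx(1.0)

    def test_exponential_parameters_recovered(self):
        x = np.linspace(0, 5, 6)
        y = 2.0 * np.exp(0.5 * x)
        fit = fit_curve(x, y, "exponential")
        assert fit["params"]["a"] == pytest.approx(2.0, abs=1e-6)
        assert fit["params"]["b"] == pytest.approx(0.5, abs=1e-6)

    def test_power_parameters_recovered(self):
        x = np.linspace(1, 9, 9)
        y = 3.0 * x**1.7
        fit = fit_curve(x, y, "power")
        assert fit["params"]["a"] == pytest.approx(3.0, abs=1e-6)
        assert fit["params"]["b"] == pytest.approx(1.7, abs=1e-6)

    def test_polynomial_interpolates(self):
        x = np.arange(5.0)
        y = 1 + 2 * x - 0.5 * x**2
        fit = fit_curve(x, y, "polynomial", degree=2)
        assert fit["r_squared"] == pytest.approx(1.0)
        assert fit["params"]["c2"] == pytest.approx(-0.5)

    def test_logarithmic_domain_violation(self):
        with pytest.raises(ValueError, match="x > 0"):
            fit_curve(np.array([0.0, 1, 2]), np.array([1.0, 2, 3]), "logarithmic")

    def test_exponential_domain_violation(self):
        with pytest.raises(ValueError, match="y > 0"):
            fit_curve(np.array([1.0, 2, 3]), np.array([1.0, -2, 3]), "exponential")

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least"):
            fit_curve(np.array([1.0]), np.array([1.0]), "linear")
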