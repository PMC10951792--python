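"""Relevance filtering, rule-based cell typing, and feature-pair reports.

Cell types are named conjunctions of constraints over any marker's
features; constraints are inclusive intervals or cross-feature
comparisons. Relevant cells (those passing every Marker I filter) are
assigned the first type, in definition order, whose constraints all hold;
otherwise they are labeled ``unknown``. Cells failing a filter are
``excluded`` and never classified. A diagnostic column records every type
a cell matches, so first-match tie-breaking stays inspectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RelevanceFilter",
    "Constraint",
    "CellTypeDefinition",
    "QuadrantCounts",
    "apply_filters",
    "classify_cells",
    "quartile_thresholds",
    "quadrant_counts",
    "fit_curve",
    "CURVE_MODELS",
]

_RELATIONS = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
}


@dataclass(frozen=True)
class RelevanceFilter:
    """Inclusive interval filter on a Marker I feature."""

    feature: str
    min: float = -math.inf
    max: float = math.inf

    def __post_init__(self) -> None:
        if self.min > self.max:
            raise ValueError(f"filter on {self.feature}: min > max")


@dataclass(frozen=True)
class Constraint:
    """Interval constraint (``feature`` within [min, max], inclusive) or a
    cross-feature comparison (``left_feature <relation> right_feature``)."""

    feature: str | None = None
    min: float = -math.inf
    max: float = math.inf
    left_feature: str | None = None
    relation: str | None = None
    right_feature: str | None = None

    def __post_init__(self) -> None:
        if self.feature is not None:
            if self.left_feature or self.right_feature or self.relation:
                raise ValueError("constraint is either interval or comparison, not both")
            if self.min > self.max:
                raise ValueError(f"constraint on {self.feature}: min > max")
        else:
            if not (self.left_feature and self.relation and self.right_feature):
                raise ValueError("comparison constraint needs left, relation, right")
            if self.relation not in _RELATIONS:
                raise ValueError(f"unknown relation '{self.relation}'")

    @property
    def is_comparison(self) -> bool:
        return self.feature is None

    def referenced_features(self) -> list[str]:
        if self.is_comparison:
            return [self.left_feature, self.right_feature]
        return [self.feature]

    def evaluate(self, row: pd.Series) -> bool:
        """Truth value on one cell; missing values never satisfy."""
        if self.is_comparison:
            a, b = row[self.left_feature], row[self.right_feature]
            if pd.isna(a) or pd.isna(b):
                return False
            return bool(_RELATIONS[self.relation](a, b))
        v = row[self.feature]
        if pd.isna(v):
            return False
        return bool(self.min <= v <= self.max)


@dataclass
class CellTypeDefinition:
    name: str
    constraints: list[Constraint]
    color: tuple[int, int, int] = (255, 0, 0)

    def __post_init__(self) -> None:
        if not self.constraints:
            raise ValueError(f"cell type '{self.name}' needs at least one constraint")


@dataclass(frozen=True)
class QuadrantCounts:
    feature_x: str
    feature_y: str
    thr_x: float
    thr_y: float
    n_ll: int
    n_lh: int
    n_hl: int
    n_hh: int

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.n_ll, self.n_lh, self.n_hl, self.n_hh)


def _require_columns(table: pd.DataFrame, names: list[str], context: str) -> None:
    valid = [c for c in table.columns if c not in ("relevant", "cell_type", "all_matching_types")]
    for name in names:
        if name not in table.columns:
            raise ValueError(
                f"{context}: unknown feature '{name}'; valid names: " + ", ".join(valid)
            )


def apply_filters(table: pd.DataFrame, filters: list[RelevanceFilter]) -> pd.DataFrame:
    """Flag relevant cells: those satisfying every filter, bounds inclusive.

    Returns a copy of the table with a boolean ``relevant`` column. With no
    filters every cell is relevant.
    """
    _require_columns(table, [f.feature for f in filters], "relevance filter")
    out = table.copy()
    relevant = pd.Series(True, index=table.index)
    for f in filters:
        col = table[f.feature]
        relevant &= col.notna() & (col >= f.min) & (col <= f.max)
    out["relevant"] = relevant
    return out


def classify_cells(table: pd.DataFrame, types: list[CellTypeDefinition]) -> pd.DataFrame:
    """Assign a cell-type label to every cell.

    Relevant cells get the first type (definition order) whose constraints
    all hold, else ``unknown``; irrelevant cells are ``excluded``. The
    ``all_matching_types`` column lists every satisfied type separated by
    ``|`` for diagnostics.
    """
    names = [t.name for t in types]
    if len(set(names)) != len(names):
        raise ValueError("cell type names must be unique")
    for t in types:
        for c in t.constraints:
            _require_columns(table, c.referenced_features(), f"cell type '{t.name}'")
    out = table.copy()
    if "relevant" not in out.columns:
        out["relevant"] = True
    labels, matches = [], []
    for _, row in out.iterrows():
        if not row["relevant"]:
            labels.append("excluded")
            matches.append("")
            continue
        matched = [
            t.name for t in types if all(c.evaluate(row) for c in t.constraints)
        ]
        labels.append(matched[0] if matched else "unknown")
        matches.append("|".join(matched))
    out["cell_type"] = labels
    out["all_matching_types"] = matches
    return out


def quartile_thresholds(table: pd.DataFrame, feature: str) -> tuple[float, float, float]:
    """Type-7 quartiles (Q1, Q2, Q3) of a feature over relevant cells.

    Intended for quartile-based typing recipes: "in Q4" means value >= Q3,
    "in Q1" means value <= Q1, "interquartile" means Q1 < value < Q3.
    """
    _require_columns(table, [feature], "quartile thresholds")
    values = table[feature]
    if "relevant" in table.columns:
        values = values[table["relevant"]]
    values = values.dropna()
    if len(values) < 4:
        raise ValueError(
            f"quartile thresholds on '{feature}' need >= 4 relevant cells, got {len(values)}"
        )
    q1, q2, q3 = np.quantile(values.to_numpy(), [0.25, 0.5, 0.75])
    return float(q1), float(q2), float(q3)


def quadrant_counts(
    table: pd.DataFrame,
    feature_x: str,
    feature_y: str,
    thr_x: float,
    thr_y: float,
) -> QuadrantCounts:
    """Count relevant cells in the four quadrants of a feature pair.

    A cell is "high" on an axis iff its value >= the threshold. Only
    relevant cells with both features present are counted; the four counts
    sum to that number.
    """
    _require_columns(table, [feature_x, feature_y], "quadrant counts")
    sub = table
    if "relevant" in table.columns:
        sub = table[table["relevant"]]
    sub = sub.dropna(subset=[feature_x, feature_y])
    hx = sub[feature_x] >= thr_x
    hy = sub[feature_y] >= thr_y
    return QuadrantCounts(
        feature_x=feature_x, feature_y=feature_y, thr_x=thr_x, thr_y=thr_y,
        n_ll=int((~hx & ~hy).sum()),
        n_lh=int((~hx & hy).sum()),
        n_hl=int((hx & ~hy).sum()),
        n_hh=int((hx & hy).sum()),
    )


CURVE_MODELS = ("linear", "polynomial", "power", "logarithmic", "exponential")


def fit_curve(
    x: np.ndarray,
    y: np.ndarray,
    model: str = "linear",
    degree: int = 2,
) -> dict:
    """Least-squares fit of a named model; returns parameters and R².

    Models: ``linear`` (y = a·x + b), ``polynomial`` of given degree,
    ``power`` (y = a·x^b, fit by log–log linearization), ``logarithmic``
    (y = a + b·ln x), ``exponential`` (y = a·e^(b·x), fit by semilog
    linearization). R² is always evaluated on the original y scale.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if model not in CURVE_MODELS:
        raise ValueError(f"unknown model '{model}'; valid: {', '.join(CURVE_MODELS)}")
    n_params = degree + 1 if model == "polynomial" else 2
    if x.size != y.size or x.size < n_params:
        raise ValueError(f"need at least {n_params} points for model '{model}'")
    if model in ("power", "logarithmic") and (x <= 0).any():
        bad = np.nonzero(x <= 0)[0][:5].tolist()
        raise ValueError(f"model '{model}' requires x > 0; offending points at indices {bad}")
    if model in ("power", "exponential") and (y <= 0).any():
        bad = np.nonzero(y <= 0)[0][:5].tolist()
        raise ValueError(f"model '{model}' requires y > 0; offending points at indices {bad}")

    if model == "linear":
        b, a = np.polynomial.polynomial.polyfit(x, y, 1)
        params = {"slope": float(a), "intercept": float(b)}
        y_hat = a * x + b
    elif model == "polynomial":
        coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
        params = {f"c{i}": float(c) for i, c in enumerate(coeffs)}
        y_hat = np.polynomial.polynomial.polyval(x, coeffs)
    elif model == "power":
        lb, slope = np.polynomial.polynomial.polyfit(np.log(x), np.log(y), 1)
        params = {"a": float(np.exp(lb)), "b": float(slope)}
        y_hat = params["a"] * x ** params["b"]
    elif model == "logarithmic":
        a, b = np.polynomial.polynomial.polyfit(np.log(x), y, 1)
        params = {"a": float(a), "b": float(b)}
        y_hat = a + b * np.log(x)
    else:  # exponential
        la, slope = np.polynomial.polynomial.polyfit(x, np.log(y), 1)
        params = {"a": float(np.exp(la)), "b": float(slope)}
        y_hat = params["a"] * np.exp(params["b"] * x)

    ss_res = float(((y - y_hat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return {"model": model, "params": params, "r_squared": r2}
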