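"""Single-image and batch execution of a configured analysis.

``run_single`` composes the whole pipeline for one image — load, marker
matching, ROI crop, preprocessing, auto-threshold segmentation, labeling,
feature extraction on Marker I, secondary-marker measurement, relevance
filtering, cell typing, and report generation — reading every choice from
an :class:`~celltyper.config.AnalysisConfig`. ``run_batch`` maps it over a
directory in lexicographic filename order, isolating per-image failures,
and writes a set-level summary.

All tables are CSV with values printed at 6 significant digits, preceded
by a header comment stating the coordinate convention, so repeated runs
are byte-identical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from celltyper import classify as _classify
from celltyper.config import AnalysisConfig, ConstraintSpec
from celltyper.features import extract_features, summarize
from celltyper.imgio import (
    MarkerImage,
    MarkerRole,
    RegionOfInterest,
    channel_histogram,
    crop_to_roi,
    load_image,
    match_channels,
    rescale_to_8bit,
    threshold_to_native,
)
from celltyper.preprocess import apply_chain
from celltyper.regions import RegionResizeSpec, measure_marker
from celltyper.segment import auto_threshold, binarize, fill_holes, label_cells, watershed_split

__all__ = ["run_single", "run_batch", "SingleResult", "BatchResult"]

logger = logging.getLogger("celltyper")

_COORD_HEADER = "# coordinates: x = column, y = row, 0-based, origin top-left\n"
_IMAGE_SUFFIXES = (".tif", ".tiff", ".png")


@dataclass
class SingleResult:
    image: str
    table: pd.DataFrame
    n_cells: int
    n_relevant: int
    type_counts: dict[str, int]
    threshold: float
    quadrants: _classify.QuadrantCounts | None = None
    fit: dict | None = None


@dataclass
class BatchResult:
    summary: pd.DataFrame
    results: list[SingleResult] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_COORD_HEADER)
        df.to_csv(fh, index=index, float_format="%.6g", lineterminator="\n")


def _build_roi(config: AnalysisConfig, shape: tuple[int, int]) -> RegionOfInterest | None:
    roi = config.roi
    if roi.type == "none":
        return None
    if roi.type == "rectangle":
        return RegionOfInterest.rectangle(int(roi.x), int(roi.y), int(roi.w), int(roi.h), shape)
    if roi.type == "ellipse":
        return RegionOfInterest.ellipse(roi.cx, roi.cy, roi.rx, roi.ry, shape)
    return RegionOfInterest.polygon(roi.points, shape)


def _resolve_bound(bound: float | str, table: pd.DataFrame) -> float:
    if not isinstance(bound, str):
        return bound
    from celltyper.config import _QUARTILE_RE

    m = _QUARTILE_RE.match(bound)
    if not m:
        raise ValueError(f"malformed quartile bound '{bound}'")
    q1, q2, q3 = _classify.quartile_thresholds(table, m.group(2))
    return {"Q1": q1, "Q2": q2, "Q3": q3}[m.group(1)]


def _resolve_constraint(spec: ConstraintSpec, table: pd.DataFrame) -> _classify.Constraint:
    if spec.is_comparison:
        return _classify.Constraint(
            left_feature=spec.left_feature,
            relation=spec.relation,
            right_feature=spec.right_feature,
        )
    return _classify.Constraint(
        feature=spec.feature,
        min=_resolve_bound(spec.min, table),
        max=_resolve_bound(spec.max, table),
    )


def run_single(
    image_path: str | Path,
    config: AnalysisConfig,
    out_dir: str | Path | None = None,
) -> SingleResult:
    """Run the full configured analysis on one image.

    Writes ``cells.csv``, ``classification.csv``, ``summary.csv`` and any
    configured report tables into ``out_dir`` when given. Deterministic
    for fixed inputs.
    """
    image_path = Path(image_path)
    config.validate()
    planes = load_image(image_path)
    mapping = {
        idx: role for (key, idx), role in zip(
            config.channels.items(), config.mapped_roles().values()
        )
    }
    markers = match_channels(planes, mapping, config.calibration)

    any_marker = markers[MarkerRole.MARKER_I]
    roi = _build_roi(config, any_marker.shape)
    offset = (0, 0)
    if roi is not None:
        markers, offset = crop_to_roi(markers, roi)

    raw_m1 = markers[MarkerRole.MARKER_I]
    seg_plane = apply_chain(raw_m1, config.preprocess)

    hist = channel_histogram(seg_plane)
    t8 = auto_threshold(hist, config.segment_method)
    t_native = threshold_to_native(t8, seg_plane)
    mask = binarize(seg_plane, t_native, config.dark_background)
    if config.fill_holes:
        mask = fill_holes(mask)
    if config.watershed:
        mask = watershed_split(mask)
    label_map, contours = label_cells(mask)
    logger.info(
        "%s: method=%s threshold=%g cells=%d",
        image_path.name, config.segment_method, t_native, label_map.n_cells,
    )

    table = extract_features(label_map, contours, raw_m1, config.calibration, offset)

    for key, role, prefix in (
        ("markerII", MarkerRole.MARKER_II, "M2"),
        ("markerIII", MarkerRole.MARKER_III, "M3"),
    ):
        if role not in markers:
            continue
        spec = getattr(config, key)
        cols = measure_marker(
            label_map,
            markers[role],
            RegionResizeSpec(mode=spec.resize_mode, radius=spec.resize_radius),
            foci_enabled=spec.foci_enabled,
            tolerance=spec.foci_tolerance,
            calibration=config.calibration,
            presmooth_sigma=spec.presmooth_sigma,
        )
        if len(table):
            table = table.merge(cols, on="cell_id", how="left")
        else:
            for c in cols.columns:
                if c != "cell_id":
                    table[c] = pd.Series(dtype=float)

    filters = [
        _classify.RelevanceFilter(feature=f.feature, min=f.min, max=f.max)
        for f in config.filters
    ]
    table = _classify.apply_filters(table, filters)

    resolved_types = [
        _classify.CellTypeDefinition(
            name=ct.name,
            color=ct.color,
            constraints=[_resolve_constraint(c, table) for c in ct.constraints],
        )
        for ct in config.cell_types
    ]
    table = _classify.classify_cells(table, resolved_types)

    n_cells = len(table)
    n_relevant = int(table["relevant"].sum()) if n_cells else 0
    type_counts = {ct.name: 0 for ct in config.cell_types}
    type_counts["unknown"] = 0
    if n_cells:
        for name, cnt in table.loc[table["relevant"], "cell_type"].value_counts().items():
            type_counts[name] = int(cnt)

    quadrants = None
    fit = None
    rep = config.report
    if rep.quadrants_x and rep.quadrants_y and n_relevant:
        quadrants = _classify.quadrant_counts(
            table, rep.quadrants_x, rep.quadrants_y,
            _resolve_bound(rep.quadrants_thr_x, table),
            _resolve_bound(rep.quadrants_thr_y, table),
        )
    if rep.fit_model and rep.scatter_x and rep.scatter_y and n_relevant:
        sub = table[table["relevant"]].dropna(subset=[rep.scatter_x, rep.scatter_y])
        try:
            fit = _classify.fit_curve(
                sub[rep.scatter_x].to_numpy(), sub[rep.scatter_y].to_numpy(),
                rep.fit_model, rep.fit_degree,
            )
        except ValueError as exc:
            logger.warning("%s: curve fit skipped (%s)", image_path.name, exc)

    result = SingleResult(
        image=image_path.name, table=table, n_cells=n_cells,
        n_relevant=n_relevant, type_counts=type_counts,
        threshold=float(t_native), quadrants=quadrants, fit=fit,
    )
    if out_dir is not None:
        _write_outputs(result, config, Path(out_dir))
    return result


def _write_outputs(result: SingleResult, config: AnalysisConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    table = result.table
    _write_csv(table, out_dir / "cells.csv")
    cls_cols = ["cell_id", "relevant", "cell_type", "all_matching_types"]
    if len(table):
        _write_csv(table[cls_cols], out_dir / "classification.csv")
        if table["relevant"].any():
            _write_csv(summarize(table[table["relevant"]]), out_dir / "summary.csv", index=True)
        else:
            (out_dir / "summary.csv").write_text(_COORD_HEADER)
    else:
        _write_csv(pd.DataFrame(columns=cls_cols), out_dir / "classification.csv")
        (out_dir / "summary.csv").write_text(_COORD_HEADER)
    rep = config.report
    if rep.scatter_x and rep.scatter_y and len(table):
        color_map = {ct.name: ct.color for ct in config.cell_types}
        sub = table[table["relevant"]]
        scatter = pd.DataFrame({
            "x": sub[rep.scatter_x],
            "y": sub[rep.scatter_y],
            "cell_type": sub["cell_type"],
            "color": [
                ",".join(map(str, color_map.get(t, (128, 128, 128))))
                for t in sub["cell_type"]
            ],
        })
        _write_csv(scatter, out_dir / "scatter.csv")
    if result.quadrants is not None:
        q = result.quadrants
        _write_csv(pd.DataFrame([{
            "feature_x": q.feature_x, "feature_y": q.feature_y,
            "thr_x": q.thr_x, "thr_y": q.thr_y,
            "n_LL": q.n_ll, "n_LH": q.n_lh, "n_HL": q.n_hl, "n_HH": q.n_hh,
        }]), out_dir / "quadrants.csv")
    if result.fit is not None:
        row = {"model": result.fit["model"], "r_squared": result.fit["r_squared"]}
        row.update(result.fit["params"])
        _write_csv(pd.DataFrame([row]), out_dir / "fit.csv")


def run_batch(
    input_dir: str | Path,
    output_dir: str | Path,
    config: AnalysisConfig,
) -> BatchResult:
    """Run the configured analysis on every supported image in a directory.

    Images are processed in lexicographic filename order; one output folder
    per image plus a set-level ``batch_summary.csv``. Failures on
    individual images are logged, skipped, and recorded in the summary.
    """
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    config.validate()
    images = sorted(
        p for p in input_dir.iterdir()
        if p.is_file() and p.suffix.lower() in _IMAGE_SUFFIXES
    )
    if not images:
        raise ValueError(f"no supported images (TIFF/PNG) found in {input_dir}")
    output_dir.mkdir(parents=True, exist_ok=True)

    results: list[SingleResult] = []
    failures: dict[str, str] = {}
    rows = []
    type_names = [ct.name for ct in config.cell_types]
    for img in images:
        try:
            res = run_single(img, config, output_dir / img.stem)
        except Exception as exc:  # per-image fault isolation
            logger.error("%s: failed (%s)", img.name, exc)
            failures[img.name] = str(exc)
            rows.append({
                "image": img.name, "status": "failed", "n_cells": 0, "n_relevant": 0,
                **{f"n_{t}": 0 for t in type_names}, "n_unknown": 0,
                "error": str(exc),
            })
            continue
        results.append(res)
        rows.append({
            "image": img.name, "status": "ok",
            "n_cells": res.n_cells, "n_relevant": res.n_relevant,
            **{f"n_{t}": res.type_counts.get(t, 0) for t in type_names},
            "n_unknown": res.type_counts.get("unknown", 0),
            "error": "",
        })
    summary = pd.DataFrame(rows)
    _write_csv(summary, output_dir / "batch_summary.csv")
    return BatchResult(summary=summary, results=results, failures=failures)
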