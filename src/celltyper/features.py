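"""Per-cell shape descriptors, intensity statistics, and population summaries.

Feature names are namespaced by marker role in tables: ``M1.area``,
``M2.mean``, ``M3.foci_count``. Shape geometry always comes from the
Marker I segmentation; intensity statistics are computed on the raw pixel
values of the requested marker plane within the cell's pixel set.

Formula conventions (documented so results are reproducible bit-exactly
within this package):

- perimeter: corner-weighted crack-boundary length (the standard weighted
  pixel-configuration approximation).
- circularity = 4*pi*area / perimeter^2, clamped to <= 1.
- roundness = 4*area / (pi * major_axis^2).
- aspect_ratio = major_axis / minor_axis.
- solidity = area / convex hull area.
- ellipse axes/angle from normalized second central moments.
- Feret diameters by rotating calipers over the convex hull of the cell's
  crack-boundary corner points.
- skewness / kurtosis: population moments, kurtosis reported as excess;
  both 0 by convention for zero-variance regions.
- mode: the lowest value among tied most-frequent intensities.

Lengths are calibrated by ``pixel_width``, areas by
``pixel_width * pixel_height``; dimensionless descriptors are computed on
the pixel grid and are calibration-invariant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from skimage.measure import regionprops

from celltyper.imgio import Calibration, MarkerImage, MarkerRole
from celltyper.segment import CellContour, LabelMap

__all__ = [
    "shape_features",
    "intensity_features",
    "summarize",
    "extract_features",
    "SHAPE_FEATURES",
    "INTENSITY_FEATURES",
    "marker_prefix",
]

SHAPE_FEATURES = (
    "area", "perimeter", "circularity", "roundness", "aspect_ratio",
    "solidity", "feret_max", "feret_min", "ellipse_major", "ellipse_minor",
    "ellipse_angle", "centroid_x", "centroid_y",
    "bbox_x", "bbox_y", "bbox_w", "bbox_h",
)
INTENSITY_FEATURES = (
    "mean", "median", "mode", "std", "min", "max",
    "integrated_density", "raw_integrated_density", "skewness", "kurtosis",
)

_PREFIX = {MarkerRole.MARKER_I: "M1", MarkerRole.MARKER_II: "M2", MarkerRole.MARKER_III: "M3"}


def marker_prefix(role: MarkerRole) -> str:
    return _PREFIX[role]


def _feret_diameters(points: np.ndarray) -> tuple[float, float]:
    """Max/min Feret diameter of a 2D point cloud via its convex hull."""
    hull = ConvexHull(points)
    v = points[hull.vertices]
    # max: largest pairwise distance between hull vertices
    d2 = ((v[:, None, :] - v[None, :, :]) ** 2).sum(axis=2)
    feret_max = float(np.sqrt(d2.max()))
    # min: smallest width over hull edges (rotating calipers)
    feret_min = np.inf
    n = len(v)
    for i in range(n):
        a, b = v[i], v[(i + 1) % n]
        edge = b - a
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        width = np.abs((v - a) @ normal).max()
        feret_min = min(feret_min, float(width))
    return feret_max, feret_min


def shape_features(
    cell_mask: np.ndarray,
    calibration: Calibration | None = None,
    contour: CellContour | None = None,
    offset: tuple[int, int] = (0, 0),
) -> dict[str, float]:
    """Shape descriptors of a single cell's pixel set.

    ``cell_mask`` is a 2D boolean array containing exactly one cell;
    ``offset`` (x0, y0) translates reported coordinates into the original
    image frame (used after ROI cropping).
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("empty cell region")
    cal = calibration or Calibration()
    props = regionprops(cell_mask.astype(np.uint8))[0]
    area_px = float(props.area)
    perim_px = float(props.perimeter) if props.perimeter > 0 else 1.0
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    circ = min(1.0, 4.0 * np.pi * area_px / perim_px**2)
    roundness = 4.0 * area_px / (np.pi * major**2) if major > 0 else 1.0
    aspect = major / minor if minor > 0 else np.inf
    if contour is not None and len(contour.polygon) >= 3:
        pts = np.asarray(contour.polygon, dtype=np.float64)
    else:
        ys, xs = np.nonzero(cell_mask)
        corners = np.array([(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0)])
        pts = (np.stack([xs, ys], axis=1)[:, None, :] + corners[None, :, :]).reshape(-1, 2)
    feret_max, feret_min = _feret_diameters(pts)
    cy, cx = props.centroid
    min_row, min_col, max_row, max_col = props.bbox
    pw = cal.pixel_width
    return {
        "area": area_px * cal.pixel_area,
        "perimeter": perim_px * pw,
        "circularity": circ,
        "roundness": min(1.0, roundness),
        "aspect_ratio": aspect,
        "solidity": float(props.solidity),
        "feret_max": feret_max * pw,
        "feret_min": feret_min * pw,
        "ellipse_major": major * pw,
        "ellipse_minor": minor * pw,
        "ellipse_angle": float(np.degrees(props.orientation)),
        "centroid_x": float(cx) + offset[0],
        "centroid_y": float(cy) + offset[1],
        "bbox_x": float(min_col) + offset[0],
        "bbox_y": float(min_row) + offset[1],
        "bbox_w": float(max_col - min_col),
        "bbox_h": float(max_row - min_row),
    }


def intensity_features(
    cell_mask: np.ndarray,
    marker: MarkerImage,
    calibration: Calibration | None = None,
) -> dict[str, float]:
    """Intensity statistics of one cell's pixels on one raw marker plane."""
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("empty cell region")
    if cell_mask.shape != marker.shape:
        raise ValueError("cell mask not congruent with marker plane")
    cal = calibration or marker.calibration
    vals = marker.pixels[cell_mask].astype(np.float64)
    n = vals.size
    mean = float(vals.mean())
    std = float(vals.std(ddof=0))
    if np.issubdtype(marker.pixels.dtype, np.integer):
        counts = np.bincount(vals.astype(np.int64))
        mode = float(counts.argmax())
    else:
        uniq, cnt = np.unique(vals, return_counts=True)
        mode = float(uniq[cnt.argmax()])
    if std > 0:
        z = (vals - mean) / std
        skew = float((z**3).mean())
        kurt = float((z**4).mean() - 3.0)
    else:
        skew = kurt = 0.0
    area_cal = n * cal.pixel_area
    return {
        "mean": mean,
        "median": float(np.median(vals)),
        "mode": mode,
        "std": std,
        "min": float(vals.min()),
        "max": float(vals.max()),
        "integrated_density": mean * area_cal,
        "raw_integrated_density": float(vals.sum()),
        "skewness": skew,
        "kurtosis": kurt,
    }


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Descriptive statistics per numeric feature column.

    Rows: mean, median, variance (sample, n-1), std, min, max, Q1, Q2, Q3,
    IQR. Quantiles use linear interpolation (type-7).
    """
    numeric = table.select_dtypes(include=[np.number])
    numeric = numeric.drop(columns=[c for c in ("cell_id",) if c in numeric])
    if numeric.shape[0] < 1 or numeric.shape[1] < 1:
        raise ValueError("cannot summarize an empty feature table")
    rows = {
        "mean": numeric.mean(),
        "median": numeric.median(),
        "variance": numeric.var(ddof=1),
        "std": numeric.std(ddof=1),
        "min": numeric.min(),
        "max": numeric.max(),
        "Q1": numeric.quantile(0.25),
        "Q2": numeric.quantile(0.5),
        "Q3": numeric.quantile(0.75),
    }
    out = pd.DataFrame(rows).T
    out.loc["IQR"] = out.loc["Q3"] - out.loc["Q1"]
    out.index.name = "statistic"
    return out


def extract_features(
    label_map: LabelMap,
    contours: list[CellContour],
    marker: MarkerImage,
    calibration: Calibration | None = None,
    offset: tuple[int, int] = (0, 0),
) -> pd.DataFrame:
    """Build the Marker I feature table: shape + intensity per cell.

    One row per labeled cell; columns are namespaced by the marker prefix
    (``M1.area``, ``M1.mean``, ...). Intensity statistics are measured on
    the raw plane passed in ``marker``.
    """
    from scipy import ndimage as ndi

    cal = calibration or marker.calibration
    prefix = marker_prefix(marker.role or MarkerRole.MARKER_I)
    contour_by_id = {c.cell_id: c for c in contours}
    rows = []
    objects = ndi.find_objects(label_map.labels) if label_map.n_cells else []
    for cid in range(1, label_map.n_cells + 1):
        sl = objects[cid - 1]
        sub_mask = label_map.labels[sl] == cid
        sub_off = (offset[0] + sl[1].start, offset[1] + sl[0].start)
        row: dict[str, float] = {"cell_id": cid}
        shp = shape_features(sub_mask, cal, contour_by_id.get(cid), sub_off)
        row.update({f"{prefix}.{k}": v for k, v in shp.items()})
        sub_marker = MarkerImage(
            pixels=marker.pixels[sl], role=marker.role,
            bit_depth=marker.bit_depth, calibration=marker.calibration,
        )
        inten = intensity_features(sub_mask, sub_marker, cal)
        row.update({f"{prefix}.{k}": v for k, v in inten.items()})
        rows.append(row)
    if not rows:
        cols = ["cell_id"] + [f"{prefix}.{k}" for k in SHAPE_FEATURES + INTENSITY_FEATURES]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)
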