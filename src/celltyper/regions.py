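"""Region resizing for Markers II/III and foci-per-nucleus counting.

Measurements on the secondary markers may be taken in the region detected
on Marker I unchanged, shrunk (erosion), or grown (dilation) by a disk
structuring element. Foci (small bright dots, e.g. DNA-damage sites) are
counted per cell as intensity local maxima that pass a prominence test
controlled by the ``tolerance`` parameter (default 30): a local maximum
counts as a distinct focus iff it cannot be reached from any higher
maximum without descending by at least ``tolerance`` intensity levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import disk

from celltyper.features import INTENSITY_FEATURES, intensity_features, marker_prefix
from celltyper.imgio import Calibration, MarkerImage
from celltyper.segment import LabelMap

__all__ = [
    "RegionResizeSpec",
    "FociResult",
    "resize_region",
    "resize_labels",
    "find_foci",
    "measure_marker",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)

DEFAULT_FOCI_TOLERANCE = 30.0


@dataclass(frozen=True)
class RegionResizeSpec:
    """How to resize Marker I regions before measuring another marker."""

    mode: str = "none"  # none | erode | dilate
    radius: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("none", "erode", "dilate"):
            raise ValueError(f"unknown resize mode '{self.mode}'")
        if self.mode != "none" and self.radius < 1:
            raise ValueError("resize radius must be >= 1")


@dataclass
class FociResult:
    cell_id: int
    count: int
    maxima: list[tuple[float, float]] = field(default_factory=list)
    tolerance: float = DEFAULT_FOCI_TOLERANCE


def resize_region(cell_mask: np.ndarray, spec: RegionResizeSpec) -> np.ndarray:
    """Erode/dilate a single cell's pixel set by a disk of ``spec.radius``.

    Pure morphology on one region; collisions between neighbouring cells'
    dilations are handled by :func:`resize_labels`. Over-erosion may return
    an empty mask, which callers must treat as a missing region.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if spec.mode == "none":
        return cell_mask.copy()
    se = disk(spec.radius)
    if spec.mode == "erode":
        return ndi.binary_erosion(cell_mask, structure=se, border_value=0)
    return ndi.binary_dilation(cell_mask, structure=se)


def resize_labels(label_map: LabelMap, spec: RegionResizeSpec) -> np.ndarray:
    """Resize every cell region, resolving dilation overlaps.

    Returns an integer label image of the resized regions. For dilation,
    contested pixels (reachable from several cells) are assigned to the
    cell whose original pixel set is nearest (Euclidean distance, ties to
    the lower cell id); original pixels always keep their own label.
    """
    labels = label_map.labels
    n = label_map.n_cells
    if spec.mode == "none" or n == 0:
        return labels.copy()
    if spec.mode == "erode":
        out = np.zeros_like(labels)
        se = disk(spec.radius)
        objects = ndi.find_objects(labels)
        pad = spec.radius + 1
        for cid in range(1, n + 1):
            sl = objects[cid - 1]
            if sl is None:
                continue
            ys = slice(max(0, sl[0].start - pad), min(labels.shape[0], sl[0].stop + pad))
            xs = slice(max(0, sl[1].start - pad), min(labels.shape[1], sl[1].stop + pad))
            sub = labels[ys, xs] == cid
            eroded = ndi.binary_erosion(sub, structure=se, border_value=0)
            out[ys, xs][eroded] = cid
        return out
    # dilate: nearest-original-cell assignment via per-cell distance maps,
    # increasing id order makes ties go to the lower id
    best_dist = np.full(labels.shape, np.inf)
    best_id = np.zeros_like(labels)
    for cid in range(1, n + 1):
        d = ndi.distance_transform_edt(labels != cid)
        better = d < best_dist
        best_dist[better] = d[better]
        best_id[better] = cid
    out = np.where(best_dist <= spec.radius, best_id, 0)
    return out.astype(labels.dtype)


def _plateaus(values: np.ndarray, mask: np.ndarray) -> list[tuple[float, np.ndarray]]:
    """Local-maximum plateaus within ``mask`` (8-connected).

    A plateau is a connected set of equal-valued pixels none of whose
    in-mask neighbours is higher. Returns (value, plateau mask) pairs.
    """
    v = np.where(mask, values, -np.inf)
    vmax = ndi.maximum_filter(v, footprint=_STRUCT8, mode="constant", cval=-np.inf)
    candidate = mask & (v >= vmax)  # no strictly higher neighbour
    lbl, n = ndi.label(candidate, structure=_STRUCT8)
    plateaus = []
    for pid in range(1, n + 1):
        pm = lbl == pid
        # a candidate component is a plateau maximum only if no in-mask
        # neighbour of the component is higher (equal-valued neighbours
        # inside the component are fine by construction)
        val = values[pm][0]
        ring = ndi.binary_dilation(pm, structure=_STRUCT8) & mask & ~pm
        if ring.any() and (values[ring] > val).any():
            continue
        plateaus.append((float(val), pm))
    return plateaus


def find_foci(
    marker: MarkerImage,
    cell_mask: np.ndarray,
    tolerance: float = DEFAULT_FOCI_TOLERANCE,
    cell_id: int = 0,
) -> FociResult:
    """Count bright foci in one cell by prominence-filtered local maxima.

    A plateau of locally maximal intensity is accepted as a focus iff a
    flood fill from it over pixels above ``value - tolerance`` (restricted
    to the cell) reaches no higher pixel. Equal-valued maxima connected by
    such a flood merge into one focus. Each accepted plateau contributes
    one maximum at its centroid (x, y). Flat regions contain no foci.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("empty cell region")
    values = marker.pixels.astype(np.float64)
    vals_in = values[cell_mask]
    if vals_in.max() == vals_in.min():
        return FociResult(cell_id=cell_id, count=0, maxima=[], tolerance=tolerance)

    plateaus = _plateaus(values, cell_mask)
    # deterministic order: descending value, then raster order of first pixel
    def _first_pixel(pm: np.ndarray) -> int:
        return int(np.flatnonzero(pm.ravel())[0])

    plateaus.sort(key=lambda p: (-p[0], _first_pixel(p[1])))

    consumed = np.zeros_like(cell_mask)
    maxima: list[tuple[float, float]] = []
    for val, pm in plateaus:
        if (consumed & pm).any():
            continue
        reach = cell_mask & (values > val - tolerance)
        flood_lbl, _ = ndi.label(reach, structure=_STRUCT8)
        seed_label = flood_lbl[pm][0]
        flood = flood_lbl == seed_label
        consumed |= flood
        if (values[flood] > val).any():
            continue  # reachable from higher ground without a >= tolerance dip
        ys, xs = np.nonzero(pm)
        maxima.append((float(xs.mean()), float(ys.mean())))
    return FociResult(cell_id=cell_id, count=len(maxima), maxima=maxima, tolerance=tolerance)


def measure_marker(
    label_map: LabelMap,
    marker: MarkerImage,
    resize: RegionResizeSpec | None = None,
    foci_enabled: bool = False,
    tolerance: float = DEFAULT_FOCI_TOLERANCE,
    calibration: Calibration | None = None,
    presmooth_sigma: float = 0.0,
) -> pd.DataFrame:
    """Measure one secondary marker in every (resized) cell region.

    Returns a DataFrame with ``cell_id`` plus namespaced intensity columns
    (``M2.mean``, ...) and, when enabled, ``M2.foci_count``. Shape features
    are not recomputed — geometry belongs to Marker I. Regions emptied by
    erosion get missing values.
    """
    if marker.role is None:
        raise ValueError("marker must have an assigned role")
    prefix = marker_prefix(marker.role)
    spec = resize or RegionResizeSpec()
    resized = resize_labels(label_map, spec)
    foci_plane = marker
    if foci_enabled and presmooth_sigma > 0:
        smoothed = ndi.gaussian_filter(marker.pixels.astype(np.float64), presmooth_sigma)
        foci_plane = MarkerImage(
            pixels=smoothed, role=marker.role, bit_depth=marker.bit_depth,
            calibration=marker.calibration,
        )
    rows = []
    objects = ndi.find_objects(resized, max_label=label_map.n_cells)
    for cid in range(1, label_map.n_cells + 1):
        sl = objects[cid - 1] if cid <= len(objects) else None
        row: dict[str, float] = {"cell_id": cid}
        if sl is None:
            row.update({f"{prefix}.{k}": np.nan for k in INTENSITY_FEATURES})
            if foci_enabled:
                row[f"{prefix}.foci_count"] = np.nan
        else:
            region = resized[sl] == cid
            sub = MarkerImage(
                pixels=marker.pixels[sl], role=marker.role,
                bit_depth=marker.bit_depth, calibration=marker.calibration,
            )
            feats = intensity_features(region, sub, calibration)
            row.update({f"{prefix}.{k}": v for k, v in feats.items()})
            if foci_enabled:
                sub_foci = MarkerImage(
                    pixels=foci_plane.pixels[sl], role=marker.role,
                    bit_depth=marker.bit_depth, calibration=marker.calibration,
                )
                row[f"{prefix}.foci_count"] = float(
                    find_foci(sub_foci, region, tolerance, cid).count
                )
        rows.append(row)
    cols = ["cell_id"] + [f"{prefix}.{k}" for k in INTENSITY_FEATURES]
    if foci_enabled:
        cols.append(f"{prefix}.foci_count")
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)
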