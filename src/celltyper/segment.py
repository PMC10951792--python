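"""Binarization, hole filling, watershed splitting, and cell labeling.

Foreground connectivity is 8, background 4 (the standard dual pair for
particle analysis). Labels are assigned in raster order of each
component's first pixel (topmost, then leftmost), so IDs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed as _sk_watershed

from celltyper.imgio import MarkerImage
from celltyper.thresholds import THRESHOLD_METHODS, auto_threshold

__all__ = [
    "BinaryMask",
    "LabelMap",
    "CellContour",
    "THRESHOLD_METHODS",
    "auto_threshold",
    "binarize",
    "fill_holes",
    "watershed_split",
    "label_cells",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class BinaryMask:
    mask: np.ndarray
    foreground_is_bright: bool = True

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("binary mask must be 2D")


@dataclass
class LabelMap:
    """Integer-labeled segmentation: 0 = background, 1..N = cells."""

    labels: np.ndarray
    n_cells: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2D")


@dataclass
class CellContour:
    """Closed outer boundary polygon of one labeled cell.

    Vertices lie on pixel corners (crack boundary), so the polygon's
    enclosed area equals the pixel count of the label.
    """

    cell_id: int
    polygon: list[tuple[float, float]] = field(default_factory=list)


def binarize(image: MarkerImage, t: float, dark_background: bool = True) -> BinaryMask:
    """Threshold a plane at native-scale level ``t``.

    With a dark background (default), pixels strictly above ``t`` are
    foreground; with ``dark_background=False`` the comparison is flipped
    for inverted material (dark objects on a bright field).
    """
    if dark_background:
        mask = image.pixels > t
    else:
        mask = image.pixels < t
    return BinaryMask(mask=mask, foreground_is_bright=dark_background)


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Fill background components not connected to the image border."""
    filled = ndi.binary_fill_holes(mask.mask)
    return BinaryMask(mask=filled, foreground_is_bright=mask.foreground_is_bright)


def watershed_split(mask: BinaryMask) -> BinaryMask:
    """Split touching objects along ridges of the distance transform.

    Binary (distance-transform) watershed: seeds are the local maxima of
    the Euclidean distance map of the foreground (nearby peaks within
    0.5 px of each other in height are merged into one seed), and the
    watershed lines between basins are removed from the foreground. The
    foreground pixel set is otherwise preserved, so component count can
    only grow.
    """
    m = mask.mask
    if not m.any():
        return BinaryMask(mask=m.copy(), foreground_is_bright=mask.foreground_is_bright)
    dist = ndi.distance_transform_edt(m)
    # peak merging: quantize the distance map so plateaus/near-ties at
    # tolerance 0.5 px collapse to single seeds
    qdist = np.round(dist * 2.0) / 2.0
    coords = peak_local_max(qdist, labels=m, footprint=np.ones((7, 7)), exclude_border=False)
    seeds = np.zeros_like(m, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        seeds[r, c] = i
    # merge seeds belonging to one plateau
    seed_lbl, n_seeds = ndi.label(seeds > 0, structure=_STRUCT8)
    if n_seeds == 0:
        return BinaryMask(mask=m.copy(), foreground_is_bright=mask.foreground_is_bright)
    basins = _sk_watershed(-dist, markers=seed_lbl, mask=m, watershed_line=True)
    out = m & (basins > 0)
    return BinaryMask(mask=out, foreground_is_bright=mask.foreground_is_bright)


def _raster_relabel(labels: np.ndarray, n: int) -> np.ndarray:
    """Renumber labels 1..N in raster order of each component's first pixel."""
    if n == 0:
        return labels
    order = []
    seen = set()
    flat = labels.ravel()
    for v in flat:
        if v != 0 and v not in seen:
            seen.add(int(v))
            order.append(int(v))
            if len(order) == n:
                break
    remap = np.zeros(n + 1, dtype=labels.dtype)
    for new_id, old_id in enumerate(order, start=1):
        remap[old_id] = new_id
    return remap[labels]


def trace_contour(cell_mask: np.ndarray, offset: tuple[int, int] = (0, 0)) -> list[tuple[float, float]]:
    """Trace the outer crack boundary of a single-cell mask.

    Walks the cracks between foreground and background pixels, producing a
    closed polygon over pixel corners in (x, y) coordinates. The enclosed
    area equals the pixel count for solid (hole-free) regions.
    """
    ys, xs = np.nonzero(cell_mask)
    if len(ys) == 0:
        return []
    h, w = cell_mask.shape

    def inside(x: int, y: int) -> bool:
        return 0 <= x < w and 0 <= y < h and bool(cell_mask[y, x])

    # directed crack edges with the foreground kept on the right; vertices
    # are pixel corners, pixel (x, y) owns corners (x..x+1, y..y+1)
    out_edges: dict[tuple[int, int], set[tuple[int, int]]] = {}
    for y, x in zip(ys.tolist(), xs.tolist()):
        if not inside(x, y - 1):
            out_edges.setdefault((x, y), set()).add((1, 0))
        if not inside(x + 1, y):
            out_edges.setdefault((x + 1, y), set()).add((0, 1))
        if not inside(x, y + 1):
            out_edges.setdefault((x + 1, y + 1), set()).add((-1, 0))
        if not inside(x - 1, y):
            out_edges.setdefault((x, y + 1), set()).add((0, -1))

    first = np.lexsort((xs, ys))[0]
    start = (int(xs[first]), int(ys[first]))
    # at a vertex crossed by two boundary strands (diagonally touching
    # pixels), prefer the turn that keeps the 8-connected component in one
    # loop: E->N, S->E, W->S, N->W first, then straight, then the other turn
    turns = {
        (1, 0): [(0, -1), (1, 0), (0, 1)],
        (0, 1): [(1, 0), (0, 1), (-1, 0)],
        (-1, 0): [(0, 1), (-1, 0), (0, -1)],
        (0, -1): [(-1, 0), (0, -1), (1, 0)],
    }
    ox, oy = offset
    pos, direction = start, (1, 0)
    polygon: list[tuple[float, float]] = [(start[0] + ox, start[1] + oy)]
    while True:
        out_edges.get(pos, set()).discard(direction)
        pos = (pos[0] + direction[0], pos[1] + direction[1])
        polygon.append((pos[0] + ox, pos[1] + oy))
        if pos == start:
            break
        cands = out_edges.get(pos, set())
        for cand in turns[direction]:
            if cand in cands:
                direction = cand
                break
        else:
            raise RuntimeError("contour tracing failed to close")
    return polygon


def label_cells(mask: BinaryMask) -> tuple[LabelMap, list[CellContour]]:
    """Label 8-connected components and trace each cell's outer contour.

    Components are numbered 1..N in raster order of their first pixel.
    """
    lbl, n = ndi.label(mask.mask, structure=_STRUCT8)
    lbl = _raster_relabel(lbl, n)
    contours: list[CellContour] = []
    if n > 0:
        objects = ndi.find_objects(lbl)
        for cid in range(1, n + 1):
            sl = objects[cid - 1]
            sub = lbl[sl] == cid
            off = (sl[1].start, sl[0].start)
            contours.append(CellContour(cell_id=cid, polygon=trace_contour(sub, off)))
    return LabelMap(labels=lbl, n_cells=int(n)), contours
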