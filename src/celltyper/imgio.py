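"""Image ingestion: channel loading, marker-role assignment, calibration, ROI.

Coordinate convention used throughout the package: ``x`` = column, ``y`` =
row, 0-based, origin at the top-left pixel. RGB channel order is index
0 = R, 1 = G, 2 = B.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile


class MarkerRole(enum.Enum):
    """Role of a channel in the analysis.

    Marker I defines what a cell is (segmentation channel); Markers II and
    III are measured within each detected cell for classification.
    """

    MARKER_I = "I"
    MARKER_II = "II"
    MARKER_III = "III"


@dataclass(frozen=True)
class Calibration:
    """Spatial calibration: physical length per pixel.

    When ``calibrated`` is False the unit is the pixel itself and both
    pixel sizes must be 1.
    """

    pixel_width: float = 1.0
    pixel_height: float = 1.0
    unit: str = "pixel"
    calibrated: bool = False

    def __post_init__(self) -> None:
        if self.pixel_width <= 0 or self.pixel_height <= 0:
            raise ValueError("pixel sizes must be positive")
        if not self.calibrated and (
            self.pixel_width != 1.0 or self.pixel_height != 1.0 or self.unit != "pixel"
        ):
            raise ValueError(
                "uncalibrated images must have pixel_width = pixel_height = 1 "
                "and unit 'pixel'"
            )

    @property
    def pixel_area(self) -> float:
        return self.pixel_width * self.pixel_height


@dataclass
class MarkerImage:
    """A single 2D intensity plane bound to a marker role."""

    pixels: np.ndarray
    role: MarkerRole | None = None
    bit_depth: int = 8
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("MarkerImage requires a 2D single-plane array")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if np.issubdtype(self.pixels.dtype, np.integer) and self.pixels.min() < 0:
            raise ValueError("intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass
class RegionOfInterest:
    """Closed region restricting the analysis, as a filled boolean mask.

    ``offset`` is the (x0, y0) of the mask's bounding box in original-image
    coordinates, recorded so that cell coordinates measured inside a crop
    can be reported in the original frame.
    """

    mask: np.ndarray
    offset: tuple[int, int] = (0, 0)
    closed: bool = True

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2D")
        if not self.mask.any():
            raise ValueError("ROI must contain at least one pixel")

    @classmethod
    def rectangle(cls, x: int, y: int, w: int, h: int, shape: tuple[int, int]) -> "RegionOfInterest":
        if w <= 0 or h <= 0:
            raise ValueError("rectangle ROI needs positive width and height")
        mask = np.zeros(shape, dtype=bool)
        mask[y : y + h, x : x + w] = True
        if not mask.any():
            raise ValueError("rectangle ROI lies outside the image")
        return cls(mask=mask)

    @classmethod
    def ellipse(cls, cx: float, cy: float, rx: float, ry: float, shape: tuple[int, int]) -> "RegionOfInterest":
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        mask = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
        if not mask.any():
            raise ValueError("ellipse ROI contains no pixels")
        return cls(mask=mask)

    @classmethod
    def polygon(cls, vertices: list[tuple[float, float]], shape: tuple[int, int]) -> "RegionOfInterest":
        from skimage.draw import polygon as sk_polygon

        xs = [v[0] for v in vertices]
        ys = [v[1] for v in vertices]
        rr, cc = sk_polygon(ys, xs, shape=shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        if not mask.any():
            raise ValueError("polygon ROI contains no pixels")
        return cls(mask=mask)


_SUPPORTED_SUFFIXES = {".tif", ".tiff", ".png"}


def load_image(path: str | Path) -> list[MarkerImage]:
    """Load a 2D single-plane image and split it into per-channel planes.

    Supported inputs: single-plane TIFF or PNG, either one grayscale plane
    (8- or 16-bit) or a 3-channel 24-bit RGB image. Returns one
    :class:`MarkerImage` per channel, in channel order (R, G, B for RGB),
    with roles unassigned. Pixel values are preserved losslessly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ValueError(
            f"unsupported format '{path.suffix}': only TIFF and PNG are supported"
        )
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        arr = iio.imread(str(path))
    arr = np.asarray(arr)

    if arr.ndim == 2:
        planes = [arr]
    elif arr.ndim == 3:
        # channel axis may be first (CYX) or last (YXC); accept alpha-less color only
        if arr.shape[-1] in (3, 4) and arr.shape[0] not in (3, 4):
            if arr.shape[-1] == 4:  # drop alpha from RGBA PNGs
                arr = arr[..., :3]
            planes = [arr[..., c] for c in range(arr.shape[-1])]
        elif arr.shape[0] == 3:
            planes = [arr[c] for c in range(3)]
        else:
            raise ValueError(
                "2D single-plane required: z-stacks/time series and images "
                f"with more than 3 channels are not supported (shape {arr.shape})"
            )
    else:
        raise ValueError(
            f"2D single-plane required: got {arr.ndim}-dimensional data"
        )

    bit_depth = 16 if planes[0].dtype.itemsize >= 2 else 8
    return [MarkerImage(pixels=p, role=None, bit_depth=bit_depth) for p in planes]


def match_channels(
    planes: list[MarkerImage],
    mapping: dict[int, MarkerRole],
    calibration: Calibration | None = None,
) -> dict[MarkerRole, MarkerImage]:
    """Assign marker roles to channel indices.

    ``mapping`` maps channel index -> role. Marker I must be assigned to
    exactly one channel; Markers II/III are optional; no role may repeat.
    Unmapped planes are discarded.
    """
    roles = list(mapping.values())
    if len(roles) != len(set(roles)):
        raise ValueError("duplicate marker role in channel mapping")
    if MarkerRole.MARKER_I not in roles:
        raise ValueError("channel mapping must assign Marker I to exactly one channel")
    out: dict[MarkerRole, MarkerImage] = {}
    for idx, role in mapping.items():
        if idx < 0 or idx >= len(planes):
            raise ValueError(f"channel index {idx} out of range for {len(planes)} planes")
        src = planes[idx]
        out[role] = MarkerImage(
            pixels=src.pixels,
            role=role,
            bit_depth=src.bit_depth,
            calibration=calibration or src.calibration,
        )
    return out


def crop_to_roi(
    markers: dict[MarkerRole, MarkerImage], roi: RegionOfInterest
) -> tuple[dict[MarkerRole, MarkerImage], tuple[int, int]]:
    """Restrict all marker planes to the ROI's bounding box.

    Pixels inside the bounding box but outside the ROI mask are zeroed so
    they cannot contribute foreground. Returns the cropped markers and the
    (x0, y0) offset to translate cropped coordinates back into the original
    image frame.
    """
    if not roi.closed:
        raise ValueError("ROI must be a closed shape")
    any_marker = next(iter(markers.values()))
    if roi.mask.shape != any_marker.shape:
        raise ValueError("ROI mask is not congruent with the image")
    rows = np.any(roi.mask, axis=1)
    cols = np.any(roi.mask, axis=0)
    y0, y1 = np.where(rows)[0][[0, -1]]
    x0, x1 = np.where(cols)[0][[0, -1]]
    sub_mask = roi.mask[y0 : y1 + 1, x0 : x1 + 1]
    cropped: dict[MarkerRole, MarkerImage] = {}
    for role, m in markers.items():
        sub = m.pixels[y0 : y1 + 1, x0 : x1 + 1].copy()
        sub[~sub_mask] = 0
        cropped[role] = MarkerImage(
            pixels=sub, role=m.role, bit_depth=m.bit_depth, calibration=m.calibration
        )
    return cropped, (int(x0), int(y0))


def rescale_to_8bit(marker: MarkerImage) -> np.ndarray:
    """Map a plane onto the 0–255 range used for histograms and thresholds.

    8-bit planes pass through unchanged. 16-bit planes are rescaled by the
    full bit range (value * 255 / 65535, rounded half up) so the 8-bit
    threshold algorithms apply unchanged; the chosen threshold is mapped
    back to the native scale before binarization.
    """
    px = marker.pixels
    if marker.bit_depth == 8:
        return px.astype(np.uint8, copy=False)
    scaled = np.floor(px.astype(np.float64) * 255.0 / 65535.0 + 0.5)
    return scaled.astype(np.uint8)


def threshold_to_native(t8: int, marker: MarkerImage) -> float:
    """Map a 0–255 threshold back onto the plane's native intensity scale."""
    if marker.bit_depth == 8:
        return float(t8)
    return t8 * 65535.0 / 255.0


def channel_histogram(marker: MarkerImage) -> np.ndarray:
    """256-bin intensity histogram of one marker plane.

    Bin counts always sum to the pixel count; 16-bit data are binned after
    linear rescaling onto 0–255.
    """
    if marker.pixels.size == 0:
        raise ValueError("marker plane is empty")
    data = rescale_to_8bit(marker)
    return np.bincount(data.ravel(), minlength=256)[:256].astype(np.int64)
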