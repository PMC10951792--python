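"""Optional image conditioning applied to the Marker I plane before
segmentation.

The chain is declarative — an ordered list of named steps with numeric
parameters — so a run is fully described by its configuration. Conditioning
only influences segmentation: intensity features downstream are always
measured on the raw, unpreprocessed planes, keeping measured statistics
comparable across runs with different chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, restoration

from celltyper.imgio import MarkerImage

__all__ = ["PreprocessStep", "apply_chain", "PREPROCESS_OPS"]


@dataclass
class PreprocessStep:
    """One conditioning step: ``op`` name plus its numeric parameters.

    Supported ops and parameters:

    - ``gaussian_blur``: ``sigma`` (px, > 0)
    - ``median_filter``: ``radius`` (px, >= 1)
    - ``mean_filter``: ``radius`` (px, >= 1)
    - ``subtract_background``: ``radius`` (rolling-ball radius, px, > 0)
    - ``enhance_contrast``: ``saturation`` (fraction of pixels saturated
      at each tail, in (0, 0.5))
    - ``invert``: no parameters
    - ``gamma_correction``: ``gamma`` (> 0)
    """

    op: str
    params: dict[str, float] = field(default_factory=dict)


def _clip_to_depth(arr: np.ndarray, image: MarkerImage) -> np.ndarray:
    out = np.clip(np.round(arr), 0, image.max_value)
    return out.astype(image.pixels.dtype)


def _gaussian_blur(px: np.ndarray, image: MarkerImage, sigma: float) -> np.ndarray:
    return ndi.gaussian_filter(px.astype(np.float64), sigma=sigma, mode="reflect")


def _median_filter(px: np.ndarray, image: MarkerImage, radius: float) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    footprint = xx**2 + yy**2 <= r**2
    return ndi.median_filter(px, footprint=footprint, mode="reflect")


def _mean_filter(px: np.ndarray, image: MarkerImage, radius: float) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    footprint = (xx**2 + yy**2 <= r**2).astype(np.float64)
    footprint /= footprint.sum()
    return ndi.convolve(px.astype(np.float64), footprint, mode="reflect")


def _subtract_background(px: np.ndarray, image: MarkerImage, radius: float) -> np.ndarray:
    background = restoration.rolling_ball(px, radius=radius)
    return px.astype(np.float64) - background


def _enhance_contrast(px: np.ndarray, image: MarkerImage, saturation: float) -> np.ndarray:
    lo, hi = np.percentile(px, [100 * saturation, 100 * (1 - saturation)])
    if hi <= lo:
        return px.astype(np.float64)
    return exposure.rescale_intensity(
        px.astype(np.float64), in_range=(lo, hi), out_range=(0, image.max_value)
    )


def _invert(px: np.ndarray, image: MarkerImage) -> np.ndarray:
    return image.max_value - px.astype(np.float64)


def _gamma_correction(px: np.ndarray, image: MarkerImage, gamma: float) -> np.ndarray:
    mx = float(image.max_value)
    return mx * (px.astype(np.float64) / mx) ** gamma


PREPROCESS_OPS = {
    "gaussian_blur": (_gaussian_blur, ("sigma",)),
    "median_filter": (_median_filter, ("radius",)),
    "mean_filter": (_mean_filter, ("radius",)),
    "subtract_background": (_subtract_background, ("radius",)),
    "enhance_contrast": (_enhance_contrast, ("saturation",)),
    "invert": (_invert, ()),
    "gamma_correction": (_gamma_correction, ("gamma",)),
}


def apply_chain(image: MarkerImage, steps: list[PreprocessStep]) -> MarkerImage:
    """Apply an ordered conditioning chain to one marker plane.

    Output preserves shape, dtype, and bit depth. An empty chain returns
    the input image unchanged (same object).
    """
    if not steps:
        return image
    px = image.pixels
    for i, step in enumerate(steps):
        if step.op not in PREPROCESS_OPS:
            raise ValueError(
                f"step {i}: unknown preprocessing op '{step.op}'; valid ops: "
                + ", ".join(sorted(PREPROCESS_OPS))
            )
        fn, param_names = PREPROCESS_OPS[step.op]
        args = []
        for name in param_names:
            if name not in step.params:
                raise ValueError(f"step {i} ({step.op}): missing parameter '{name}'")
            value = float(step.params[name])
            if value <= 0:
                raise ValueError(
                    f"step {i} ({step.op}): parameter '{name}' must be positive"
                )
            args.append(value)
        px = fn(px, image, *args)
        px = _clip_to_depth(px, image)
    return MarkerImage(
        pixels=px, role=image.role, bit_depth=image.bit_depth,
        calibration=image.calibration,
    )
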