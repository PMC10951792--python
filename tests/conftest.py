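"""Shared fixtures: small synthetic scenes and histogram generators."""

from __future__ import annotations

import numpy as np
import pytest

from celltyper.imgio import MarkerImage, MarkerRole
from celltyper.synthgen import SceneParams, generate_scene, preset


def bimodal_histogram(rng: np.random.Generator) -> np.ndarray:
    """Random two-component intensity histogram (256 bins)."""
    mu1, mu2 = rng.uniform(30, 100), rng.uniform(130, 230)
    s1, s2 = rng.uniform(5, 18), rng.uniform(5, 22)
    n1, n2 = rng.integers(500, 5000), rng.integers(500, 5000)
    x1 = np.clip(rng.normal(mu1, s1, n1), 0, 255).astype(int)
    x2 = np.clip(rng.normal(mu2, s2, n2), 0, 255).astype(int)
    return np.bincount(np.concatenate([x1, x2]), minlength=256)[:256]


@pytest.fixture(scope="session")
def small_scene():
    """20 well-separated noiseless nuclei in a 256x256 frame."""
    return generate_scene(
        SceneParams(n_cells=20, size=(256, 256)), seed=11, noise_sigma=0.0
    )


@pytest.fixture(scope="session")
def noisy_scene():
    """Low-noise nuclei scene (the default study conditions, smaller frame)."""
    return generate_scene(SceneParams(n_cells=15, size=(256, 256)), seed=5)


def disk_image(radius: int = 20, value: int = 200, background: int = 10,
               pad: int = 6) -> MarkerImage:
    n = 2 * (radius + pad) + 1
    c = radius + pad
    yy, xx = np.mgrid[0:n, 0:n]
    img = np.full((n, n), background, dtype=np.uint8)
    img[(xx - c) ** 2 + (yy - c) ** 2 <= radius**2] = value
    return MarkerImage(img, MarkerRole.MARKER_I, 8)
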