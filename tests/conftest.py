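"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


# ---------------------------------------------------------------------------
# independent oracles


def otsu_scan_oracle(values: np.ndarray, bins: int = 256) -> float:
    """Exhaustive within-class-variance scan over all candidate bin splits.

    Independent of the implementation: evaluates the within-class variance of
    every split directly from the histogram and picks the first minimum, then
    maps the split to a threshold as the largest pixel of the lower class.
    """
    values = np.asarray(values).ravel()
    lo, hi = float(values.min()), float(values.max())
    hist, edges = np.histogram(values, bins=bins, range=(lo, hi))
    levels = np.arange(bins, dtype=float)
    best_k, best_wcv = None, np.inf
    total = hist.sum()
    for k in range(bins - 1):
        w0 = hist[: k + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[: k + 1] * levels[: k + 1]).sum() / w0
        m1 = (hist[k + 1:] * levels[k + 1:]).sum() / w1
        v0 = (hist[: k + 1] * (levels[: k + 1] - m0) ** 2).sum() / w0
        v1 = (hist[k + 1:] * (levels[k + 1:] - m1) ** 2).sum() / w1
        wcv = (w0 * v0 + w1 * v1) / total
        if wcv < best_wcv - 1e-12:
            best_wcv, best_k = wcv, k
    assert best_k is not None
    background = values[values < edges[best_k + 1]]
    return float(background.max())


def opening_oracle(image: np.ndarray, radius: int) -> np.ndarray:
    """Brute-force grayscale opening with a ball (sphere-cap) element.

    Erosion ignores pixels outside the image (+inf padding); dilation ignores
    positions outside the eroded image (-inf padding).
    """
    image = np.asarray(image, dtype=float)
    r = radius
    yy, xx = np.mgrid[-r: r + 1, -r: r + 1]
    d2 = (xx ** 2 + yy ** 2).astype(float)
    cap = np.where(d2 <= r * r, np.sqrt(np.maximum(r * r - d2, 0.0)), np.nan)
    h, w = image.shape
    padded = np.pad(image, r, constant_values=np.inf)
    eroded = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            win = padded[i: i + 2 * r + 1, j: j + 2 * r + 1]
            eroded[i, j] = np.nanmin(win - cap)
    padded = np.pad(eroded, r, constant_values=-np.inf)
    opened = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            win = padded[i: i + 2 * r + 1, j: j + 2 * r + 1]
            opened[i, j] = np.nanmax(win + cap)
    return np.minimum(opened, image)


def draw_disk(image: np.ndarray, cx: float, cy: float, r: float, value: float):
    yy, xx = np.mgrid[0: image.shape[0], 0: image.shape[1]]
    image[(xx - cx) ** 2 + (yy - cy) ** 2 <= r * r] = value
    return image
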