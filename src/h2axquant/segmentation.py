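"""Nuclei segmentation on the DAPI channel.

Nuclei are detected by Otsu auto-thresholding of the DNA counterstain.  The
histogram convention follows the ImageJ auto-threshold behaviour for >8-bit
data: 256 bins spanning [min, max] of the image, foreground strictly above the
returned threshold.  A well is thresholded once — by default on its
lexicographically first field — and that threshold is reused for every field
of the well, so treatment-induced intensity shifts inside a well cannot move
the segmentation.  Connected components use 8-connectivity and objects
touching the image border are discarded to avoid truncated-area bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skimage import measure as skmeasure
from skimage import segmentation as sksegmentation
from scipy import ndimage

from .io import FieldImage

THRESHOLD_MODES = ("per_well_first_field", "per_well_pooled", "per_image")


class ConstantImageError(ValueError):
    """Image has a single intensity value; no Otsu threshold exists."""


@dataclass
class ThresholdPolicy:
    """How the Otsu threshold is chosen for the fields of one well."""

    mode: str = "per_well_first_field"
    bins: int = 256

    def __post_init__(self) -> None:
        if self.mode not in THRESHOLD_MODES:
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.bins < 2:
            raise ValueError("need at least 2 histogram bins")


@dataclass
class LabeledMask:
    """Connected-component labels for one field plus the threshold that made them."""

    labels: np.ndarray
    threshold_used: float
    field_name: str = ""

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


def _otsu_bin_index(hist: np.ndarray) -> int:
    """Index of the last background bin maximizing between-class variance.

    Ties are broken toward the lowest qualifying bin.  Bin indices act as the
    intensity levels; the affine map from index to intensity does not change
    the argmax.
    """
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    w0 = np.cumsum(hist)[:-1]          # background weight for split after bin k
    w1 = total - w0
    mu0_sum = np.cumsum(hist * np.arange(hist.size))[:-1]
    mu_total = (hist * np.arange(hist.size)).sum()
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        raise ConstantImageError("histogram has a single occupied bin")
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_total * w0 / total - mu0_sum) ** 2 / (w0 * w1)
    between[~valid] = -np.inf
    return int(np.argmax(between))     # np.argmax returns the first maximum


def _threshold_from_split(values: np.ndarray, edges: np.ndarray, idx: int) -> float:
    # threshold = largest pixel value in the background class, so that
    # "strictly greater than threshold" reproduces the bin split exactly
    background = values[values < edges[idx + 1]]
    return float(background.max())


def otsu_threshold(image: FieldImage | np.ndarray, bins: int = 256) -> float:
    """Otsu threshold on a 256-bin histogram spanning [min, max].

    Returns a scalar t such that foreground = pixels strictly greater than t.
    Raises :class:`ConstantImageError` on a constant image.
    """
    values = image.pixels if isinstance(image, FieldImage) else np.asarray(image)
    values = values.ravel()
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise ConstantImageError("constant image: no threshold exists")
    hist, edges = np.histogram(values, bins=bins, range=(lo, hi))
    idx = _otsu_bin_index(hist)
    return _threshold_from_split(values, edges, idx)


def _pooled_threshold(fields: Sequence[FieldImage], bins: int) -> float:
    pooled = np.concatenate([f.pixels.ravel() for f in fields])
    return otsu_threshold(pooled, bins=bins)


def _field_sort_key(f: FieldImage) -> str:
    if f.ref is not None:
        return f.ref.filename
    return ""


def segment_well(
    dapi_fields: Sequence[FieldImage],
    policy: ThresholdPolicy | None = None,
) -> list[LabeledMask]:
    """Threshold and label every DAPI field of one well.

    Under ``per_well_first_field`` (default) the threshold computed on the
    lexicographically first field is applied to all fields of the well, which
    reproduces the save-and-reuse behaviour of the acquisition-time macro.
    ``per_well_pooled`` thresholds the concatenated histogram of the well and
    ``per_image`` thresholds every field independently.
    """
    if not dapi_fields:
        raise ValueError("segment_well needs at least one DAPI field")
    policy = policy or ThresholdPolicy()
    fields = sorted(dapi_fields, key=_field_sort_key)

    if policy.mode == "per_well_first_field":
        t = otsu_threshold(fields[0], bins=policy.bins)
        thresholds = [t] * len(fields)
    elif policy.mode == "per_well_pooled":
        t = _pooled_threshold(fields, policy.bins)
        thresholds = [t] * len(fields)
    else:
        thresholds = [otsu_threshold(f, bins=policy.bins) for f in fields]

    masks = []
    for f, t in zip(fields, thresholds):
        binary = f.pixels > t
        labels = skmeasure.label(binary, connectivity=2)
        name = f.ref.position if f.ref is not None else ""
        masks.append(LabeledMask(labels=labels, threshold_used=t, field_name=name))
    return masks


def exclude_edge_objects(mask: LabeledMask) -> LabeledMask:
    """Drop every object with a pixel on the image border; relabel 1..n.

    Idempotent; relabeling preserves the original label order.
    """
    cleared = sksegmentation.clear_border(mask.labels)
    kept = np.unique(cleared)
    kept = kept[kept > 0]
    lut = np.zeros(int(mask.labels.max()) + 1, dtype=mask.labels.dtype)
    lut[kept] = np.arange(1, kept.size + 1, dtype=mask.labels.dtype)
    return LabeledMask(
        labels=lut[cleared],
        threshold_used=mask.threshold_used,
        field_name=mask.field_name,
    )


def filter_small_objects(mask: LabeledMask, min_area_px: int) -> LabeledMask:
    """Optional particle-size filter (off by default in the pipeline)."""
    if min_area_px <= 0:
        return mask
    areas = np.bincount(mask.labels.ravel())
    keep = np.flatnonzero(areas >= min_area_px)
    keep = keep[keep > 0]
    lut = np.zeros(areas.size, dtype=mask.labels.dtype)
    lut[keep] = np.arange(1, keep.size + 1, dtype=mask.labels.dtype)
    return LabeledMask(
        labels=lut[mask.labels],
        threshold_used=mask.threshold_used,
        field_name=mask.field_name,
    )


def fill_holes(mask: LabeledMask) -> LabeledMask:
    """Optional hole filling of each labeled object (off by default)."""
    filled = np.zeros_like(mask.labels)
    for lab in range(1, mask.n_objects + 1):
        obj = ndimage.binary_fill_holes(mask.labels == lab)
        filled[obj & (filled == 0)] = lab
    return LabeledMask(labels=filled, threshold_used=mask.threshold_used,
                       field_name=mask.field_name)


def object_areas(
    mask: LabeledMask, calibration: float
) -> Mapping[int, tuple[int, float]]:
    """Per-label pixel count and calibrated area (area_um2 = px * calibration^2)."""
    counts = np.bincount(mask.labels.ravel())
    cal2 = calibration * calibration
    return {
        lab: (int(counts[lab]), float(counts[lab]) * cal2)
        for lab in range(1, mask.n_objects + 1)
    }
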