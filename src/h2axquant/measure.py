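"""Per-nucleus intensity measurement.

Each nucleus detected in the DAPI channel is measured on the
background-subtracted Cy3 channel: the record carries the object's area in
pixels and square micrometres and its MFV, the arithmetic mean of the Cy3
intensities over the object's pixels.  The DAPI-derived labels are applied to
Cy3 as-is; an optional isotropic dilation of the ROI is available but
defaults to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import FieldImage
from .segmentation import LabeledMask


@dataclass(frozen=True)
class NucleusRecord:
    """One segmented nucleus with its area and mean Cy3 fluorescence."""

    well: str
    field: str
    label: int
    area_px: int
    area_um2: float
    mfv: float


def measure_objects(
    mask: LabeledMask,
    cy3_subtracted: FieldImage | np.ndarray,
    calibration: float,
    well: str = "",
    field: str = "",
    roi_dilation_px: int = 0,
) -> list[NucleusRecord]:
    """Mean Cy3 intensity and area for every label of an edge-excluded mask."""
    cy3 = (
        cy3_subtracted.pixels
        if isinstance(cy3_subtracted, FieldImage)
        else np.asarray(cy3_subtracted)
    )
    labels = mask.labels
    if cy3.shape != labels.shape:
        raise ValueError(
            f"shape mismatch: mask {labels.shape} vs Cy3 {cy3.shape}"
        )
    if roi_dilation_px > 0:
        labels = ndimage.grey_dilation(labels, size=2 * roi_dilation_px + 1)
        labels = np.where(mask.labels > 0, mask.labels, labels)

    n = mask.n_objects
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    sums = np.bincount(labels.ravel(), weights=cy3.ravel().astype(float),
                       minlength=n + 1)
    cal2 = calibration * calibration
    records = []
    for lab in range(1, n + 1):
        area_px = int(counts[lab])
        records.append(
            NucleusRecord(
                well=well,
                field=field or mask.field_name,
                label=lab,
                area_px=area_px,
                area_um2=area_px * cal2,
                mfv=float(sums[lab] / counts[lab]) if area_px else float("nan"),
            )
        )
    return records
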