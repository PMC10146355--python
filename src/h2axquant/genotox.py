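"""Genotoxicity statistics and classification.

The assay scores a treated condition against its negative control with three
numbers derived from the pooled well summaries:

    MoA  = MFV_mean / Area_mean          (area-normalised gammaH2AX signal)
    fold = MoA_sample / MoA_ctrl         (genotoxicity endpoint)
    RA   = 100 * Area_sample / Area_ctrl (relative area, cytotoxicity proxy
                                          standing in for relative cell counts)

and classifies with the standard gammaH2AX flow-cytometry criteria: a fold
above 1.5 with RA above the 25% viability limit is genotoxic; a fold below
1.5 is non-genotoxic; a fold above 1.5 with RA below 25% is
cytotoxicity-driven (false positive); a fold at exactly 1.5 with adequate RA
is equivocal.  Fold exactly at threshold with RA below the limit is undefined
in those criteria and is reported as NOT_EVALUABLE rather than silently
coerced; likewise RA exactly at the limit with an elevated fold is reported
EQUIVOCAL.  RA above 100% (proliferation above control) is allowed and
classified by the same rules.

Both fold and RA are ratios, so they are invariant to any common rescaling of
intensities (detector gain) and of the spatial calibration.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass

from .wellstats import WellSummary

logger = logging.getLogger("h2axquant")

DEFAULT_FOLD_THRESHOLD = 1.5
DEFAULT_RA_LIMIT = 25.0
_TOL = 1e-9


class Call(enum.Enum):
    GENOTOXIC = "genotoxic"
    NON_GENOTOXIC = "non-genotoxic"
    CYTOTOXICITY_DRIVEN_FALSE_POSITIVE = "cytotoxicity-driven false positive"
    EQUIVOCAL = "equivocal"
    NOT_EVALUABLE = "not evaluable"


@dataclass
class ConditionResult:
    """MoA, fold, RA and the genotoxicity call for one treated condition."""

    condition: str
    control_condition: str
    moa_sample: float
    moa_ctrl: float
    fold: float
    ra_percent: float
    call: Call


def moa(mfv_mean: float, area_mean: float) -> float:
    """Mean fluorescence value over mean area."""
    if not area_mean > 0:
        raise ValueError(f"area mean must be positive, got {area_mean}")
    return mfv_mean / area_mean


def fold_change(moa_sample: float, moa_ctrl: float) -> float:
    """MoA of the treated sample over MoA of its control."""
    if not moa_ctrl > 0:
        raise ValueError(f"control MoA must be positive, got {moa_ctrl}")
    return moa_sample / moa_ctrl


def relative_area(area_sample: float, area_ctrl: float) -> float:
    """Relative area in percent of control; the cytotoxicity proxy."""
    if not area_ctrl > 0:
        raise ValueError(f"control area must be positive, got {area_ctrl}")
    return 100.0 * area_sample / area_ctrl


def classify(
    fold: float,
    ra_percent: float,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    ra_limit: float = DEFAULT_RA_LIMIT,
) -> Call:
    """Genotoxic / non-genotoxic / false-positive / equivocal call.

    Non-finite inputs yield NOT_EVALUABLE.  Equality with the fold threshold
    or the RA limit is decided within a 1e-9 tolerance.
    """
    if not (math.isfinite(fold) and math.isfinite(ra_percent)):
        logger.warning("non-finite fold/RA (%s, %s): not evaluable", fold, ra_percent)
        return Call.NOT_EVALUABLE
    at_threshold = abs(fold - fold_threshold) <= _TOL
    at_limit = abs(ra_percent - ra_limit) <= _TOL
    if at_threshold:
        if at_limit or ra_percent > ra_limit:
            return Call.EQUIVOCAL
        logger.warning(
            "fold at threshold %.3g with RA %.3g%% below the %g%% limit is "
            "undefined in the evaluation criteria: not evaluable",
            fold_threshold, ra_percent, ra_limit,
        )
        return Call.NOT_EVALUABLE
    if fold < fold_threshold:
        return Call.NON_GENOTOXIC
    if at_limit:
        logger.warning(
            "fold %.3g above threshold with RA exactly at the %g%% limit: "
            "equivocal", fold, ra_limit,
        )
        return Call.EQUIVOCAL
    if ra_percent > ra_limit:
        return Call.GENOTOXIC
    return Call.CYTOTOXICITY_DRIVEN_FALSE_POSITIVE


def evaluate_condition(
    sample: WellSummary,
    control: WellSummary,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    ra_limit: float = DEFAULT_RA_LIMIT,
) -> ConditionResult:
    """Score one treated well summary against its control summary."""
    if sample.n_objects == 0 or control.n_objects == 0:
        logger.warning(
            "condition %r or control %r has no objects: not evaluable",
            sample.condition, control.condition,
        )
        nan = math.nan
        return ConditionResult(sample.condition, control.condition, nan, nan,
                               nan, nan, Call.NOT_EVALUABLE)
    moa_ctrl = moa(control.mfv_mean, control.area_mean_um2)
    moa_sample = moa(sample.mfv_mean, sample.area_mean_um2)
    fold = fold_change(moa_sample, moa_ctrl)
    ra = relative_area(sample.area_mean_um2, control.area_mean_um2)
    return ConditionResult(
        condition=sample.condition,
        control_condition=control.condition,
        moa_sample=moa_sample,
        moa_ctrl=moa_ctrl,
        fold=fold,
        ra_percent=ra,
        call=classify(fold, ra, fold_threshold, ra_limit),
    )
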