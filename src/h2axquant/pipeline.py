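"""End-to-end orchestration: sort -> segment -> subtract -> measure -> score.

The pipeline mirrors the assay's three-step structure (data sorting, image
analysis, feature analysis).  Per-well soft failures — a constant DAPI image,
a well with no complete channel pair — are logged and excluded; the affected
condition is reported NOT_EVALUABLE rather than aborting the run.  A
serialized copy of the effective configuration is written into every output
directory and two runs with identical inputs and configuration produce
identical result CSVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .background import rolling_ball_subtract
from .genotox import (
    DEFAULT_FOLD_THRESHOLD,
    DEFAULT_RA_LIMIT,
    ConditionResult,
    evaluate_condition,
)
from .io import (
    DEFAULT_CALIBRATION_UM_PER_PX,
    FieldPair,
    PlateLayout,
    read_field,
    sort_plate,
    write_condition_results,
    write_results,
)
from .measure import NucleusRecord, measure_objects
from .segmentation import (
    ConstantImageError,
    ThresholdPolicy,
    exclude_edge_objects,
    fill_holes as fill_mask_holes,
    filter_small_objects,
    segment_well,
)
from .wellstats import WellSummary, summarize_well

logger = logging.getLogger("h2axquant")


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run."""

    input_dir: Path
    output_dir: Path
    layout: PlateLayout
    threshold_mode: str = "per_well_first_field"
    threshold_bins: int = 256
    background_radius_px: int = 50
    background_smooth_pre: bool = False
    calibration_um_per_px: float = DEFAULT_CALIBRATION_UM_PER_PX
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD
    ra_limit_percent: float = DEFAULT_RA_LIMIT
    min_area_px: int = 0
    fill_holes: bool = False
    roi_dilation_px: int = 0
    channel_aliases: dict[str, str] = field(default_factory=dict)
    save_overlays: bool = False

    def to_serializable(self) -> dict:
        data = asdict(self)
        data["input_dir"] = str(self.input_dir)
        data["output_dir"] = str(self.output_dir)
        data["layout"] = {
            "wells": self.layout.conditions,
            "control": self.layout.control,
            "control_overrides": self.layout.control_overrides,
        }
        data["version"] = __version__
        return data


@dataclass
class PipelineResult:
    records: list[NucleusRecord]
    summaries: list[WellSummary]
    condition_results: list[ConditionResult]
    paths: dict[str, Path]
    failed_wells: list[str]


def _save_overlay(out_dir: Path, well: str, pair: FieldPair, labels, cy3_pixels):
    import imageio.v3 as iio
    from skimage import color, exposure

    base = exposure.rescale_intensity(cy3_pixels.astype(float), out_range=(0, 1))
    overlay = color.label2rgb(labels, image=base, bg_label=0, kind="overlay")
    path = out_dir / f"overlay_{well}_{pair.position}.jpg"
    iio.imwrite(path, (overlay * 255).astype(np.uint8))


def analyze_well(
    well: str,
    pairs: list[FieldPair],
    config: RunConfig,
) -> tuple[list[NucleusRecord], float, list[str]]:
    """Segment, subtract and measure every complete field pair of one well.

    Returns the per-object records, the threshold used, and log lines.
    """
    log_lines: list[str] = []
    dapi_fields = [
        read_field(p.dapi, config.calibration_um_per_px)
        for p in pairs if p.dapi is not None
    ]
    if not dapi_fields:
        raise ConstantImageError(f"well {well}: no DAPI fields")
    policy = ThresholdPolicy(mode=config.threshold_mode, bins=config.threshold_bins)
    masks = segment_well(dapi_fields, policy)
    mask_by_position = {m.field_name: m for m in masks}

    records: list[NucleusRecord] = []
    threshold = masks[0].threshold_used
    for pair in pairs:
        if not pair.complete:
            log_lines.append(f"well {well} position {pair.position}: incomplete pair, skipped")
            continue
        mask = mask_by_position[pair.position]
        mask = exclude_edge_objects(mask)
        if config.fill_holes:
            mask = fill_mask_holes(mask)
        if config.min_area_px > 0:
            mask = filter_small_objects(mask, config.min_area_px)
        cy3 = read_field(pair.cy3, config.calibration_um_per_px)
        cy3_sub = rolling_ball_subtract(
            cy3, radius=config.background_radius_px,
            smooth_pre=config.background_smooth_pre,
        )
        field_records = measure_objects(
            mask, cy3_sub, config.calibration_um_per_px,
            well=well, field=pair.position,
            roi_dilation_px=config.roi_dilation_px,
        )
        records.extend(field_records)
        log_lines.append(
            f"well {well} position {pair.position}: image {cy3.shape[0]}x{cy3.shape[1]}"
            f" threshold {mask.threshold_used:g} objects {mask.n_objects}"
        )
        if config.save_overlays:
            _save_overlay(config.output_dir, well, pair, mask.labels, cy3.pixels)
    return records, threshold, log_lines


def score_conditions(
    summaries: list[WellSummary],
    layout: PlateLayout,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    ra_limit: float = DEFAULT_RA_LIMIT,
) -> list[ConditionResult]:
    """Pool well summaries per condition and score treated vs control.

    When a condition spans several wells, objects are pooled by weighting the
    per-well means with the object counts, which equals pooling the raw
    records.
    """
    def pooled(condition: str) -> WellSummary | None:
        group = [s for s in summaries if s.condition == condition and s.n_objects > 0]
        if not group:
            return None
        n = sum(s.n_objects for s in group)
        mfv = sum(s.mfv_mean * s.n_objects for s in group) / n
        area = sum(s.area_mean_um2 * s.n_objects for s in group) / n
        rep = group[0]
        return WellSummary(
            well=",".join(s.well for s in group), condition=condition,
            n_objects=n, mfv_mean=mfv, mfv_iqr=float("nan"),
            mfv_median=float("nan"), area_mean_um2=area,
            area_iqr_um2=float("nan"), area_median_um2=float("nan"),
            threshold_used=rep.threshold_used,
        )

    results = []
    for condition in layout.treated_conditions:
        sample = pooled(condition)
        control = pooled(layout.control_for(condition))
        if sample is None or control is None:
            logger.warning("condition %r not evaluable: missing data", condition)
            nan = float("nan")
            from .genotox import Call
            results.append(ConditionResult(
                condition, layout.control_for(condition),
                nan, nan, nan, nan, Call.NOT_EVALUABLE,
            ))
            continue
        results.append(
            evaluate_condition(sample, control, fold_threshold, ra_limit)
        )
    return results


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full workflow and write all result files."""
    config.output_dir = Path(config.output_dir)
    config.output_dir.mkdir(parents=True, exist_ok=True)
    with open(config.output_dir / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_serializable(), fh, sort_keys=True)

    wells = sort_plate(config.input_dir, config.channel_aliases or None)
    records: list[NucleusRecord] = []
    summaries: list[WellSummary] = []
    failed_wells: list[str] = []
    log_lines = [f"threshold mode {config.threshold_mode}",
                 f"rolling-ball radius {config.background_radius_px}px",
                 f"calibration {config.calibration_um_per_px} um/px"]
    for well, pairs in wells.items():
        condition = config.layout.condition_of(well)
        if condition is None:
            logger.warning("well %s has no layout condition; skipped", well)
            log_lines.append(f"well {well}: not in layout, skipped")
            continue
        try:
            well_records, threshold, well_log = analyze_well(well, pairs, config)
        except ConstantImageError as exc:
            logger.warning("well %s failed: %s", well, exc)
            log_lines.append(f"well {well}: FAILED ({exc})")
            failed_wells.append(well)
            continue
        records.extend(well_records)
        log_lines.extend(well_log)
        summary = summarize_well(well_records, condition=condition,
                                 threshold_used=threshold)
        summary.well = summary.well or well
        summaries.append(summary)

    condition_results = score_conditions(
        summaries, config.layout, config.fold_threshold, config.ra_limit_percent
    )
    paths = write_results(records, summaries, config.output_dir, log_lines)
    paths["condition_results"] = write_condition_results(
        condition_results, config.output_dir
    )
    return PipelineResult(records, summaries, condition_results, paths,
                          failed_wells)
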