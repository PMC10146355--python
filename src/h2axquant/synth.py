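"""Synthetic two-channel plate generator with ground truth.

Emulates the acquisition geometry of the assay — a 96-well plate imaged as a
4x4 grid of single frames per well, two channels per field — so the whole
pipeline (sorting, segmentation, background subtraction, measurement, well
statistics, genotoxicity scoring) is testable end to end without a
microscope.  Each field contains non-overlapping elliptical nuclei with
Gaussian-blurred edges rendered into the DAPI channel; the Cy3 channel
carries a per-nucleus gammaH2AX amplitude plus a smooth additive background
gradient; both channels are corrupted by Poisson-Gaussian noise.  Default
parameters put pooled well totals in the 1000-3000 object range observed in
real wells of this assay.

Treatment effects are multiplicative, matching the direction observed with a
genotoxin: treated wells gain Cy3 signal while nucleus area and count drop.
``ConditionEffect.cy3_gain`` is defined as the designed fold change of the
*area-normalised* signal (the MoA endpoint): the per-pixel Cy3 amplitude is
multiplied by ``cy3_gain * area_scale`` while per-nucleus area scales by
``area_scale``, so a perfect pipeline recovers fold = cy3_gain and
RA = 100 * area_scale.

Nuclei are non-overlapping by construction (rejection sampling with bounded
retries) because the segmentation deliberately has no declumping step; an
overlap stress mode can be emulated by raising the packing density, but is
not part of the standard conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage

from .io import (
    CHANNEL_CY3,
    CHANNEL_DAPI,
    DEFAULT_CALIBRATION_UM_PER_PX,
    FieldImage,
    FieldImageRef,
    compose_field_filename,
)

logger = logging.getLogger("h2axquant")


@dataclass(frozen=True)
class ConditionEffect:
    """Multiplicative treatment effects applied to one condition's wells."""

    cy3_gain: float = 1.0    # designed fold on the area-normalised Cy3 signal
    area_scale: float = 1.0  # per-nucleus area multiplier
    count_scale: float = 1.0  # nuclei-per-field count multiplier

    def __post_init__(self) -> None:
        if self.cy3_gain <= 0 or self.area_scale <= 0 or self.count_scale < 0:
            raise ValueError("condition effect scales must be positive")


@dataclass(frozen=True)
class TruthNucleus:
    """Ground truth for one rendered nucleus."""

    well: str
    field: str
    index: int
    cx: float
    cy: float
    semi_major_px: float
    semi_minor_px: float
    theta: float
    area_px: int          # rendered (pre-blur) mask pixel count
    dapi_amplitude: float
    cy3_mean: float       # noise-free in-nucleus Cy3 amplitude
    touches_edge: bool


@dataclass
class SyntheticPlateConfig:
    """Generative parameters of a synthetic plate; fixed seed => identical output."""

    wells: dict[str, str] = dc_field(
        default_factory=lambda: {"B2": "ctrl", "B4": "treated"}
    )
    condition_effects: dict[str, ConditionEffect] = dc_field(
        default_factory=lambda: {
            "ctrl": ConditionEffect(),
            "treated": ConditionEffect(cy3_gain=3.0, area_scale=0.7,
                                       count_scale=0.8),
        }
    )
    control_condition: str = "ctrl"
    fields_per_well: int = 16          # 4x4 single frames per well
    image_size: tuple[int, int] = (512, 512)
    nuclei_per_field_mean: float = 125.0  # pooled well totals ~2000
    poisson_counts: bool = True        # False: exactly round(mean*count_scale)
    nucleus_radius_mean_px: float = 6.0
    nucleus_radius_sd_px: float = 1.0
    nucleus_min_radius_px: float = 2.0
    axis_ratio_max: float = 1.5        # major/minor, uniform in [1, max]
    edge_blur_sigma_px: float = 1.0
    dapi_amplitude_mean: float = 3000.0
    dapi_amplitude_sd: float = 600.0
    cy3_log_mean: float = float(np.log(300.0))  # log-normal per-nucleus amplitude
    cy3_log_sd: float = 0.5
    background_offset: float = 100.0   # additive Cy3 pedestal
    background_gradient: float = 40.0  # peak-to-peak planar gradient across field
    poisson_noise: bool = True         # shot noise on the clean signal
    gaussian_noise_sd: float = 5.0     # read noise
    bit_depth: int = 16
    calibration: float = DEFAULT_CALIBRATION_UM_PER_PX
    date_token: str = "20230101"
    acq_run: str = "01"
    file_extension: str = "tif"
    max_placement_retries: int = 200
    seed: int = 0

    def effect_for(self, condition: str) -> ConditionEffect:
        return self.condition_effects.get(condition, ConditionEffect())


def low_noise_benchmark_config(seed: int = 1) -> SyntheticPlateConfig:
    """Frozen low-noise plate for end-to-end parameter-recovery benchmarks.

    Three wells: a control, a genotoxin-like condition (designed MoA fold 3.0,
    area scale 0.7, count scale 0.8) and a sham condition with the same
    cytotoxicity but no signal gain (designed fold 1.0).  Runtime-scaled
    problem size: 256x256 px fields, 16 fields per well, ~45 nuclei of ~8 px
    radius per field.  Low noise means read noise only (no shot noise) and
    narrow per-nucleus amplitude spreads, so the recovered fold and RA isolate
    estimator bias from population heterogeneity.
    """
    return SyntheticPlateConfig(
        wells={"B2": "ctrl", "B4": "treated", "B6": "sham"},
        condition_effects={
            "ctrl": ConditionEffect(),
            "treated": ConditionEffect(cy3_gain=3.0, area_scale=0.7,
                                       count_scale=0.8),
            "sham": ConditionEffect(cy3_gain=1.0, area_scale=0.7,
                                    count_scale=0.8),
        },
        fields_per_well=16,
        image_size=(256, 256),
        nuclei_per_field_mean=45.0,
        nucleus_radius_mean_px=8.0,
        dapi_amplitude_sd=300.0,
        poisson_noise=False,
        gaussian_noise_sd=2.0,
        cy3_log_sd=0.2,
        seed=seed,
    )


def _field_rng(config: SyntheticPlateConfig, well: str, field_index: int
               ) -> np.random.Generator:
    # stable per-field stream independent of generation order
    well_key = (ord(well[0]) - ord("A")) * 12 + int(well[1:])
    return np.random.default_rng([config.seed, well_key, field_index])


def _sample_nuclei(
    config: SyntheticPlateConfig,
    effect: ConditionEffect,
    rng: np.random.Generator,
) -> list[tuple[float, float, float, float, float]]:
    """Rejection-sample non-overlapping (cx, cy, a, b, theta) ellipses."""
    h, w = config.image_size
    if config.poisson_counts:
        n_target = int(rng.poisson(config.nuclei_per_field_mean * effect.count_scale))
    else:
        n_target = int(round(config.nuclei_per_field_mean * effect.count_scale))
    placed: list[tuple[float, float, float, float, float]] = []
    size_factor = np.sqrt(effect.area_scale)
    for _ in range(n_target):
        for _attempt in range(config.max_placement_retries):
            r = max(
                rng.normal(config.nucleus_radius_mean_px, config.nucleus_radius_sd_px),
                config.nucleus_min_radius_px,
            ) * size_factor
            ratio = rng.uniform(1.0, config.axis_ratio_max)
            a = r * np.sqrt(ratio)   # semi-major; area ~= pi r^2 preserved
            b = r / np.sqrt(ratio)
            theta = rng.uniform(0.0, np.pi)
            cx = rng.uniform(0.0, w)
            cy = rng.uniform(0.0, h)
            margin = 2.0 + 2.0 * config.edge_blur_sigma_px
            if all(
                (cx - px) ** 2 + (cy - py) ** 2 > (a + pa + margin) ** 2
                for px, py, pa, _pb, _pt in placed
            ):
                placed.append((cx, cy, a, b, theta))
                break
        else:
            logger.warning(
                "placed only %d of %d nuclei without overlap", len(placed), n_target
            )
            break
    return placed


def _ellipse_mask(shape: tuple[int, int], cx: float, cy: float,
                  a: float, b: float, theta: float) -> np.ndarray:
    h, w = shape
    r_ext = int(np.ceil(max(a, b))) + 1
    x0, x1 = int(np.floor(cx)) - r_ext, int(np.ceil(cx)) + r_ext + 1
    y0, y1 = int(np.floor(cy)) - r_ext, int(np.ceil(cy)) + r_ext + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
    dx, dy = xx - cx, yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    local = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask = np.zeros(shape, dtype=bool)
    mask[y0c:y1c, x0c:x1c] = local
    return mask


def generate_field(
    config: SyntheticPlateConfig,
    well: str,
    field_index: int,
    rng: np.random.Generator | None = None,
) -> tuple[FieldImage, FieldImage, list[TruthNucleus]]:
    """Render one DAPI/Cy3 field pair plus its ground truth.

    ``field_index`` is zero-based; the position token in the refs is the
    one-based zero-padded index.
    """
    rng = rng if rng is not None else _field_rng(config, well, field_index)
    condition = config.wells.get(well, config.control_condition)
    effect = config.effect_for(condition)
    h, w = config.image_size
    position = f"{field_index + 1:04d}"

    ellipses = _sample_nuclei(config, effect, rng)
    dapi_signal = np.zeros((h, w), dtype=float)
    cy3_signal = np.zeros((h, w), dtype=float)
    truth: list[TruthNucleus] = []
    pixel_gain = effect.cy3_gain * effect.area_scale
    for i, (cx, cy, a, b, theta) in enumerate(ellipses):
        mask = _ellipse_mask((h, w), cx, cy, a, b, theta)
        area_px = int(mask.sum())
        if area_px == 0:
            continue
        dapi_amp = max(
            rng.normal(config.dapi_amplitude_mean, config.dapi_amplitude_sd), 1.0
        )
        cy3_amp = float(np.exp(rng.normal(config.cy3_log_mean, config.cy3_log_sd)))
        cy3_amp *= pixel_gain
        dapi_signal[mask] = dapi_amp
        cy3_signal[mask] = cy3_amp
        ys, xs = np.nonzero(mask)
        touches = bool(
            (ys == 0).any() or (ys == h - 1).any()
            or (xs == 0).any() or (xs == w - 1).any()
        )
        truth.append(TruthNucleus(
            well=well, field=position, index=i, cx=cx, cy=cy,
            semi_major_px=a, semi_minor_px=b, theta=theta, area_px=area_px,
            dapi_amplitude=dapi_amp, cy3_mean=cy3_amp, touches_edge=touches,
        ))

    # edge blur applies to the rendered nuclei of the DAPI channel; the Cy3
    # signal is a flat per-nucleus amplitude so that the in-mask mean is the
    # ground-truth amplitude
    if config.edge_blur_sigma_px > 0:
        dapi_signal = ndimage.gaussian_filter(dapi_signal, config.edge_blur_sigma_px)

    yy, xx = np.mgrid[0:h, 0:w]
    gradient = config.background_gradient * (xx + yy) / max(h + w - 2, 1)
    cy3_clean = cy3_signal + config.background_offset + gradient
    dapi_clean = dapi_signal

    def _digitize(clean: np.ndarray) -> np.ndarray:
        noisy = rng.poisson(clean).astype(float) if config.poisson_noise else clean
        if config.gaussian_noise_sd > 0:
            noisy = noisy + rng.normal(0.0, config.gaussian_noise_sd, clean.shape)
        limit = 2 ** config.bit_depth - 1
        dtype = np.uint8 if config.bit_depth == 8 else np.uint16
        return np.clip(np.rint(noisy), 0, limit).astype(dtype)

    def _ref(channel: str) -> FieldImageRef:
        return FieldImageRef(
            channel=channel, date_token=config.date_token, well=well,
            position=position, acq_run=config.acq_run,
            extension=config.file_extension,
        )

    dapi = FieldImage(_digitize(dapi_clean), config.bit_depth,
                      config.calibration, _ref(CHANNEL_DAPI))
    cy3 = FieldImage(_digitize(cy3_clean), config.bit_depth,
                     config.calibration, _ref(CHANNEL_CY3))
    return dapi, cy3, truth


def iter_plate(config: SyntheticPlateConfig) -> Iterator[
    tuple[FieldImage, FieldImage, list[TruthNucleus]]
]:
    for well in sorted(config.wells):
        for field_index in range(config.fields_per_well):
            yield generate_field(config, well, field_index)


def generate_plate(config: SyntheticPlateConfig, out_dir: Path | str) -> Path:
    """Write the plate as convention-named TIFFs plus truth CSV and layout YAML.

    The output folder is directly consumable by :func:`h2axquant.io.sort_plate`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth_rows: list[dict] = []
    for dapi, cy3, truth in iter_plate(config):
        for img in (dapi, cy3):
            assert img.ref is not None
            tifffile.imwrite(out_dir / compose_field_filename(img.ref), img.pixels)
        truth_rows.extend(asdict(t) for t in truth)
    pd.DataFrame(truth_rows).to_csv(out_dir / "ground_truth.csv", index=False)
    layout = {
        "wells": dict(sorted(config.wells.items())),
        "control": config.control_condition,
    }
    with open(out_dir / "layout.yaml", "w") as fh:
        yaml.safe_dump(layout, fh, sort_keys=True)
    return out_dir
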