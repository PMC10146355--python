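"""Plate I/O: filename convention, plate sorting, image reading, result tables.

Acquisition software exports every field of a 96-well plate as a flat dump of
single-channel grayscale TIFFs named

    ``ChannelName_DateToken_Well_PositionInWell_AcqRun.Extension``

e.g. ``DAPI_20230101_B8_0003_01.tif``.  Two channels are acquired per field:
a DNA counterstain (DAPI/Hoechst) used for nuclei segmentation and a Cy3
channel carrying the gammaH2AX immunofluorescence signal.  This module parses
that convention, groups the dump into per-well channel pairs, reads the TIFFs
into calibrated :class:`FieldImage` containers and writes the per-object /
per-well CSV outputs together with a plain-text run log.

The date token is kept as an opaque string (its day width is ambiguous in the
wild) and channel spellings are configurable through an alias map.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from . import __version__

logger = logging.getLogger("h2axquant")

CHANNEL_DAPI = "DAPI"
CHANNEL_CY3 = "Cy3"

#: default spelling → canonical channel name; matching is case-insensitive
DEFAULT_CHANNEL_ALIASES: Mapping[str, str] = {
    "dapi": CHANNEL_DAPI,
    "hoechst": CHANNEL_DAPI,
    "cy3": CHANNEL_CY3,
}

_WELL_RE = re.compile(r"^[A-H](1[0-2]|[1-9])$")

#: micrometres per pixel edge: 650 nm camera pixels, 4x4 binning, 10x objective
DEFAULT_CALIBRATION_UM_PER_PX = 0.65 * 4


class MalformedFilenameError(ValueError):
    """Filename does not follow the five-token acquisition convention."""


class EmptyPlateError(ValueError):
    """No parseable field image found in the input folder."""


@dataclass(frozen=True)
class FieldImageRef:
    """Identity of one acquired field: channel, well, position and source file."""

    channel: str
    date_token: str
    well: str
    position: str
    acq_run: str
    extension: str = "tif"
    path: Path | None = None

    def __post_init__(self) -> None:
        if self.channel not in (CHANNEL_DAPI, CHANNEL_CY3):
            raise MalformedFilenameError(f"unsupported channel {self.channel!r}")
        if not _WELL_RE.match(self.well):
            raise MalformedFilenameError(f"invalid well token {self.well!r}")

    @property
    def filename(self) -> str:
        return compose_field_filename(self)


@dataclass
class FieldImage:
    """One single-channel grayscale field with spatial calibration.

    ``calibration`` is the isotropic pixel edge length in micrometres.
    """

    pixels: np.ndarray
    bit_depth: int
    calibration: float = DEFAULT_CALIBRATION_UM_PER_PX
    ref: FieldImageRef | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("field image must be a 2-D array")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.pixels.size and (
            self.pixels.min() < 0 or self.pixels.max() > 2**self.bit_depth - 1
        ):
            raise ValueError("pixel values outside the bit-depth range")
        if not self.calibration > 0:
            raise ValueError("calibration must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class FieldPair:
    """DAPI/Cy3 refs of one field position; either side may be missing."""

    position: str
    dapi: FieldImageRef | None = None
    cy3: FieldImageRef | None = None

    @property
    def complete(self) -> bool:
        return self.dapi is not None and self.cy3 is not None


@dataclass
class PlateLayout:
    """Mapping of wells to condition labels plus the control designation.

    ``conditions`` maps a well (e.g. ``"B8"``) to a condition label;
    ``control`` names the condition every treated condition is compared to.
    A per-condition override map may be supplied when different treatment
    groups use different controls.
    """

    conditions: dict[str, str]
    control: str
    control_overrides: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for well in self.conditions:
            if not _WELL_RE.match(well):
                raise ValueError(f"invalid well {well!r} in layout")
        if self.control not in self.conditions.values():
            raise ValueError(f"control condition {self.control!r} has no well")

    def condition_of(self, well: str) -> str | None:
        return self.conditions.get(well)

    def control_for(self, condition: str) -> str:
        return self.control_overrides.get(condition, self.control)

    def wells_of(self, condition: str) -> list[str]:
        return sorted(w for w, c in self.conditions.items() if c == condition)

    @property
    def treated_conditions(self) -> list[str]:
        ctrl_like = {self.control} | set(self.control_overrides.values())
        return sorted(set(self.conditions.values()) - ctrl_like)

    @classmethod
    def from_dict(cls, data: Mapping) -> "PlateLayout":
        return cls(
            conditions=dict(data["wells"]),
            control=str(data["control"]),
            control_overrides=dict(data.get("control_overrides", {})),
        )


def parse_field_filename(
    name: str, channel_aliases: Mapping[str, str] | None = None
) -> FieldImageRef:
    """Split a bare filename into its five convention tokens.

    Raises :class:`MalformedFilenameError` when the token count is not five,
    the channel spelling is unknown, or the well token is invalid.
    """
    aliases = dict(DEFAULT_CHANNEL_ALIASES)
    if channel_aliases:
        aliases.update({k.lower(): v for k, v in channel_aliases.items()})
    stem, dot, extension = name.rpartition(".")
    if not dot or not stem:
        raise MalformedFilenameError(f"{name!r} has no extension")
    tokens = stem.split("_")
    if len(tokens) != 5:
        raise MalformedFilenameError(
            f"{name!r}: expected 5 underscore-separated tokens, got {len(tokens)}"
        )
    channel_token, date_token, well, position, acq_run = tokens
    channel = aliases.get(channel_token.lower())
    if channel is None:
        raise MalformedFilenameError(f"{name!r}: unknown channel {channel_token!r}")
    return FieldImageRef(
        channel=channel,
        date_token=date_token,
        well=well,
        position=position,
        acq_run=acq_run,
        extension=extension,
    )


def compose_field_filename(ref: FieldImageRef) -> str:
    return (
        f"{ref.channel}_{ref.date_token}_{ref.well}_{ref.position}"
        f"_{ref.acq_run}.{ref.extension}"
    )


def sort_plate(
    folder: Path | str, channel_aliases: Mapping[str, str] | None = None
) -> dict[str, list[FieldPair]]:
    """Group a flat image dump into per-well lists of channel-paired fields.

    Non-parseable files are skipped with a warning.  Pairing across channels
    is by exact position-token match; a position with only one channel is kept
    and flagged incomplete (warning logged).  Output ordering is deterministic:
    wells sorted, positions sorted lexicographically within each well,
    regardless of directory iteration order.
    """
    folder = Path(folder)
    refs: list[FieldImageRef] = []
    for path in sorted(folder.iterdir()):
        if not path.is_file():
            continue
        try:
            ref = parse_field_filename(path.name, channel_aliases)
        except MalformedFilenameError as exc:
            logger.warning("skipping non-conforming file: %s", exc)
            continue
        refs.append(replace(ref, path=path))
    if not refs:
        raise EmptyPlateError(f"no parseable field images in {folder}")

    wells: dict[str, dict[str, dict[str, FieldImageRef]]] = {}
    for ref in refs:
        pos = wells.setdefault(ref.well, {}).setdefault(ref.position, {})
        if ref.channel in pos:
            logger.warning(
                "duplicate %s image for well %s position %s; keeping first",
                ref.channel, ref.well, ref.position,
            )
            continue
        pos[ref.channel] = ref

    out: dict[str, list[FieldPair]] = {}
    for well in sorted(wells):
        pairs = []
        for position in sorted(wells[well]):
            chans = wells[well][position]
            pair = FieldPair(
                position=position,
                dapi=chans.get(CHANNEL_DAPI),
                cy3=chans.get(CHANNEL_CY3),
            )
            if not pair.complete:
                logger.warning(
                    "well %s position %s has only the %s channel",
                    well, position, CHANNEL_DAPI if pair.dapi else CHANNEL_CY3,
                )
            pairs.append(pair)
        out[well] = pairs
    return out


def read_field(
    ref: FieldImageRef, calibration: float = DEFAULT_CALIBRATION_UM_PER_PX
) -> FieldImage:
    """Load one single-page grayscale TIFF into a calibrated FieldImage."""
    if ref.path is None:
        raise ValueError("FieldImageRef has no path to read from")
    pixels = tifffile.imread(ref.path)
    if pixels.ndim != 2:
        raise ValueError(f"{ref.path}: expected a single-page grayscale image")
    if pixels.dtype == np.uint8:
        bit_depth = 8
    elif pixels.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(f"{ref.path}: unsupported dtype {pixels.dtype}")
    return FieldImage(pixels=pixels, bit_depth=bit_depth,
                      calibration=calibration, ref=ref)


# ---------------------------------------------------------------------------
# result tables

OBJECT_COLUMNS = ["well", "field", "label", "area_px", "area_um2", "mfv"]


def records_to_frame(records: Sequence) -> pd.DataFrame:
    rows = [
        {
            "well": r.well, "field": r.field, "label": r.label,
            "area_px": r.area_px, "area_um2": r.area_um2, "mfv": r.mfv,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=OBJECT_COLUMNS)


def summaries_to_frame(summaries: Sequence) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append({
            "well": s.well,
            "condition": s.condition,
            "n_objects": s.n_objects,
            "mfv_mean": s.mfv_mean,
            "mfv_iqr": s.mfv_iqr,
            "mfv_median": s.mfv_median,
            "area_mean_um2": s.area_mean_um2,
            "area_iqr_um2": s.area_iqr_um2,
            "area_median_um2": s.area_median_um2,
            "threshold_used": s.threshold_used,
            "mfv_normality_p": s.mfv_normality.p,
            "mfv_normality_verdict": s.mfv_normality.verdict,
            "area_normality_p": s.area_normality.p,
            "area_normality_verdict": s.area_normality.verdict,
        })
    return pd.DataFrame(rows)


def write_results(
    records: Sequence,
    summaries: Sequence,
    out_dir: Path | str,
    log_lines: Iterable[str] = (),
) -> dict[str, Path]:
    """Write per-well object CSVs, the plate summary CSV and the run log.

    CSVs use '.' decimals and ',' delimiters.  Reruns on identical inputs are
    byte-identical except for the timestamp line of the log.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    frame = records_to_frame(records)
    if frame.empty:
        logger.warning("no object records to write")
        wells: list[str] = []
    else:
        wells = sorted(frame["well"].unique())
    for well in wells:
        p = out_dir / f"objects_{well}.csv"
        frame[frame["well"] == well].to_csv(p, index=False)
        paths[f"objects_{well}"] = p
    if not wells:
        p = out_dir / "objects_empty.csv"
        frame.to_csv(p, index=False)
        paths["objects_empty"] = p

    p = out_dir / "well_summary.csv"
    summaries_to_frame(summaries).to_csv(p, index=False)
    paths["well_summary"] = p

    import datetime

    log_path = out_dir / "run_log.txt"
    with open(log_path, "w") as fh:
        fh.write(f"h2axquant version {__version__}\n")
        fh.write(f"timestamp {datetime.datetime.now().isoformat()}\n")
        for line in log_lines:
            fh.write(line.rstrip("\n") + "\n")
    paths["run_log"] = log_path
    return paths


def write_condition_results(results: Sequence, out_dir: Path | str) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "condition": r.condition,
            "control_condition": r.control_condition,
            "moa_sample": r.moa_sample,
            "moa_ctrl": r.moa_ctrl,
            "fold": r.fold,
            "ra_percent": r.ra_percent,
            "call": r.call.name,
        }
        for r in results
    ]
    frame = pd.DataFrame(
        rows,
        columns=["condition", "control_condition", "moa_sample", "moa_ctrl",
                 "fold", "ra_percent", "call"],
    )
    path = out_dir / "condition_results.csv"
    frame.to_csv(path, index=False)
    return path
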