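"""Published valinomycin benchmark values for the gammaH2AX assay.

Well-level summary statistics from a published valinomycin exposure
experiment on HeLa and CHO-K1 cells (30 and 15 uM, 4 h and 24 h, DMSO
control), as printed: pooled per-well MFV mean and IQR, nucleus-area mean and
IQR (um^2), and the derived MoA, fold and RA columns.  Also included is an
independent reference from a commercial high-content-screening platform:
A549 cells, 30 uM valinomycin, 24 h, scored as mean nuclear gammaH2AX
intensity over cell number — the same arithmetic with cell count taking the
place of nuclear area.

These values are regression benchmarks for the fold/RA statistics: feeding
the printed MFV and area means through :mod:`h2axquant.genotox` must
reproduce the printed MoA, fold and RA columns within the rounding of the
printed inputs (1% relative).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BenchmarkRow:
    """One printed well row: inputs (mean/IQR) and derived columns."""

    cell_line: str
    time_h: int
    sample: str            # "ctrl" | "val30" | "val15"
    mfv_mean: float
    mfv_iqr: float
    area_mean: float       # um^2 as printed
    area_iqr: float
    moa: float             # printed MoA column
    fold: float            # printed fold column (1 for control)
    ra_percent: float      # printed RA column


#: printed well summaries: 4 h and 24 h valinomycin exposures
VALINOMYCIN_WELLS: tuple[BenchmarkRow, ...] = (
    BenchmarkRow("CHO-K1", 4, "ctrl",  1.641, 1.520, 2.130, 1.058, 0.770, 1.000, 100.00),
    BenchmarkRow("CHO-K1", 4, "val30", 2.179, 1.872, 1.423, 0.862, 1.531, 1.987, 66.81),
    BenchmarkRow("CHO-K1", 4, "val15", 2.151, 1.439, 1.614, 0.814, 1.333, 1.730, 75.78),
    BenchmarkRow("HeLa",   4, "ctrl",  0.132, 0.166, 3.249, 1.334, 0.041, 1.000, 100.00),
    BenchmarkRow("HeLa",   4, "val30", 0.127, 0.149, 2.955, 1.109, 0.043, 1.063, 90.94),
    BenchmarkRow("HeLa",   4, "val15", 0.119, 0.147, 3.040, 1.167, 0.039, 0.966, 93.56),
    BenchmarkRow("CHO-K1", 24, "ctrl",  1.518, 1.509, 2.186, 0.973, 0.694, 1.000, 100.00),
    BenchmarkRow("CHO-K1", 24, "val30", 2.785, 3.229, 0.893, 0.405, 3.119, 4.495, 40.83),
    BenchmarkRow("CHO-K1", 24, "val15", 2.605, 2.670, 1.173, 0.572, 2.221, 3.199, 53.66),
    BenchmarkRow("HeLa",   24, "ctrl",  0.064, 0.082, 2.919, 1.276, 0.022, 1.000, 100.00),
    BenchmarkRow("HeLa",   24, "val30", 0.595, 0.324, 2.070, 0.806, 0.287, 13.200, 70.91),
    BenchmarkRow("HeLa",   24, "val15", 0.358, 0.275, 2.227, 0.893, 0.161, 7.376, 76.30),
)


@dataclass(frozen=True)
class HCSReferenceRow:
    """Commercial HCS platform reference: intensity over cell number."""

    sample: str
    gh2ax_response: float   # mean nuclear gammaH2AX intensity
    cell_number: float
    mean_over_cell_number: float
    fold: float
    relative_cell_number_percent: float


#: A549, 30 uM valinomycin, 24 h (digitised from the kit manufacturer's chart)
A549_HCS_REFERENCE: tuple[HCSReferenceRow, ...] = (
    HCSReferenceRow("ctrl",  90.4, 184.0, 0.491, 1.0, 100.0),
    HCSReferenceRow("val30", 201.5, 72.9, 2.764, 5.6, 40.0),
)


def get_row(cell_line: str, time_h: int, sample: str) -> BenchmarkRow:
    for row in VALINOMYCIN_WELLS:
        if (row.cell_line, row.time_h, row.sample) == (cell_line, time_h, sample):
            return row
    raise KeyError((cell_line, time_h, sample))
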