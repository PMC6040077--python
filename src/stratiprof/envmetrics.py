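"""Closed-form environmental and cytometry computations.

Includes the water-column nutrient table of the photic-zone field campaign
(a printed table used as input data) for N:P recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

#: Total N / Total P (uM) of the nine water-column samples of the field
#: campaign (two winter-mixing, six stratified photic, one aphotic).
WATER_COLUMN_NUTRIENTS: pd.DataFrame = pd.DataFrame(
    [
        ("MedWinter-JAN2015-20m", 20, "mixed", 3.68, 0.15),
        ("MedWinter-JAN2015-80m", 80, "mixed", 4.36, 0.12),
        ("Med-OCT2015-15m", 15, "stratified", 0.40, 0.10),
        ("Med-OCT2015-30m", 30, "stratified", 0.41, 0.12),
        ("Med-OCT2015-45m", 45, "stratified", 0.48, 0.14),
        ("Med-OCT2015-60m", 60, "stratified", 0.46, 0.12),
        ("Med-OCT2015-75m", 75, "stratified", 6.33, 0.16),
        ("Med-OCT2015-90m", 90, "stratified", 6.90, 0.25),
        ("Med-OCT2015-1000m", 1000, "aphotic", 8.89, 0.45),
    ],
    columns=["sample_id", "depth_m", "season", "total_n_uM", "total_p_uM"],
)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero (reporting convention for ratios)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def np_ratio(total_n_uM: float, total_p_uM: float) -> float:
    """Molar N:P ratio; use round_half_up(..., 2) for reporting."""
    if total_p_uM <= 0:
        raise ValueError("total_p_uM must be > 0 for an N:P ratio")
    return total_n_uM / total_p_uM


def np_table(nutrients: pd.DataFrame | None = None) -> pd.DataFrame:
    """N:P ratios (2-decimal reporting) for a nutrient table."""
    df = (nutrients if nutrients is not None else WATER_COLUMN_NUTRIENTS).copy()
    df["np_ratio"] = [
        round_half_up(np_ratio(n, p), 2)
        for n, p in zip(df["total_n_uM"], df["total_p_uM"])
    ]
    return df


@dataclass(frozen=True)
class CytometryRun:
    """One flow-cytometry acquisition."""

    n_events: int
    flow_rate_uL_per_min: float
    duration_min: float

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if self.flow_rate_uL_per_min <= 0 or self.duration_min <= 0:
            raise ValueError("flow rate and duration must be > 0")


def cytometry_concentration(run: CytometryRun) -> float:
    """Cells per mL: N = (n x 1000) / (q x t), q in uL/min, t in minutes."""
    return run.n_events * 1000.0 / (run.flow_rate_uL_per_min * run.duration_min)


def seconds_to_minutes(seconds: float) -> float:
    return seconds / 60.0
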