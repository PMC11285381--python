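"""Screening of raw actigraphy and 30 s → 60 s aggregation.

A recording is usable when it is long enough (>= 5760 min, i.e. four days)
and contains a continuous wearing period of at least the same length, where
"continuous wearing" means no run of consecutive zero counts exceeding
120 min. A zero-run of exactly the cap does NOT split a wearing period
("no more than" reads as strictly-greater splits); the splitting run is
excluded from both neighbouring periods. Downstream detection runs on the
single longest wearing period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .io import ActigraphySeries


@dataclass(frozen=True)
class WearPeriod:
    """Half-open epoch interval ``[start_idx, end_idx)`` of continuous wear."""

    start_idx: int
    end_idx: int
    duration_min: float

    def __post_init__(self):
        if not self.start_idx < self.end_idx:
            raise ContractError("WearPeriod requires start_idx < end_idx")


@dataclass(frozen=True)
class ScreenResult:
    passed: bool
    total_min: float
    longest_period: WearPeriod | None
    reason: str


def find_wear_periods(
    series: ActigraphySeries, max_zero_run_min: float = 120.0
) -> list[WearPeriod]:
    """Maximal intervals whose internal zero-runs never exceed the cap.

    Zero-runs strictly longer than ``max_zero_run_min`` split the recording
    and are excluded from both sides; shorter runs stay inside a period.
    Segments consisting solely of zeros are dropped (nothing was worn).
    """
    vals = series.values
    cap_epochs = int(round(max_zero_run_min * 60.0 / series.epoch_s))
    is_zero = vals == 0

    periods: list[WearPeriod] = []
    seg_start = 0
    # boundaries of zero-runs
    padded = np.concatenate(([False], is_zero, [False]))
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])

    def emit(lo, hi):
        if hi > lo and np.any(vals[lo:hi] != 0):
            periods.append(
                WearPeriod(int(lo), int(hi), (hi - lo) * series.epoch_s / 60.0)
            )

    for zs, ze in zip(starts, ends):
        if ze - zs > cap_epochs:  # splitting run
            emit(seg_start, zs)
            seg_start = ze
    emit(seg_start, series.n)
    return periods


def screen(
    series: ActigraphySeries,
    min_total_min: float = 5760.0,
    min_period_min: float = 5760.0,
    max_zero_run_min: float = 120.0,
) -> ScreenResult:
    """Apply the inclusion rules; ``reason`` names the first failed rule."""
    total = series.duration_min
    periods = find_wear_periods(series, max_zero_run_min)
    longest = max(periods, key=lambda p: p.duration_min, default=None)
    if total < min_total_min:
        return ScreenResult(False, total, longest, f"total<{min_total_min:g}")
    if longest is None or longest.duration_min < min_period_min:
        return ScreenResult(
            False, total, longest, f"longest_period<{min_period_min:g}"
        )
    return ScreenResult(True, total, longest, "ok")


def aggregate_to_60s(series: ActigraphySeries) -> ActigraphySeries:
    """Sum consecutive pairs of 30 s epochs into 60 s epochs.

    Counts are additive intensities, so aggregation is a sum, not a mean.
    A trailing unpaired epoch is truncated with a warning.
    """
    if series.epoch_s != 30:
        raise ContractError(f"expected epoch_s=30, got {series.epoch_s}")
    vals = series.values
    if vals.size % 2:
        warnings.warn(
            f"subject {series.subject_id}: odd number of 30 s epochs; "
            "truncating the trailing epoch",
            stacklevel=2,
        )
        vals = vals[:-1]
    agg = vals.reshape(-1, 2).sum(axis=1)
    return ActigraphySeries(
        subject_id=series.subject_id,
        start_time=series.start_time,
        epoch_s=60,
        values=agg,
    )


def crop_to_period(series: ActigraphySeries, period: WearPeriod) -> ActigraphySeries:
    """Restrict a series to one wear period (detection runs on the longest)."""
    return ActigraphySeries(
        subject_id=series.subject_id,
        start_time=series.time_at(period.start_idx),
        epoch_s=series.epoch_s,
        values=series.values[period.start_idx : period.end_idx],
    )
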