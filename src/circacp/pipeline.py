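"""End-to-end sleep/wake onset detection for one subject.

The algorithm has two stages. First the cosinor model segments the
recording into rough circadian cycles: the dichotomized fitted curve gives
alternating diurnal/nocturnal states whose transition edges are coarse
sleep/wake onset estimates. The fixed-period cosinor cannot express
day-to-day variability, so in the second stage each rough transition is
refined by a single Gamma change-point search inside a window built around
it: windows span midpoint-to-midpoint between adjacent rough transitions,
which guarantees exactly one true transition per window under monophasic
sleep. A second search round then rebuilds the windows from the
first-round change points themselves (whose placement no longer depends on
the rigid cosinor phase) and re-runs the search once, relocating change
points that a poor window boundary had displaced.

The change point ``k`` is the last epoch of the old regime, so the emitted
event is stamped at the START of epoch ``k+1`` — the first epoch of the
new regime.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import changepoint, cosinor, preprocess, qc, validation
from .config import RunConfig
from .cosinor import CosinorFit, Direction, RoughCycle
from .changepoint import CpResult
from .errors import (
    ContractError,
    DegenerateRhythmError,
    NoEventsError,
    NoRhythmError,
    WindowTooShortError,
)
from .io import ActigraphySeries, EventKind, EventSource, SwotEvent

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchWindow:
    """Half-open epoch interval expected to hold exactly one transition."""

    lo: int
    hi: int
    direction: Direction
    anchor: int

    def __post_init__(self):
        if not (self.lo < self.anchor < self.hi):
            raise ContractError(
                f"window [{self.lo},{self.hi}) must strictly contain "
                f"anchor {self.anchor}"
            )

    @property
    def n(self) -> int:
        return self.hi - self.lo


@dataclass(frozen=True)
class DetectionResult:
    subject_id: str
    events: tuple
    rough: RoughCycle
    fit: CosinorFit
    windows: tuple
    cp_results: tuple
    qc: qc.QcReport


def build_windows(
    rough: RoughCycle, series_n: int, min_window: int = 240
) -> list[SearchWindow]:
    """One search window per rough transition, midpoint-to-midpoint.

    Boundaries are midpoints between consecutive transitions (the series
    ends for the outermost); windows shorter than ``min_window`` epochs are
    dropped with a log record.
    """
    if not rough.transitions:
        raise NoRhythmError("dichotomized curve has no transitions")
    anchors = [idx for idx, _ in rough.transitions]
    bounds = [0]
    bounds += [(a + b) // 2 for a, b in zip(anchors, anchors[1:])]
    bounds.append(series_n)
    windows = []
    for (idx, direction), lo, hi in zip(rough.transitions, bounds, bounds[1:]):
        if hi - lo < min_window:
            logger.warning(
                "dropping window [%d,%d) (%d epochs < min_window=%d)",
                lo, hi, hi - lo, min_window,
            )
            continue
        windows.append(SearchWindow(lo=lo, hi=hi, direction=direction, anchor=idx))
    return windows


def _detect_in_window(series_values, win: SearchWindow, config: RunConfig) -> CpResult:
    return changepoint.detect_cp(
        series_values[win.lo : win.hi],
        lam=config.cp_lambda,
        min_seg=config.cp_min_seg,
        eps=config.cp_eps,
        origin_idx=win.lo,
    )


def refine(
    first_round: list[CpResult],
    series: ActigraphySeries,
    config: RunConfig,
    directions: list[Direction] | None = None,
) -> tuple[list[CpResult], list[SearchWindow]]:
    """Second-round search in windows rebuilt from first-round change points.

    Midpoints between consecutive first-round CPs replace the cosinor
    anchors; each new window gets a fresh shape estimate and one re-run of
    the search. A refined CP replaces its predecessor only if it lies
    inside its new window; windows too short to search keep the
    first-round result. Exactly one pass.
    """
    if not first_round:
        return [], []
    cps = [r.k_hat_global for r in first_round]
    if directions is None:
        directions = [Direction.TO_SLEEP] * len(first_round)
    bounds = [0]
    bounds += [(a + b) // 2 for a, b in zip(cps, cps[1:])]
    bounds.append(series.n)
    refined: list[CpResult] = []
    windows: list[SearchWindow] = []
    for res, direction, lo, hi in zip(first_round, directions, bounds, bounds[1:]):
        anchor = min(max(res.k_hat_global, lo + 1), hi - 1)
        win = SearchWindow(lo=lo, hi=hi, direction=direction, anchor=anchor)
        windows.append(win)
        try:
            new = _detect_in_window(series.values, win, config)
        except WindowTooShortError:
            logger.warning(
                "refinement window [%d,%d) too short; keeping first-round CP %d",
                lo, hi, res.k_hat_global,
            )
            refined.append(res)
            continue
        if lo < new.k_hat_global < hi:
            refined.append(new)
        else:  # cannot happen by construction; kept as a guard
            refined.append(res)
    return refined, windows


def sleep_labels_from_events(events, series: ActigraphySeries) -> np.ndarray:
    """Per-epoch sleep indicator implied by an alternating event sequence.

    Epochs from an SOT (inclusive) to the next WOT (exclusive) are sleep;
    the stretch before the first event takes the complementary state of
    that event's kind (a leading WOT implies the subject was asleep).
    """
    labels = np.zeros(series.n, dtype=bool)
    if not events:
        return labels
    step_s = series.epoch_s
    idxs = [
        int(round((e.time - series.start_time).total_seconds() / step_s))
        for e in events
    ]
    first_kind = events[0].kind
    state = first_kind is EventKind.WOT  # asleep before a leading wake onset
    prev = 0
    for idx, ev in zip(idxs, events):
        labels[prev:idx] = state
        state = ev.kind is EventKind.SOT
        prev = idx
    labels[prev:] = state
    return labels


def detect_subject(series: ActigraphySeries, config: RunConfig | None = None) -> DetectionResult:
    """Run the full detection pipeline on a screened 60 s epoch series."""
    config = config or RunConfig()
    if config.enforce_screening:
        sr = preprocess.screen(
            series,
            min_total_min=config.min_total_min,
            min_period_min=config.min_period_min,
            max_zero_run_min=config.max_zero_run_min,
        )
        if not sr.passed:
            raise ContractError(
                f"subject {series.subject_id} fails screening ({sr.reason}); "
                "screen and crop to the longest wear period first"
            )

    fit = cosinor.fit_cosinor(
        series,
        T=config.period_min,
        init=config.cosinor_init,
        solver=config.cosinor_solver,
    )
    try:
        rough = cosinor.dichotomize(fit, lower_fraction=config.lower_fraction)
    except DegenerateRhythmError as exc:
        raise NoRhythmError(str(exc)) from exc

    windows = build_windows(rough, series.n, min_window=config.cp_min_window)
    if not windows:
        raise NoEventsError(
            f"subject {series.subject_id}: all search windows dropped"
        )

    first_round = [_detect_in_window(series.values, w, config) for w in windows]
    directions = [w.direction for w in windows]
    if config.refine:
        results, windows_out = refine(first_round, series, config, directions)
    else:
        results, windows_out = first_round, list(windows)

    events = []
    for res, direction in zip(results, directions):
        kind = EventKind.SOT if direction is Direction.TO_SLEEP else EventKind.WOT
        t = series.time_at(res.k_hat_global)  # first epoch of the new regime
        events.append(
            SwotEvent(
                subject_id=series.subject_id,
                kind=kind,
                time=t,
                minutes_since_midnight=validation.to_minutes(
                    t, kind, config.sot_rollover_cut_min
                ),
                source=EventSource.CIRCACP,
            )
        )

    circacp_labels = sleep_labels_from_events(events, series)
    report = qc.evaluate(
        series.values,
        rough.nocturnal,
        circacp_labels,
        threshold=config.ch_delta_threshold,
    )
    return DetectionResult(
        subject_id=series.subject_id,
        events=tuple(events),
        rough=rough,
        fit=fit,
        windows=tuple(windows_out),
        cp_results=tuple(results),
        qc=report,
    )
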