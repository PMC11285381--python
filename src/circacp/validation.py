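"""Agreement between detected sleep/wake onsets and self-reported markers.

Button-press markers are noisy ground truth: presses may be missing,
duplicated, or far from any true transition. Sequence alignment is
deliberately not used — correct markers always lie close to true onsets,
so each estimated event is matched to markers within a proximity window
(default 180 min, inclusive). When several markers qualify, a sleep onset
keeps the LATEST and a wake onset the EARLIEST (people press the button
before settling and after getting up); each marker pairs with at most one
event, assigned greedily in chronological order.

Times are converted to minutes since the event day's midnight; sleep
onsets that occur after midnight but before the changeover (noon) get
+1440 min so a night's SOTs stay on a continuous scale. Agreement is
summarized per event kind with Bland–Altman statistics (bias and
1.96-SD limits of agreement) and the median absolute difference.

``match_markers`` returns the matched pairs only; ``summarize`` takes the
original event list as well so the match-rate denominators (total events
per kind) are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta

import numpy as np

from .io import EventKind, MarkerList, SwotEvent


@dataclass(frozen=True)
class MatchedPair:
    kind: EventKind
    est_min: float
    marker_min: float
    diff: float  # est_min - marker_min, minutes
    day: date


@dataclass(frozen=True)
class AgreementSummary:
    kind: EventKind
    n_pairs: int
    bias: float
    loa_low: float
    loa_high: float
    mae: float
    match_rate: float


def to_minutes(event_time: datetime, kind: EventKind, sot_rollover_cut_min: float = 720.0) -> float:
    """Minutes since midnight, with the after-midnight SOT rollover.

    Sub-minute precision is truncated. An SOT between midnight and the
    changeover (default noon) belongs to the previous night and gets
    +1440 min, e.g. an SOT at 00:30 maps to 1470.
    """
    m = float(event_time.hour * 60 + event_time.minute)
    if EventKind(kind) is EventKind.SOT and m < sot_rollover_cut_min:
        m += 1440.0
    return m


def _truncate_to_minute(t: datetime) -> datetime:
    return t.replace(second=0, microsecond=0)


def match_markers(
    events: list[SwotEvent],
    markers: MarkerList,
    window_min: float = 180.0,
    sot_rollover_cut_min: float = 720.0,
) -> list[MatchedPair]:
    """Pair each estimated event with its most plausible marker.

    ``diff`` is the signed clock difference (event minus marker) in whole
    minutes; ``marker_min = est_min - diff`` so the pair sits on the same
    continuous minutes-since-midnight scale as the event. Events with no
    marker within the window stay unmatched.
    """
    used = [False] * len(markers.times)
    marker_times = [_truncate_to_minute(t) for t in markers.times]
    pairs: list[MatchedPair] = []
    for ev in sorted(events, key=lambda e: e.time):
        et = _truncate_to_minute(ev.time)
        cands = [
            i
            for i, mt in enumerate(marker_times)
            if not used[i]
            and abs((et - mt).total_seconds()) / 60.0 <= window_min
        ]
        if not cands:
            continue
        if ev.kind is EventKind.SOT:
            pick = max(cands, key=lambda i: marker_times[i])
        else:
            pick = min(cands, key=lambda i: marker_times[i])
        used[pick] = True
        diff = (et - marker_times[pick]).total_seconds() / 60.0
        est_min = to_minutes(et, ev.kind, sot_rollover_cut_min)
        day = et.date()
        if ev.kind is EventKind.SOT and est_min >= 1440.0:
            day = day - timedelta(days=1)  # the night belongs to the prior day
        pairs.append(
            MatchedPair(
                kind=ev.kind,
                est_min=est_min,
                marker_min=est_min - diff,
                diff=diff,
                day=day,
            )
        )
    return pairs


def summarize(
    pairs: list[MatchedPair],
    events: list[SwotEvent] | None = None,
) -> dict[EventKind, AgreementSummary]:
    """Bland–Altman bias, limits of agreement and median absolute error.

    Computed separately per event kind. ``events`` supplies the match-rate
    denominator (total estimated events of that kind); without it the rate
    is NaN. Empty kinds yield an explicit n=0 summary.
    """
    out: dict[EventKind, AgreementSummary] = {}
    for kind in EventKind:
        diffs = np.array([p.diff for p in pairs if p.kind is kind], dtype=float)
        n_events = (
            sum(1 for e in events if e.kind is kind) if events is not None else None
        )
        if diffs.size == 0:
            rate = 0.0 if n_events else float("nan")
            out[kind] = AgreementSummary(
                kind, 0, float("nan"), float("nan"), float("nan"), float("nan"), rate
            )
            continue
        bias = float(diffs.mean())
        sd = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
        rate = float("nan") if n_events is None else diffs.size / n_events
        out[kind] = AgreementSummary(
            kind=kind,
            n_pairs=int(diffs.size),
            bias=bias,
            loa_low=bias - 1.96 * sd,
            loa_high=bias + 1.96 * sd,
            mae=float(np.median(np.abs(diffs))),
            match_rate=rate,
        )
    return out
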