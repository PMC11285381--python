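"""Synthetic actigraphy with known sleep/wake ground truth.

The generator emulates the distributional structure the detector assumes:
a pseudo-cyclostationary sequence whose epochs are zero-inflated Gamma
draws with a common shape and a scale that switches between a diurnal
(wake) and a nocturnal (sleep) regime, with zero inflation much heavier
during sleep. The schedule has ~24 h periodicity with independent
Gaussian day-to-day jitter on every onset. An optional "wind-down" regime
— a sedentary stretch at an intermediate scale just before true sleep
onset — reproduces the real-world effect that activity fades before sleep
begins, which makes sleep onsets systematically harder to pin down than
wake onsets.

Schedule encoding: ``mean_wot`` and ``mean_sot`` are minutes since
midnight, with ``mean_sot`` on the extended 0–2880 scale (values >= 1440
mean "after the following midnight"), matching the rollover convention
used for reporting sleep onsets. This lets shifted schedules (night
shift, irregular) be plain parameter presets. Each simulated day
contributes one sleep onset and the corresponding wake onset; the
recording starts at noon and ends a fixed tail after the last wake onset,
so every true event is flanked by data.

Event markers are the true onsets plus Gaussian noise (``marker_sd``),
each dropped independently with probability ``marker_dropout`` — subjects
forget to press the button.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import validation
from .errors import ContractError
from .io import ActigraphySeries, EventKind, EventSource, MarkerList, SwotEvent

#: preset schedules: (mean_sot, mean_wot, day_jitter_sd)
PROFILES = {
    "day": (1380.0, 420.0, 20.0),        # sleep 23:00 -> 07:00
    "night_shift": (1920.0, 930.0, 20.0),  # sleep 08:00 -> 15:30
    "irregular": (1380.0, 420.0, 60.0),
}


@dataclass(frozen=True)
class SubjectParams:
    subject_id: str = "S000"
    mean_sot: float = 1380.0   # minutes since midnight, extended scale
    mean_wot: float = 420.0
    day_jitter_sd: float = 20.0
    theta_wake: float = 200.0
    theta_sleep: float = 10.0
    theta_winddown: float = 45.0
    xi: float = 0.8
    p0_wake: float = 0.1
    p0_sleep: float = 0.6
    p0_winddown: float = 0.3
    winddown_min: float = 30.0
    marker_sd: float = 10.0
    marker_dropout: float = 0.2
    n_days: int = 7
    epoch_s: int = 60
    seed: int = 0
    start_date: datetime = field(
        default_factory=lambda: datetime(2024, 1, 1, 12, 0)
    )
    tail_min: float = 300.0

    def __post_init__(self):
        if not (self.theta_wake > self.theta_sleep > 0):
            raise ContractError("need theta_wake > theta_sleep > 0")
        if not (0 <= self.p0_wake <= 1 and 0 <= self.p0_sleep <= 1):
            raise ContractError("zero-inflation probabilities must lie in [0,1]")
        if self.p0_sleep < self.p0_wake:
            raise ContractError("p0_sleep must be >= p0_wake")
        if not (self.mean_wot < self.mean_sot):
            raise ContractError("mean_wot must precede mean_sot (monophasic night sleep)")
        sleep_len = self.mean_wot + 1440.0 - self.mean_sot
        wake_len = self.mean_sot - self.mean_wot
        if sleep_len <= 0 or wake_len <= 0:
            raise ContractError("infeasible schedule: empty sleep or wake span")
        if self.mean_sot - 720.0 <= 2 * self.day_jitter_sd + self.winddown_min:
            raise ContractError(
                "mean_sot too close to the noon recording start"
            )
        if self.n_days < 1:
            raise ContractError("n_days must be >= 1")
        if self.start_date.hour != 12 or self.start_date.minute != 0:
            raise ContractError("recording must start at noon")


@dataclass(frozen=True)
class SimTruth:
    true_events: tuple
    markers: MarkerList
    params: SubjectParams


def _schedule(params: SubjectParams, rng) -> list[tuple[EventKind, float]]:
    """Absolute event minutes from the noon recording start, alternating."""
    events = []
    for d in range(params.n_days):
        sot = d * 1440.0 + (params.mean_sot - 720.0) + rng.normal(0, params.day_jitter_sd)
        wot = d * 1440.0 + (params.mean_wot + 720.0) + rng.normal(0, params.day_jitter_sd)
        events.append((EventKind.SOT, sot))
        events.append((EventKind.WOT, wot))
    times = [t for _, t in events]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ContractError(
            "day-to-day jitter produced a non-monotone schedule; "
            "reduce day_jitter_sd"
        )
    return events


def simulate_subject(params: SubjectParams) -> tuple[ActigraphySeries, SimTruth]:
    """Draw one subject's recording, ground-truth onsets and markers.

    Fully reproducible from ``params.seed``. The regime of each 1-minute
    slot follows the jittered schedule exactly; counts are zero with the
    regime's inflation probability, otherwise Gamma(theta_regime, xi).
    """
    rng = np.random.default_rng(params.seed)
    sched = _schedule(params, rng)
    last_wot = sched[-1][1]
    # span at least the nominal n_days (noon to noon) so four simulated days
    # always satisfy the 5760-min screening rule
    total_min = max(int(np.ceil(last_wot + params.tail_min)), params.n_days * 1440)

    # per-minute regime: 0=wake, 1=winddown, 2=sleep
    regime = np.zeros(total_min, dtype=np.int8)
    minute_edges = np.arange(total_min, dtype=float)
    for (k1, sot), (_k2, wot) in zip(sched[::2], sched[1::2]):
        sleep_mask = (minute_edges >= sot) & (minute_edges < wot)
        regime[sleep_mask] = 2
        wd_mask = (minute_edges >= sot - params.winddown_min) & (minute_edges < sot)
        regime[wd_mask & (regime == 0)] = 1

    if params.epoch_s == 60:
        reg_epoch = regime
    elif params.epoch_s == 30:
        reg_epoch = np.repeat(regime, 2)
    else:
        raise ContractError("epoch_s must be 30 or 60")

    n = reg_epoch.size
    values = np.empty(n, dtype=float)
    for code, theta, p0 in (
        (0, params.theta_wake, params.p0_wake),
        (1, params.theta_winddown, params.p0_winddown),
        (2, params.theta_sleep, params.p0_sleep),
    ):
        mask = reg_epoch == code
        m = int(mask.sum())
        if m == 0:
            continue
        draws = rng.gamma(shape=params.xi, scale=theta, size=m)
        zeros = rng.random(m) < p0
        draws[zeros] = 0.0
        values[mask] = draws

    series = ActigraphySeries(
        subject_id=params.subject_id,
        start_time=params.start_date,
        epoch_s=params.epoch_s,
        values=values,
    )

    true_events = []
    for kind, t_min in sched:
        t = params.start_date + timedelta(minutes=float(t_min))
        t = t.replace(second=0, microsecond=0)
        true_events.append(
            SwotEvent(
                subject_id=params.subject_id,
                kind=kind,
                time=t,
                minutes_since_midnight=validation.to_minutes(t, kind),
                source=EventSource.TRUTH,
            )
        )

    marker_times = []
    for ev in true_events:
        if rng.random() < params.marker_dropout:
            continue
        offset = rng.normal(0.0, params.marker_sd)
        marker_times.append(ev.time + timedelta(minutes=float(offset)))
    markers = MarkerList(
        subject_id=params.subject_id, times=tuple(sorted(marker_times))
    )

    truth = SimTruth(true_events=tuple(true_events), markers=markers, params=params)
    return series, truth


def simulate_cohort(
    n_subjects: int = 20,
    base_params: SubjectParams | None = None,
    seed: int = 0,
    profile: str = "day",
    between_subject_sd: float = 30.0,
    out_dir=None,
) -> list[tuple[ActigraphySeries, SimTruth]]:
    """A cohort of independent subjects with mild between-subject variation.

    Per-subject seeds derive deterministically from the cohort seed; mean
    onsets vary across subjects by Normal(0, ``between_subject_sd``) min.
    When ``out_dir`` is given, writes ``actigraphy.csv``, ``markers.csv``
    and ``truth.csv`` in the package's on-disk dialects.
    """
    if profile not in PROFILES:
        raise ContractError(f"unknown profile {profile!r}")
    mean_sot, mean_wot, jitter = PROFILES[profile]
    base = base_params or SubjectParams(
        mean_sot=mean_sot, mean_wot=mean_wot, day_jitter_sd=jitter
    )
    ss = np.random.SeedSequence(seed)
    cohort_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_subjects)]

    cohort = []
    for i in range(n_subjects):
        shift_sot = float(cohort_rng.normal(0, between_subject_sd))
        shift_wot = float(cohort_rng.normal(0, between_subject_sd))
        p = replace(
            base,
            subject_id=f"S{i:03d}",
            mean_sot=base.mean_sot + shift_sot,
            mean_wot=base.mean_wot + shift_wot,
            seed=child_seeds[i],
        )
        cohort.append(simulate_subject(p))

    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    act_rows, marker_rows, truth_rows = [], [], []
    for series, truth in cohort:
        for i, v in enumerate(series.values):
            act_rows.append(
                (series.subject_id, series.time_at(i).isoformat(), v)
            )
        for t in truth.markers.times:
            marker_rows.append((series.subject_id, t.isoformat()))
        for d, ev in enumerate(truth.true_events):
            truth_rows.append(
                (
                    ev.subject_id,
                    d // 2,
                    ev.kind.value,
                    ev.minutes_since_midnight,
                    ev.time.isoformat(),
                )
            )
    pd.DataFrame(
        act_rows, columns=["subject_id", "timestamp", "activity"]
    ).to_csv(out_dir / "actigraphy.csv", index=False)
    pd.DataFrame(marker_rows, columns=["subject_id", "timestamp"]).to_csv(
        out_dir / "markers.csv", index=False
    )
    pd.DataFrame(
        truth_rows,
        columns=["subject_id", "day", "kind", "true_minutes", "timestamp"],
    ).to_csv(out_dir / "truth.csv", index=False)
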