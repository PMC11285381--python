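"""Reading and writing actigraphy, event-marker and result files.

On-disk dialects (all UTF-8, comma-delimited, header row mandatory):

* actigraphy CSV: ``subject_id,timestamp,activity`` — one row per epoch,
  ISO 8601 timestamps, non-negative activity counts;
* marker CSV: ``subject_id,timestamp`` — one row per button press;
* results CSV: ``subject_id,kind,timestamp,minutes_since_midnight,source``.

Timestamps are timezone-naive local clock time: sleep/wake onset times are
defined against the local midnight and the data carry no timezone. Epoch
index is 0-based; epoch ``i`` covers ``[start + i*epoch_s, start + (i+1)*epoch_s)``.
Missing epochs are never imputed silently — a gap raises :class:`~circacp.errors.GapError`
and the caller must fill explicitly (screening treats zeros as non-wear).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .errors import ContractError, GapError, ParseError


class EventKind(str, enum.Enum):
    SOT = "SOT"  # sleep onset
    WOT = "WOT"  # wake onset


class EventSource(str, enum.Enum):
    CIRCACP = "circacp"
    COSINOR_ROUGH = "cosinor_rough"
    MARKER = "marker"
    TRUTH = "truth"


@dataclass(frozen=True)
class ActigraphySeries:
    """One subject's uniformly sampled activity counts.

    ``values[i]`` is the activity count of the epoch starting at
    ``start_time + i * epoch_s`` seconds.
    """

    subject_id: str
    start_time: datetime
    epoch_s: int
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.epoch_s not in (30, 60):
            raise ContractError(f"epoch_s must be 30 or 60, got {self.epoch_s}")
        if vals.ndim != 1 or vals.size < 1:
            raise ContractError("values must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ContractError("activity counts must be finite and >= 0")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def duration_min(self) -> float:
        return self.n * self.epoch_s / 60.0

    def time_at(self, idx: int) -> datetime:
        """Start time of epoch ``idx``."""
        return self.start_time + timedelta(seconds=int(idx) * self.epoch_s)


@dataclass(frozen=True)
class MarkerList:
    """Ordered button-press timestamps for one subject; may be empty."""

    subject_id: str
    times: tuple = field(default_factory=tuple)

    def __post_init__(self):
        times = tuple(self.times)
        object.__setattr__(self, "times", times)
        if any(b < a for a, b in zip(times, times[1:])):
            raise ContractError("marker times must be non-decreasing")

    def __len__(self):
        return len(self.times)


@dataclass(frozen=True)
class SwotEvent:
    """A detected or reported sleep-/wake-onset time."""

    subject_id: str
    kind: EventKind
    time: datetime
    minutes_since_midnight: float
    source: EventSource

    def __post_init__(self):
        object.__setattr__(self, "kind", EventKind(self.kind))
        object.__setattr__(self, "source", EventSource(self.source))
        m = self.minutes_since_midnight
        if not (0 <= m < 2880):
            raise ContractError(
                f"minutes_since_midnight must lie in [0, 2880), got {m}"
            )


def _parse_timestamps(raw: pd.Series, path) -> pd.Series:
    ts = pd.to_datetime(raw, format="ISO8601", errors="coerce")
    bad = ts.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: malformed timestamp {raw.iloc[row]!r} at data row {row}"
        )
    return ts


def read_actigraphy(path, epoch_s: int = 60) -> dict[str, ActigraphySeries]:
    """Read an actigraphy CSV into one :class:`ActigraphySeries` per subject.

    Rows may arrive in any order; they are sorted by timestamp per subject.
    Duplicate timestamps are rejected and gaps in the epoch grid raise
    :class:`GapError` naming the missing intervals.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    for col in ("subject_id", "timestamp", "activity"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    df["timestamp"] = _parse_timestamps(df["timestamp"], path)
    if (df["activity"] < 0).any():
        row = int(df.index[df["activity"] < 0][0])
        raise ContractError(f"{path}: negative activity at data row {row}")

    out: dict[str, ActigraphySeries] = {}
    step = timedelta(seconds=epoch_s)
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("timestamp")
        ts = grp["timestamp"]
        if ts.duplicated().any():
            dup = ts[ts.duplicated()].iloc[0]
            raise ContractError(f"{path}: duplicate timestamp {dup} for subject {sid}")
        deltas = ts.diff().dropna()
        holes = deltas[deltas != step]
        if len(holes):
            intervals = [
                (ts.iloc[i - 1] + step, ts.iloc[i])
                for i in np.flatnonzero((deltas != step).to_numpy()) + 1
            ]
            raise GapError(
                f"{path}: subject {sid} has {len(intervals)} gap(s) in the "
                f"epoch grid, first missing interval "
                f"[{intervals[0][0]}, {intervals[0][1]})",
                intervals=intervals,
            )
        out[str(sid)] = ActigraphySeries(
            subject_id=str(sid),
            start_time=ts.iloc[0].to_pydatetime(),
            epoch_s=epoch_s,
            values=grp["activity"].to_numpy(dtype=float),
        )
    return out


def read_markers(path) -> dict[str, MarkerList]:
    """Read a marker CSV into one :class:`MarkerList` per subject.

    An empty file (header only) yields an empty dict; a subject with no
    presses simply has no rows.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    for col in ("subject_id", "timestamp"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if df.empty:
        return {}
    df["timestamp"] = _parse_timestamps(df["timestamp"], path)
    out = {}
    for sid, grp in df.groupby("subject_id", sort=True):
        times = tuple(t.to_pydatetime() for t in grp["timestamp"].sort_values())
        out[str(sid)] = MarkerList(subject_id=str(sid), times=times)
    return out


def write_swots(events: list[SwotEvent], path) -> None:
    """Write detected/reported events; round-trips through :func:`read_swots`."""
    df = pd.DataFrame(
        {
            "subject_id": [e.subject_id for e in events],
            "kind": [e.kind.value for e in events],
            "timestamp": [e.time.isoformat() for e in events],
            "minutes_since_midnight": [e.minutes_since_midnight for e in events],
            "source": [e.source.value for e in events],
        }
    )
    df.to_csv(path, index=False)


def read_swots(path) -> list[SwotEvent]:
    df = pd.read_csv(path, dtype={"subject_id": str})
    df["timestamp"] = _parse_timestamps(df["timestamp"], path)
    return [
        SwotEvent(
            subject_id=str(r.subject_id),
            kind=EventKind(r.kind),
            time=r.timestamp.to_pydatetime(),
            minutes_since_midnight=float(r.minutes_since_midnight),
            source=EventSource(r.source),
        )
        for r in df.itertuples()
    ]
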