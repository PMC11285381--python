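from datetime import datetime, timedelta

import numpy as np
import pytest

from circacp import validation
from circacp.io import EventKind, EventSource, MarkerList, SwotEvent
from circacp.validation import match_markers, summarize, to_minutes


def _event(kind, when, sid="A"):
    return SwotEvent(
        subject_id=sid,
        kind=kind,
        time=when,
        minutes_since_midnight=to_minutes(when, kind),
        source=EventSource.CIRCACP,
    )


class TestToMinutes:
    def test_sot_after_midnight_rolls_over(self):
        assert to_minutes(datetime(2024, 1, 2, 0, 30), EventKind.SOT) == 1470

    def test_sot_before_midnight_unchanged(self):
        assert to_minutes(datetime(2024, 1, 1, 23, 45), EventKind.SOT) == 1425

    def test_wot_morning_plain(self):
        assert to_minutes(datetime(2024, 1, 2, 6, 45), EventKind.WOT) == 405

    def test_wot_never_rolls_over(self):
        assert to_minutes(datetime(2024, 1, 2, 0, 30), EventKind.WOT) == 30

    def test_seconds_truncated(self):
        assert to_minutes(datetime(2024, 1, 1, 23, 45, 59), EventKind.WOT) == 1425


class TestMatchMarkers:
    def test_sot_keeps_latest_candidate(self):
        est = _event(EventKind.SOT, datetime(2024, 1, 1, 23, 0))
        markers = MarkerList("A", (datetime(2024, 1, 1, 22, 0), datetime(2024, 1, 1, 22, 30)))
        pairs = match_markers([est], markers)
        assert len(pairs) == 1
        assert pairs[0].diff == 30.0  # matched 22:30, not 22:00

    def test_wot_keeps_earliest_candidate(self):
        est = _event(EventKind.WOT, datetime(2024, 1, 2, 6, 30))
        markers = MarkerList("A", (datetime(2024, 1, 2, 6, 40), datetime(2024, 1, 2, 7, 30)))
        pairs = match_markers([est], markers)
        assert len(pairs) == 1
        assert pairs[0].diff == -10.0  # matched 06:40

    def test_marker_at_181_minutes_not_matched(self):
        est = _event(EventKind.WOT, datetime(2024, 1, 2, 7, 0))
        markers = MarkerList("A", (datetime(2024, 1, 2, 10, 1),))
        assert match_markers([est], markers) == []

    def test_marker_at_exactly_180_minutes_matched(self):
        est = _event(EventKind.WOT, datetime(2024, 1, 2, 7, 0))
        markers = MarkerList("A", (datetime(2024, 1, 2, 10, 0),))
        assert len(match_markers([est], markers)) == 1

    def test_empty_markers_give_zero_pairs(self):
        est = _event(EventKind.SOT, datetime(2024, 1, 1, 23, 0))
        assert match_markers([est], MarkerList("A")) == []

    def test_marker_used_at_most_once(self):
        # one marker between two WOT estimates pairs with the first only
        e1 = _event(EventKind.WOT, datetime(2024, 1, 2, 6, 0))
        e2 = _event(EventKind.WOT, datetime(2024, 1, 2, 8, 0))
        markers = MarkerList("A", (datetime(2024, 1, 2, 7, 0),))
        pairs = match_markers([e1, e2], markers)
        assert len(pairs) == 1
        assert pairs[0].diff == -60.0

    def test_rollover_keeps_diff_continuous_across_midnight(self):
        est = _event(EventKind.SOT, datetime(2024, 1, 2, 0, 10))
        markers = MarkerList("A", (datetime(2024, 1, 1, 23, 50),))
        (pair,) = match_markers([est], markers)
        assert pair.est_min == 1450
        assert pair.diff == 20.0
        assert pair.marker_min == 1430
        assert pair.day == datetime(2024, 1, 1).date()  # the prior night

    def test_role_swap_flips_selection(self):
        # same geometry, roles swapped: SOT->latest vs WOT->earliest
        when = datetime(2024, 1, 1, 23, 0)
        markers = MarkerList("A", (when - timedelta(minutes=60), when + timedelta(minutes=60)))
        (p_sot,) = match_markers([_event(EventKind.SOT, when)], markers)
        (p_wot,) = match_markers([_event(EventKind.WOT, when)], markers)
        assert p_sot.diff == -60.0
        assert p_wot.diff == 60.0


class TestSummarize:
    def test_symmetric_diffs(self):
        base = datetime(2024, 1, 2, 7, 0)
        events = [_event(EventKind.WOT, base + timedelta(days=i)) for i in range(3)]
        markers = MarkerList(
            "A",
            tuple(
                base + timedelta(days=i, minutes=m)
                for i, m in enumerate((2, 0, -2))
            ),
        )
        pairs = match_markers(events, markers)
        s = summarize(pairs, events)[EventKind.WOT]
        assert s.bias == pytest.approx(0.0)
        assert s.mae == pytest.approx(2.0)
        assert s.match_rate == 1.0

    def test_constant_offset_collapses_loa(self):
        base = datetime(2024, 1, 2, 7, 0)
        events = [_event(EventKind.WOT, base + timedelta(days=i)) for i in range(4)]
        markers = MarkerList(
            "A", tuple(base + timedelta(days=i, minutes=-5) for i in range(4))
        )
        s = summarize(match_markers(events, markers), events)[EventKind.WOT]
        assert s.bias == s.loa_low == s.loa_high == pytest.approx(5.0)
        assert s.mae == pytest.approx(5.0)

    def test_empty_summary_explicit_n_zero(self):
        s = summarize([], [])
        assert s[EventKind.SOT].n_pairs == 0
        assert np.isnan(s[EventKind.SOT].bias)

    def test_matched_plus_unmatched_is_total(self):
        base = datetime(2024, 1, 2, 7, 0)
        events = [_event(EventKind.WOT, base + timedelta(days=i)) for i in range(5)]
        markers = MarkerList(
            "A", tuple(base + timedelta(days=i) for i in range(3))
        )
        pairs = match_markers(events, markers)
        s = summarize(pairs, events)[EventKind.WOT]
        assert s.n_pairs + (5 - s.n_pairs) == 5
        assert s.match_rate == pytest.approx(3 / 5)

    def test_known_gaussian_noise_gives_expected_loa(self):
        # markers = truth + N(0, 10 min): bias ~ 0, LoA ~ +-19.6 min
        rng = np.random.default_rng(77)
        base = datetime(2024, 1, 1, 7, 0)
        events, mtimes = [], []
        for i in range(400):
            t = base + timedelta(days=i)
            events.append(_event(EventKind.WOT, t))
            mtimes.append(t + timedelta(minutes=float(rng.normal(0, 10))))
        pairs = match_markers(events, MarkerList("A", tuple(sorted(mtimes))))
        s = summarize(pairs, events)[EventKind.WOT]
        assert abs(s.bias) < 1.5
        assert s.loa_high - s.bias == pytest.approx(19.6, abs=2.5)
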