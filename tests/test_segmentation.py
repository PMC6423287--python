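"""Bout/gap/recess segmentation against the definitions and the per-second oracle."""

import datetime as dt

import numpy as np
import pytest

from lapwing import segmentation as seg
from lapwing.io import (
    ARRIVAL,
    DEPARTURE,
    FEMALE,
    MALE,
    EventRecord,
    MonitoringWindow,
)
from lapwing.segmentation import (
    STATE_FEMALE,
    STATE_MALE,
    STATE_NOBODY,
    apply_quality_exclusions,
    per_second_state,
    segment_nest,
    segment_window,
)

from conftest import TZ, random_stream

D = dt.datetime(2015, 4, 20, tzinfo=TZ)


def ev(hhmm, actor, transition, **kw):
    h, m = divmod(hhmm, 100)
    return EventRecord("A", D.replace(hour=h, minute=m), actor, transition, **kw)


def win(h0, h1):
    return MonitoringWindow("A", D.replace(hour=h0), D.replace(hour=h1))


def test_worked_example_with_recess_exchanges_and_truncation():
    """Open-start female bout with a recess, complete male bout, open-end bout."""
    events = [
        ev(1000, FEMALE, ARRIVAL),
        ev(1040, FEMALE, DEPARTURE),
        ev(1045, FEMALE, ARRIVAL),
        ev(1100, FEMALE, DEPARTURE),
        ev(1102, MALE, ARRIVAL),
        ev(1130, MALE, DEPARTURE),
        ev(1133, FEMALE, ARRIVAL),
    ]
    out = segment_window(events, win(10, 12))
    assert [b.sex for b in out.bouts] == [FEMALE, MALE, FEMALE]
    f1, m1, f2 = out.bouts
    assert f1.seconds == 3600 and len(f1.recesses) == 1
    assert f1.recesses[0].seconds == 300
    assert f1.attended_seconds == 3300
    assert not f1.complete  # starts at the window edge, no observed exchange
    assert m1.seconds == 28 * 60 and m1.complete
    assert f2.seconds == 27 * 60 and not f2.complete and f2.open_end
    assert [(g.seconds, g.precedes_sex, g.complete) for g in out.gaps] == [
        (120, MALE, True),
        (180, FEMALE, True),
    ]
    # conservation to the second
    total = sum(b.seconds for b in out.bouts) + sum(g.seconds for g in out.gaps)
    assert total == 2 * 3600


def test_no_events_with_open_start_hint_gives_one_spanning_bout():
    out = segment_window([], win(10, 12), initial_on=FEMALE)
    assert len(out.bouts) == 1 and not out.gaps
    b = out.bouts[0]
    assert b.sex == FEMALE and b.seconds == 7200
    assert b.open_start and b.open_end and not b.complete


def test_no_events_closed_start_is_one_incomplete_gap():
    out = segment_window([], win(10, 12))
    assert not out.bouts
    assert len(out.gaps) == 1 and not out.gaps[0].complete
    state = per_second_state([], win(10, 12))
    assert (state == STATE_NOBODY).all()


def test_zero_second_exchange_recorded_as_zero_gap():
    events = [
        ev(1000, FEMALE, ARRIVAL),
        ev(1100, FEMALE, DEPARTURE),
        ev(1100, MALE, ARRIVAL),
        ev(1140, MALE, DEPARTURE),
    ]
    out = segment_window(events, win(10, 12))
    gaps = [g for g in out.gaps if g.complete]
    assert len(gaps) == 1 and gaps[0].seconds == 0
    assert gaps[0].precedes_sex == MALE


def test_same_second_departure_and_return_merges_without_recess():
    events = [
        ev(1000, FEMALE, ARRIVAL),
        ev(1030, FEMALE, DEPARTURE),
        ev(1030, FEMALE, ARRIVAL),
        ev(1100, FEMALE, DEPARTURE),
    ]
    out = segment_window(events, win(10, 12))
    assert len(out.bouts) == 1
    assert out.bouts[0].seconds == 3600 and not out.bouts[0].recesses


def test_uniparental_stream_yields_edge_delimited_bouts():
    events = [
        ev(1000, FEMALE, ARRIVAL),
        ev(1030, FEMALE, DEPARTURE),
        ev(1050, FEMALE, ARRIVAL),
    ]
    out = segment_window(events, win(9, 12))
    assert len(out.bouts) == 1
    b = out.bouts[0]
    assert b.sex == FEMALE and len(b.recesses) == 1 and b.recesses[0].seconds == 1200
    assert not b.complete and b.open_end
    assert [g.complete for g in out.gaps] == [False]  # leading gap only


def test_event_outside_windows_raises():
    with pytest.raises(seg.SegmentationError, match="validate_events"):
        segment_nest([ev(1300, FEMALE, ARRIVAL)], [win(10, 12)])


def test_bouts_never_span_monitoring_breaks():
    events = [ev(1000, FEMALE, ARRIVAL), ev(1500, FEMALE, DEPARTURE)]
    out = segment_nest(events, [win(9, 11), win(14, 16)])
    assert len(out.bouts) == 2
    assert all(not b.complete for b in out.bouts)
    assert out.bouts[0].open_end and out.bouts[1].open_start


class TestQualityExclusions:
    def test_disturbed_bout_and_adjacent_gaps_excluded(self):
        events = [
            ev(1000, FEMALE, ARRIVAL),
            ev(1100, FEMALE, DEPARTURE),
            ev(1102, MALE, ARRIVAL, observer_disturbance=True),
            ev(1130, MALE, DEPARTURE),
            ev(1133, FEMALE, ARRIVAL),
            ev(1150, FEMALE, DEPARTURE),
        ]
        out = segment_window(events, win(10, 12))
        kept, excluded = apply_quality_exclusions(out)
        assert [b.sex for b in excluded.bouts] == [MALE]
        assert len(excluded.gaps) == 2  # both gaps adjacent to the male bout
        assert [b.sex for b in kept.bouts] == [FEMALE, FEMALE]

    def test_untainted_stream_excludes_nothing(self):
        rng = np.random.default_rng(3)
        evs, w = random_stream(rng)
        evs = [
            EventRecord(e.nest_id, e.timestamp, e.actor, e.transition)
            for e in evs
        ]
        kept, excluded = apply_quality_exclusions(segment_window(evs, w))
        assert not excluded.bouts and not excluded.gaps

    def test_excluded_time_plus_kept_time_is_window_length(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            evs, w = random_stream(rng)
            kept, excluded = apply_quality_exclusions(segment_window(evs, w))
            total = sum(b.seconds for b in kept.bouts + excluded.bouts) + sum(
                g.seconds for g in kept.gaps + excluded.gaps
            )
            assert total == w.seconds


def test_segmentation_equals_per_second_oracle_on_random_streams():
    """Totals per sex, recess and gap time all match the brute-force walk."""
    rng = np.random.default_rng(123)
    for _ in range(200):
        events, window = random_stream(rng)
        out = segment_window(events, window)
        state = per_second_state(events, window)
        att = {
            FEMALE: sum(b.attended_seconds for b in out.bouts if b.sex == FEMALE),
            MALE: sum(b.attended_seconds for b in out.bouts if b.sex == MALE),
        }
        assert att[FEMALE] == int((state == STATE_FEMALE).sum())
        assert att[MALE] == int((state == STATE_MALE).sum())
        off = sum(r.seconds for r in out.recesses) + sum(g.seconds for g in out.gaps)
        assert off == int((state == STATE_NOBODY).sum())
        total = sum(b.seconds for b in out.bouts) + sum(g.seconds for g in out.gaps)
        assert total == window.seconds


def test_bout_of_one_parent_is_off_nest_interval_of_the_other():
    """Complement relation: during a female bout the male is never on nest."""
    rng = np.random.default_rng(9)
    for _ in range(50):
        events, window = random_stream(rng)
        out = segment_window(events, window)
        state = per_second_state(events, window)
        t0 = window.start
        for b in out.bouts:
            i = int((b.start - t0).total_seconds())
            j = int((b.end - t0).total_seconds())
            other = STATE_MALE if b.sex == FEMALE else STATE_FEMALE
            assert not (state[i:j] == other).any()


def test_no_negative_or_zero_length_intervals():
    rng = np.random.default_rng(17)
    for _ in range(100):
        events, window = random_stream(rng)
        out = segment_window(events, window)
        assert all(b.seconds >= 1 for b in out.bouts)
        assert all(r.seconds >= 1 for r in out.recesses)
        assert all(g.seconds >= 0 for g in out.gaps)
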