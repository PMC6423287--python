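"""Attendance tables: clipping, inclusion filters, and conservation."""

import datetime as dt

import numpy as np
import pytest

from lapwing import aggregation, segmentation
from lapwing.aggregation import FilterThresholds
from lapwing.io import (
    ARRIVAL,
    DEPARTURE,
    FEMALE,
    MALE,
    EventRecord,
    MonitoringWindow,
    NestMetadata,
)

TZ = dt.timezone(dt.timedelta(hours=2))
DAY0 = dt.datetime(2015, 4, 20, 0, 0, tzinfo=TZ)
META = NestMetadata("A", 49.25, 14.08, 2.0, dt.date(2015, 4, 18), 108)


def ts(day, h, m=0, s=0):
    return DAY0 + dt.timedelta(days=day, hours=h, minutes=m, seconds=s)


def segd(events, windows):
    s = segmentation.segment_nest(events, windows)
    return segmentation.apply_quality_exclusions(s)


def test_attendance_over_partial_window():
    """55 attended minutes in a fully monitored hour -> 0.9167."""
    w = MonitoringWindow("A", ts(0, 10), ts(0, 11))
    events = [
        EventRecord("A", ts(0, 10), FEMALE, ARRIVAL),
        EventRecord("A", ts(0, 10, 30), FEMALE, DEPARTURE),
        EventRecord("A", ts(0, 10, 35), FEMALE, ARRIVAL),
    ]
    kept, excl = segd(events, [w])
    row = aggregation.attendance_over(kept, excl, [w], ts(0, 10), ts(0, 11))
    assert row["attended_seconds_female"] == 55 * 60
    assert row["attendance"] == pytest.approx(55 / 60)
    empty = aggregation.attendance_over(kept, excl, [w], ts(0, 12), ts(0, 13))
    assert not empty["included"] and empty["exclusion_reason"]


def test_bout_split_across_hour_boundaries():
    """A 10:30-12:15 bout contributes 30/60/15 minutes to hours 10/11/12."""
    w = MonitoringWindow("A", ts(0, 9), ts(0, 14))
    events = [
        EventRecord("A", ts(0, 10, 30), MALE, ARRIVAL),
        EventRecord("A", ts(0, 12, 15), MALE, DEPARTURE),
    ]
    kept, excl = segd(events, [w])
    h = aggregation.hourly_table(kept, excl, [w], TZ).set_index("hour")
    assert h.loc[10, "attended_seconds_male"] == 30 * 60
    assert h.loc[11, "attended_seconds_male"] == 60 * 60
    assert h.loc[12, "attended_seconds_male"] == 15 * 60


def test_incomplete_hour_and_min_hours_filters():
    # 25 h of monitoring with a 5-min break inside one hour
    windows = [
        MonitoringWindow("A", ts(0, 0), ts(0, 6, 30)),
        MonitoringWindow("A", ts(0, 6, 35), ts(1, 4)),
    ]
    kept, excl = segd([], windows)
    h = aggregation.hourly_table(kept, excl, windows, TZ)
    broken = h[(h["date"] == DAY0.date()) & (h["hour"] == 6)].iloc[0]
    assert not broken["included"] and broken["exclusion_reason"] == "incomplete hour"
    assert int(h["included"].sum()) >= 24  # the rest qualify

    # same layout but under 24 complete hours -> everything excluded
    short = [MonitoringWindow("A", ts(0, 0), ts(0, 23))]
    kept2, excl2 = segd([], short)
    h2 = aggregation.hourly_table(kept2, excl2, short, TZ)
    assert not h2["included"].any()
    assert (h2["exclusion_reason"] == "<24 h").any()


def test_daily_coverage_filter_at_90_percent():
    win_ok = [MonitoringWindow("A", ts(0, 0), ts(0, 23))]  # 95.8%
    win_bad = [MonitoringWindow("A", ts(0, 0), ts(0, 21))]  # 87.5%
    for wins, want in ((win_ok, True), (win_bad, False)):
        kept, excl = segd([], wins)
        d = aggregation.daily_table(kept, excl, wins, META)
        assert bool(d.iloc[0]["included"]) is want
    kept, excl = segd([], win_ok)
    d = aggregation.daily_table(kept, excl, win_ok, META)
    assert d.iloc[0]["day_of_incubation"] == 2
    assert d.iloc[0]["season_start_day"] == 108


def test_monitoring_before_incubation_start_clamps_day_to_zero():
    meta = NestMetadata("A", 49.25, 14.08, 2.0, dt.date(2015, 4, 25), 115)
    wins = [MonitoringWindow("A", ts(0, 0), ts(0, 23))]
    kept, excl = segd([], wins)
    with pytest.warns(UserWarning, match="clamped"):
        d = aggregation.daily_table(kept, excl, wins, meta)
    assert d.iloc[0]["day_of_incubation"] == 0


def test_decomposition_identity_holds_to_the_second(small_study):
    from lapwing import pipeline

    res = pipeline.analyze(small_study.events, small_study.windows, small_study.metadata)
    for df in (res.hourly, res.daily):
        lhs = (
            df["attended_seconds_female"]
            + df["attended_seconds_male"]
            + df["recess_seconds_female"]
            + df["recess_seconds_male"]
            + df["gap_seconds"]
            + df["unattributed_seconds"]
        )
        assert (lhs == df["monitored_seconds"]).all()
    # attendance decomposes by sex at every scale
    for df in (res.hourly, res.daily):
        assert np.allclose(
            df["attendance"], df["attendance_female"] + df["attendance_male"]
        )


def test_daily_totals_conserve_nest_totals(small_study):
    from lapwing import pipeline

    res = pipeline.analyze(small_study.events, small_study.windows, small_study.metadata)
    for nest_id, (kept, excl, windows) in res.segmentations.items():
        d = res.daily[res.daily["nest_id"] == nest_id]
        total_attended = sum(b.attended_seconds for b in kept.bouts)
        assert (
            d["attended_seconds_female"].sum() + d["attended_seconds_male"].sum()
            == total_attended
        )


def test_filters_are_pure(small_study):
    from lapwing import pipeline

    r1 = pipeline.analyze(small_study.events, small_study.windows, small_study.metadata)
    r2 = pipeline.analyze(small_study.events, small_study.windows, small_study.metadata)
    assert r1.daily["included"].tolist() == r2.daily["included"].tolist()
    assert r1.hourly["exclusion_reason"].tolist() == r2.hourly["exclusion_reason"].tolist()


class TestNestSummary:
    def test_uniparental_nest(self):
        windows = [MonitoringWindow("A", ts(0, 0), ts(2, 0))]
        events = [EventRecord("A", ts(0, 0, 0, 30), FEMALE, ARRIVAL)]
        kept, excl = segd(events, windows)
        s = aggregation.nest_summary(kept, excl, windows, META)
        assert s["uniparental"]
        assert s["male_attendance"] == 0.0
        assert s["female_responsibility"] == pytest.approx(1.0, abs=1e-3)
        assert s["included"]  # two full days

    def test_one_day_nest_excluded_from_nest_level(self):
        windows = [MonitoringWindow("A", ts(0, 0), ts(0, 23))]
        kept, excl = segd([], windows)
        s = aggregation.nest_summary(kept, excl, windows, META)
        assert not s["included"] and "included days" in s["exclusion_reason"]

    def test_median_bout_uses_complete_untainted_bouts(self):
        windows = [MonitoringWindow("A", ts(0, 10), ts(0, 20))]
        events = []
        # alternating F/M bouts: complete F bouts of 60 and 100 minutes
        plan = [
            (FEMALE, ts(0, 10, 30), ts(0, 11, 30)),
            (MALE, ts(0, 11, 32), ts(0, 12, 0)),
            (FEMALE, ts(0, 12, 2), ts(0, 13, 42)),
            (MALE, ts(0, 13, 44), ts(0, 14, 30)),
            (FEMALE, ts(0, 14, 32), ts(0, 15, 0)),  # open-ended context below
        ]
        for sex, a, b in plan:
            events.append(EventRecord("A", a, sex, ARRIVAL))
            events.append(EventRecord("A", b, sex, DEPARTURE))
        kept, excl = segd(events, windows)
        s = aggregation.nest_summary(kept, excl, windows, META)
        # only the 100-min female bout is complete (the first follows the
        # unobserved window start, the last precedes the trailing gap)
        assert s["median_bout_female_s"] == pytest.approx(100 * 60)
        assert s["median_bout_male_s"] == pytest.approx((28 + 46) / 2 * 60)


class TestLongestNightBouts:
    def _night(self):
        from lapwing import solar

        ctx = solar.SolarContext(META.latitude, META.longitude, META.utc_offset)
        return solar.night_for_evening(ctx, DAY0.date())

    def test_qualification_threshold_and_maximum(self):
        night = self._night()
        w = MonitoringWindow("A", ts(0, 12), ts(1, 12))
        mk = lambda a, b: [
            EventRecord("A", a, FEMALE, ARRIVAL),
            EventRecord("A", b, FEMALE, DEPARTURE),
        ]
        # 5-h bout fully in night qualifies; a mostly-daytime bout does not
        ev = (
            mk(night.start + dt.timedelta(minutes=5),
               night.start + dt.timedelta(hours=5))
            + [
                EventRecord("A", night.start + dt.timedelta(hours=5, minutes=2),
                            MALE, ARRIVAL),
                EventRecord("A", night.end + dt.timedelta(hours=2), MALE,
                            DEPARTURE),
            ]
        )
        kept, excl = segd(ev, [w])
        nb = aggregation.longest_night_bouts(kept, META, [DAY0.date()])
        assert len(nb) == 1
        assert nb.iloc[0]["longest_female_bout_s"] == 5 * 3600 - 300
        assert nb.iloc[0]["night_length_s"] == night.length

    def test_night_without_qualifying_bout_is_omitted(self):
        w = MonitoringWindow("A", ts(0, 8), ts(0, 20))  # daytime only
        ev = [
            EventRecord("A", ts(0, 9), FEMALE, ARRIVAL),
            EventRecord("A", ts(0, 12), FEMALE, DEPARTURE),
        ]
        kept, excl = segd(ev, [w])
        nb = aggregation.longest_night_bouts(kept, META, [DAY0.date()])
        assert nb.empty


def test_filter_threshold_validation():
    with pytest.raises(ValueError):
        FilterThresholds(day_coverage=1.01)
    with pytest.raises(ValueError):
        FilterThresholds(min_days=0)
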