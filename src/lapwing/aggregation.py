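"""Attendance, responsibility, and bout summaries at hour/day/nest scales.

Nest attendance is the proportion of monitored time a parent actually sits
on (or shades) the eggs — recesses excluded.  Responsibility is the
proportion of monitored time covered by a parent's whole bouts, recesses
included.  Inclusion filters follow the study design:

* hourly rows need a fully monitored clock hour (3600 s with no excluded
  time) and a nest with at least ``min_hours`` such hours;
* daily rows need more than ``day_coverage`` (default 90%) of the calendar
  day monitored;
* nest-level summaries need at least ``min_days`` (default 2) included days.

Every row satisfies the decomposition identity, to the second::

    attended_f + attended_m + recess_f + recess_m + gap + unattributed
        = monitored

where monitored excludes quality-excluded time and ``unattributed`` is
monitored time outside all kept bouts and gaps (edge effects of exclusion).
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import FEMALE, MALE, MonitoringWindow, NestMetadata
from .segmentation import Bout, ExchangeGap, Segmentation
from . import solar

__all__ = [
    "FilterThresholds",
    "attendance_over",
    "hourly_table",
    "daily_table",
    "nest_summary",
    "longest_night_bouts",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Inclusion thresholds; defaults are the study's printed values."""

    day_coverage: float = 0.9
    min_days: int = 2
    min_hours: int = 24
    night_fraction: float = 0.6

    def __post_init__(self) -> None:
        if not (0 < self.day_coverage <= 1):
            raise ValueError(f"day_coverage must be in (0, 1]: {self.day_coverage}")
        if not (0 <= self.night_fraction <= 1):
            raise ValueError(f"night_fraction out of range: {self.night_fraction}")
        if self.min_days < 1 or self.min_hours < 1:
            raise ValueError("min_days and min_hours must be positive")


DEFAULT_FILTERS = FilterThresholds()


def _epoch(t: dt.datetime) -> int:
    return int(t.timestamp())


class _IntervalSet:
    """Disjoint half-open intervals in epoch seconds, with fast clipping."""

    def __init__(self, pairs: Sequence[tuple[int, int]]):
        pairs = sorted((int(a), int(b)) for a, b in pairs if b > a)
        self.starts = np.array([p[0] for p in pairs], dtype=np.int64)
        self.ends = np.array([p[1] for p in pairs], dtype=np.int64)

    def overlap(self, start: int, end: int) -> int:
        if len(self.starts) == 0 or end <= start:
            return 0
        s = np.maximum(self.starts, start)
        e = np.minimum(self.ends, end)
        return int(np.maximum(e - s, 0).sum())

    @property
    def total(self) -> int:
        return int((self.ends - self.starts).sum())


@dataclass
class _Bundle:
    """Clippable interval sets derived from a (kept, excluded) segmentation."""

    on: dict
    recess: dict
    gap: _IntervalSet
    excluded: _IntervalSet
    windows: _IntervalSet

    @classmethod
    def build(
        cls,
        kept: Segmentation,
        excluded: Segmentation,
        windows: Sequence[MonitoringWindow],
    ) -> "_Bundle":
        on = {FEMALE: [], MALE: []}
        recess = {FEMALE: [], MALE: []}
        for b in kept.bouts:
            cursor = _epoch(b.start)
            for r in b.recesses:
                on[b.sex].append((cursor, _epoch(r.start)))
                recess[b.sex].append((_epoch(r.start), _epoch(r.end)))
                cursor = _epoch(r.end)
            on[b.sex].append((cursor, _epoch(b.end)))
        gap = [(_epoch(g.start), _epoch(g.end)) for g in kept.gaps]
        excl = [(_epoch(b.start), _epoch(b.end)) for b in excluded.bouts]
        excl += [(_epoch(g.start), _epoch(g.end)) for g in excluded.gaps]
        return cls(
            on={s: _IntervalSet(v) for s, v in on.items()},
            recess={s: _IntervalSet(v) for s, v in recess.items()},
            gap=_IntervalSet(gap),
            excluded=_IntervalSet(excl),
            windows=_IntervalSet([(_epoch(w.start), _epoch(w.end)) for w in windows]),
        )

    def row(self, start: int, end: int) -> dict:
        monitored_raw = self.windows.overlap(start, end)
        excluded = self.excluded.overlap(start, end)
        monitored = monitored_raw - excluded
        att_f = self.on[FEMALE].overlap(start, end)
        att_m = self.on[MALE].overlap(start, end)
        rec_f = self.recess[FEMALE].overlap(start, end)
        rec_m = self.recess[MALE].overlap(start, end)
        gap = self.gap.overlap(start, end)
        return {
            "monitored_seconds": monitored,
            "excluded_seconds": excluded,
            "attended_seconds_female": att_f,
            "attended_seconds_male": att_m,
            "recess_seconds_female": rec_f,
            "recess_seconds_male": rec_m,
            "gap_seconds": gap,
            "unattributed_seconds": monitored - att_f - att_m - rec_f - rec_m - gap,
        }


def attendance_over(
    kept: Segmentation,
    excluded: Segmentation,
    windows: Sequence[MonitoringWindow],
    start: dt.datetime,
    end: dt.datetime,
) -> dict:
    """Attendance decomposition of ``[start, end)`` by half-open clipping."""
    bundle = _Bundle.build(kept, excluded, windows)
    row = bundle.row(_epoch(start), _epoch(end))
    m = row["monitored_seconds"]
    row["attendance"] = (
        (row["attended_seconds_female"] + row["attended_seconds_male"]) / m
        if m > 0
        else np.nan
    )
    row["included"] = m > 0
    row["exclusion_reason"] = "" if m > 0 else "outside monitoring"
    return row


def _span_bins(
    windows: Sequence[MonitoringWindow], tz: dt.timezone, step: str
) -> list[dt.datetime]:
    """Clock-aligned bin starts (local time) covering all windows."""
    if not windows:
        return []
    lo = min(w.start for w in windows).astimezone(tz)
    hi = max(w.end for w in windows).astimezone(tz)
    if step == "hour":
        cur = lo.replace(minute=0, second=0)
        delta = dt.timedelta(hours=1)
    else:
        cur = lo.replace(hour=0, minute=0, second=0)
        delta = dt.timedelta(days=1)
    out = []
    while cur < hi:
        out.append(cur)
        cur = cur + delta
    return out


def hourly_table(
    kept: Segmentation,
    excluded: Segmentation,
    windows: Sequence[MonitoringWindow],
    tz: dt.timezone,
    filters: FilterThresholds = DEFAULT_FILTERS,
) -> pd.DataFrame:
    """Per-clock-hour attendance rows for one nest.

    A row is included only when the full 3600 s of the hour were monitored
    with no quality-excluded time, and the nest provides at least
    ``filters.min_hours`` such hours.
    """
    nest_id = windows[0].nest_id if windows else ""
    bundle = _Bundle.build(kept, excluded, windows)
    rows = []
    for h in _span_bins(windows, tz, "hour"):
        start = _epoch(h)
        row = bundle.row(start, start + 3600)
        if row["monitored_seconds"] == 0 and row["excluded_seconds"] == 0:
            continue
        row.update(
            nest_id=nest_id,
            hour_start=h,
            date=h.date(),
            hour=h.hour,
            time_h=h.hour + 0.5,  # bin midpoint, hours
            day_in_season=int(h.timetuple().tm_yday),
        )
        full = row["monitored_seconds"] == 3600
        row["included"] = full
        row["exclusion_reason"] = "" if full else "incomplete hour"
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    n_full = int(df["included"].sum())
    if n_full < filters.min_hours:
        df["included"] = False
        df.loc[df["exclusion_reason"] == "", "exclusion_reason"] = (
            f"<{filters.min_hours} h"
        )
    df["attendance_female"] = df["attended_seconds_female"] / 3600.0
    df["attendance_male"] = df["attended_seconds_male"] / 3600.0
    df["attendance"] = df["attendance_female"] + df["attendance_male"]
    return df


def daily_table(
    kept: Segmentation,
    excluded: Segmentation,
    windows: Sequence[MonitoringWindow],
    metadata: NestMetadata,
    filters: FilterThresholds = DEFAULT_FILTERS,
) -> pd.DataFrame:
    """Per-calendar-day (local time) attendance rows for one nest.

    A day is included when monitored (after quality exclusion) for more
    than ``filters.day_coverage`` of 86 400 s.  Also emits the seasonal
    covariates: day_of_incubation (clamped at 0) and season_start_day.
    """
    bundle = _Bundle.build(kept, excluded, windows)
    tz = metadata.tz
    rows = []
    for d in _span_bins(windows, tz, "day"):
        start = _epoch(d)
        row = bundle.row(start, start + 86400)
        if row["monitored_seconds"] == 0 and row["excluded_seconds"] == 0:
            continue
        doi = (d.date() - metadata.incubation_start).days
        if doi < 0:
            warnings.warn(
                f"nest {metadata.nest_id}: monitoring on {d.date()} precedes "
                "incubation start; day_of_incubation clamped to 0"
            )
            doi = 0
        m = row["monitored_seconds"]
        ok = m > filters.day_coverage * 86400
        row.update(
            nest_id=metadata.nest_id,
            date=d.date(),
            day_of_incubation=doi,
            season_start_day=metadata.season_start_day,
            included=ok,
            exclusion_reason="" if ok else f"monitored {m/864:.1f}% of day",
            attendance_female=row["attended_seconds_female"] / m if m else np.nan,
            attendance_male=row["attended_seconds_male"] / m if m else np.nan,
        )
        row["attendance"] = row["attendance_female"] + row["attendance_male"]
        rows.append(row)
    return pd.DataFrame(rows)


def _median_bout_seconds(bouts: Sequence[Bout], sex: str) -> float:
    ok = [b.seconds for b in bouts if b.sex == sex and b.complete and not b.tainted]
    return float(np.median(ok)) if ok else np.nan


def nest_summary(
    kept: Segmentation,
    excluded: Segmentation,
    windows: Sequence[MonitoringWindow],
    metadata: NestMetadata,
    daily: Optional[pd.DataFrame] = None,
    filters: FilterThresholds = DEFAULT_FILTERS,
) -> dict:
    """Overall per-nest summary over included days.

    Qualifies for nest-level analyses iff at least ``filters.min_days``
    days pass the daily coverage filter.  Bout medians use complete,
    untainted bouts (unsplit).  Daylight male attendance uses the
    sunrise-to-sunset (-0.833 degree) span of each monitored day.
    """
    if daily is None:
        daily = daily_table(kept, excluded, windows, metadata, filters)
    inc = daily[daily["included"]] if not daily.empty else daily
    n_days = int(len(inc))
    monitored = float(inc["monitored_seconds"].sum()) if n_days else 0.0
    att_f = float(inc["attended_seconds_female"].sum()) if n_days else 0.0
    att_m = float(inc["attended_seconds_male"].sum()) if n_days else 0.0

    # responsibility: whole-bout coverage clipped to the included days
    day_bins = (
        _IntervalSet(
            [
                (_epoch(dt.datetime.combine(d, dt.time(0), tzinfo=metadata.tz)),
                 _epoch(dt.datetime.combine(d, dt.time(0), tzinfo=metadata.tz)) + 86400)
                for d in inc["date"]
            ]
        )
        if n_days
        else _IntervalSet([])
    )
    resp = {FEMALE: 0, MALE: 0}
    for b in kept.bouts:
        if n_days:
            resp[b.sex] += day_bins.overlap(_epoch(b.start), _epoch(b.end))

    # daylight male attendance over monitored days (hour-scale male share of
    # the sunrise..sunset span)
    ctx = solar.SolarContext(metadata.latitude, metadata.longitude, metadata.utc_offset)
    bundle = _Bundle.build(kept, excluded, windows)
    day_att_m = day_monitored = 0
    if not daily.empty:
        for d in daily["date"]:
            rs = solar.sunrise_sunset(ctx, d)
            if rs is None:
                continue
            s, e = _epoch(rs[0]), _epoch(rs[1])
            r = bundle.row(s, e)
            day_att_m += r["attended_seconds_male"]
            day_monitored += r["monitored_seconds"]

    male_att = att_m / monitored if monitored else np.nan
    return {
        "nest_id": metadata.nest_id,
        "n_days_included": n_days,
        "monitored_seconds": monitored,
        "overall_attendance": (att_f + att_m) / monitored if monitored else np.nan,
        "female_attendance": att_f / monitored if monitored else np.nan,
        "male_attendance": male_att,
        "female_responsibility": resp[FEMALE] / monitored if monitored else np.nan,
        "male_responsibility": resp[MALE] / monitored if monitored else np.nan,
        "daylight_male_attendance": (
            day_att_m / day_monitored if day_monitored else np.nan
        ),
        "median_bout_female_s": _median_bout_seconds(kept.bouts, FEMALE),
        "median_bout_male_s": _median_bout_seconds(kept.bouts, MALE),
        "uniparental": not any(b.sex == MALE for b in kept.bouts),
        "included": n_days >= filters.min_days,
        "exclusion_reason": (
            "" if n_days >= filters.min_days else f"<{filters.min_days} included days"
        ),
    }


def longest_night_bouts(
    kept: Segmentation,
    metadata: NestMetadata,
    dates: Sequence[dt.date],
    filters: FilterThresholds = DEFAULT_FILTERS,
) -> pd.DataFrame:
    """Longest qualifying female bout per night.

    A night belongs to the evening date it begins on.  A female bout
    qualifies for a night when at least ``filters.night_fraction`` (default
    60%) of its length falls in night (sun below -6 degrees); per night the
    longest qualifying bout is reported, nights with none are omitted.
    """
    ctx = solar.SolarContext(metadata.latitude, metadata.longitude, metadata.utc_offset)
    rows = []
    for d in sorted(set(dates)):
        night = solar.night_for_evening(ctx, d)
        if night is None:
            continue
        ns, ne = _epoch(night.start), _epoch(night.end)
        best = None
        for b in kept.bouts:
            if b.sex != FEMALE:
                continue
            bs, be = _epoch(b.start), _epoch(b.end)
            if min(be, ne) <= max(bs, ns):
                continue  # no overlap with this night
            frac = solar.fraction_in_night(ctx, b.start, b.end)
            if frac >= filters.night_fraction:
                if best is None or b.seconds > best:
                    best = b.seconds
        if best is not None:
            rows.append(
                {
                    "nest_id": metadata.nest_id,
                    "night_date": d,
                    "night_length_s": night.length,
                    "longest_female_bout_s": best,
                }
            )
    return pd.DataFrame(rows)
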