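"""Sun-position geometry for incubation analyses.

Night is defined as the Sun more than 6 degrees below the horizon (end of
civil twilight); sunrise/sunset use the conventional -0.833 degree crossing
(solar radius plus standard refraction).  Elevation comes from the NOAA
low-precision solar-position equations (Fourier series in the day angle),
good to about 0.1-0.2 degrees — ample for twilight bookkeeping, where a
0.2 degree error moves a crossing by under a minute at mid-latitudes.

All instants are timezone-aware datetimes; computations run in UTC.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SolarContext",
    "NightInterval",
    "sun_elevation",
    "night_intervals",
    "night_for_evening",
    "sunrise_sunset",
    "fraction_in_night",
]

NIGHT_THRESHOLD_DEG = -6.0
SUNRISE_THRESHOLD_DEG = -0.833


@dataclass(frozen=True)
class SolarContext:
    """Site geometry and the elevation thresholds used for day/night rules."""

    latitude: float
    longitude: float
    utc_offset: float = 0.0  # hours; local civil time = UTC + offset
    night_threshold: float = NIGHT_THRESHOLD_DEG
    sunrise_threshold: float = SUNRISE_THRESHOLD_DEG

    def __post_init__(self) -> None:
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValueError(f"longitude out of range: {self.longitude}")
        for thr in (self.night_threshold, self.sunrise_threshold):
            if not (-18.0 < thr < 5.0):
                raise ValueError(f"threshold out of range: {thr}")

    @property
    def tz(self) -> dt.timezone:
        return dt.timezone(dt.timedelta(hours=self.utc_offset))


@dataclass(frozen=True)
class NightInterval:
    """A maximal interval with sun elevation below the night threshold.

    ``date`` is the civil date the night is keyed to (the evening on which
    it begins, for nights spanning midnight).
    """

    date: dt.date
    start: dt.datetime
    end: dt.datetime

    @property
    def length(self) -> int:
        return int((self.end - self.start).total_seconds())


def _elevation_epoch(lat: float, lon: float, epoch: np.ndarray) -> np.ndarray:
    """Geometric solar elevation (degrees) at POSIX epoch seconds (UTC)."""
    epoch = np.asarray(epoch, dtype=float)
    # seconds since start of the UTC year, without building datetimes per sample
    days = epoch / 86400.0
    # fractional day-of-year: derive from the Gregorian calendar via numpy
    d64 = epoch.astype("datetime64[s]")
    year_start = d64.astype("datetime64[Y]").astype("datetime64[s]")
    doy = (d64 - year_start).astype(float) / 86400.0  # 0-based fractional
    frac_hour = (days - np.floor(days)) * 24.0  # UTC hour of day

    gamma = 2.0 * np.pi / 365.0 * (doy + (frac_hour - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )
    time_offset = eqtime + 4.0 * lon  # minutes
    tst = frac_hour * 60.0 + time_offset  # true solar time, minutes
    ha = np.deg2rad(tst / 4.0 - 180.0)  # hour angle
    lat_r = np.deg2rad(lat)
    cos_zen = np.sin(lat_r) * np.sin(decl) + np.cos(lat_r) * np.cos(decl) * np.cos(ha)
    cos_zen = np.clip(cos_zen, -1.0, 1.0)
    return 90.0 - np.rad2deg(np.arccos(cos_zen))


def sun_elevation(ctx: SolarContext, t: dt.datetime) -> float:
    """Geometric solar elevation in degrees at instant ``t`` (tz-aware)."""
    if t.tzinfo is None:
        raise ValueError("sun_elevation requires a timezone-aware instant")
    epoch = t.timestamp()
    return float(_elevation_epoch(ctx.latitude, ctx.longitude, np.array([epoch]))[0])


def _bisect_crossing(
    ctx: SolarContext, lo: float, hi: float, threshold: float
) -> float:
    """Epoch second where elevation crosses ``threshold`` between lo and hi."""
    f_lo = _elevation_epoch(ctx.latitude, ctx.longitude, np.array([lo]))[0] - threshold
    while hi - lo > 1.0:
        mid = 0.5 * (lo + hi)
        f_mid = (
            _elevation_epoch(ctx.latitude, ctx.longitude, np.array([mid]))[0]
            - threshold
        )
        if (f_lo < 0) == (f_mid < 0):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    return float(np.ceil(hi))


def _below_intervals(
    ctx: SolarContext,
    start_epoch: float,
    end_epoch: float,
    threshold: float,
) -> list[Tuple[float, float]]:
    """Maximal [s, e) sub-intervals with elevation below ``threshold``.

    60-second scan over [start, end) followed by bisection of each crossing
    to 1-second precision.
    """
    grid = np.arange(start_epoch, end_epoch + 60.0, 60.0)
    grid[-1] = end_epoch
    elev = _elevation_epoch(ctx.latitude, ctx.longitude, grid)
    below = elev < threshold
    out: list[Tuple[float, float]] = []
    i = 0
    n = len(grid)
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and below[j + 1]:
            j += 1
        s = grid[i] if i == 0 else _bisect_crossing(ctx, grid[i - 1], grid[i], threshold)
        e = grid[j] if j == n - 1 else _bisect_crossing(ctx, grid[j], grid[j + 1], threshold)
        if e > s:
            out.append((s, e))
        i = j + 1
    return out


def _day_bounds_epoch(ctx: SolarContext, date: dt.date) -> Tuple[float, float]:
    start = dt.datetime.combine(date, dt.time(0), tzinfo=ctx.tz)
    return start.timestamp(), start.timestamp() + 86400.0


def night_intervals(ctx: SolarContext, date: dt.date) -> list[NightInterval]:
    """Night intervals (elevation < night_threshold) within the civil date."""
    s, e = _day_bounds_epoch(ctx, date)
    out = []
    for a, b in _below_intervals(ctx, s, e, ctx.night_threshold):
        out.append(
            NightInterval(
                date=date,
                start=dt.datetime.fromtimestamp(a, tz=ctx.tz),
                end=dt.datetime.fromtimestamp(b, tz=ctx.tz),
            )
        )
    return out


def night_for_evening(ctx: SolarContext, date: dt.date) -> Optional[NightInterval]:
    """The night that begins on the evening of ``date``.

    Searched from local noon of ``date`` to local noon of the next day;
    returns None under polar day (no interval below the night threshold).
    """
    noon = dt.datetime.combine(date, dt.time(12), tzinfo=ctx.tz).timestamp()
    pieces = _below_intervals(ctx, noon, noon + 86400.0, ctx.night_threshold)
    if not pieces:
        return None
    # maximal piece starting after this noon; pieces are disjoint and sorted
    a, b = max(pieces, key=lambda p: p[1] - p[0])
    return NightInterval(
        date=date,
        start=dt.datetime.fromtimestamp(a, tz=ctx.tz),
        end=dt.datetime.fromtimestamp(b, tz=ctx.tz),
    )


def sunrise_sunset(
    ctx: SolarContext, date: dt.date
) -> Optional[Tuple[dt.datetime, dt.datetime]]:
    """Sunrise and sunset instants (-0.833 degree crossings) on the civil date.

    Returns None for polar day or polar night (no crossing).
    """
    s, e = _day_bounds_epoch(ctx, date)
    below = _below_intervals(ctx, s, e, ctx.sunrise_threshold)
    if not below:
        return None  # polar day: sun never below threshold
    total_below = sum(b - a for a, b in below)
    if total_below >= (e - s) - 1:
        return None  # polar night
    # sunrise = end of the below-interval touching the morning; sunset = start
    # of the below-interval touching the evening
    rise = None
    sset = None
    for a, b in below:
        if a <= s + 1 and b < e - 1:
            rise = b
        if b >= e - 1 and a > s + 1:
            sset = a
    if rise is None:  # sun already up at midnight? (high latitude summer)
        rise = below[0][1] if below[0][0] <= s + 1 else None
    if rise is None or sset is None:
        return None
    return (
        dt.datetime.fromtimestamp(rise, tz=ctx.tz),
        dt.datetime.fromtimestamp(sset, tz=ctx.tz),
    )


def fraction_in_night(
    ctx: SolarContext, start: dt.datetime, end: dt.datetime
) -> float:
    """Fraction of [start, end) spent with the sun below the night threshold."""
    if end <= start:
        raise ValueError("fraction_in_night requires a positive-length interval")
    s, e = start.timestamp(), end.timestamp()
    pieces = _below_intervals(ctx, s, e, ctx.night_threshold)
    overlap = sum(min(b, e) - max(a, s) for a, b in pieces)
    return float(overlap / (e - s))
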