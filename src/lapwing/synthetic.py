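"""Synthetic biparental incubation studies with known ground truth.

The generator emulates the statistical structure of a temperate-zone
shorebird incubation study: nests monitored continuously for a few days,
female-dominated attendance with highly variable male contributions,
whole-night female incubation, male take-overs concentrated after sunrise
and before sunset, lognormal bout and exchange-gap durations, and recesses
inserted inside bouts so each nest hits its target attendance.

Mechanism: an alternating-renewal state machine over event time.  At each
exchange the next incubator is drawn from sex-specific weights (the male
weight carries post-sunrise and pre-sunset bumps); bout durations are
sex-specific lognormals; at night-fall the sitter hands over and the female
holds one bout spanning the whole night (sun below -6 degrees) with
probability ``p_night``.  Recesses are then allocated inside daytime bout
portions, day by day, so realized daily attendance matches the nest's
per-day target; nights stay recess-free.  Everything is rounded to integer
seconds and emitted as arrival/departure events that pass validation with
zero fatal violations.

Nest-level heterogeneity (attendance and male-share random effects, with
female attendance coupled to male attendance through a configurable
compensation slope) gives nonzero day-to-day repeatability and a known
compensation truth for estimator-recovery tests.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.stats

from . import io, solar
from .io import FEMALE, MALE, ARRIVAL, DEPARTURE, EventRecord, MonitoringWindow, NestMetadata

__all__ = [
    "SimulationConfig",
    "TrueParams",
    "Study",
    "simulate_nest",
    "simulate_study",
    "simulate_daily_attendance",
    "simulate_hourly_rhythm",
]

INCUBATION_PERIOD_DAYS = 27


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults are the study-like conditions.

    Durations are seconds, times local civil time at ``utc_offset``.
    """

    n_nests: int = 60
    latitude: float = 49.25
    longitude: float = 14.08
    utc_offset: float = 2.0
    season_start: dt.date = dt.date(2015, 4, 1)
    season_end: dt.date = dt.date(2015, 6, 15)
    monitoring_days_range: tuple = (2, 7)
    dropout_per_hour: float = 0.0  # P(a clock hour of recording is lost)
    # male share of monitored time: Beta(a, b) scaled to [0, male_share_max]
    male_share_beta: tuple = (1.6, 2.8)
    male_share_max: float = 0.4
    p_uniparental: float = 0.08  # 5 of 60 nests female-only
    # overall attendance target: median 0.87.  attendance_range is a wide
    # feasibility clamp, NOT the study's observed range: the observed
    # 0.68-0.94 spread emerges from the male-share coupling plus noise, and
    # a hard clip at those values would distort the linear female-male
    # coupling that compensation-recovery rests on.
    attendance_median: float = 0.87
    attendance_range: tuple = (0.60, 0.97)
    attendance_sd: float = 0.045  # between-nest sd of the target
    attendance_day_sd: float = 0.05  # day-to-day jitter around the nest target
    male_day_sd: float = 0.03  # day-to-day jitter of the male attendance
    compensation: float = 0.62  # slope coupling female to male attendance
    female_bout_median_s: float = 3600.0  # 60 min (daytime)
    male_bout_median_s: float = 1920.0  # 32 min
    bout_sigma: float = 0.7  # lognormal shape of bout durations
    gap_median_s: float = 114.0  # 1.9 min
    gap_sigma: float = 0.9
    gap_min_s: int = 6
    p_night: float = 1.0  # P(female holds one bout spanning the night)
    male_peak_amp: float = 1.5  # post-sunrise / pre-sunset take-over bumps
    male_peak_width_h: float = 1.5
    # per daytime bout portion; a nest holding the whole night at 68%
    # overall attendance must spend ~half the daylight off the nest, so
    # this cap has to clear that
    max_recess_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.dropout_per_hour, self.p_uniparental, self.p_night):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of range: {p}")
        if self.gap_median_s > 10 * min(
            self.female_bout_median_s, self.male_bout_median_s
        ):
            raise ValueError("infeasible config: gaps longer than bouts")
        lo, hi = self.monitoring_days_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad monitoring_days_range: {(lo, hi)}")

    @property
    def male_share_median(self) -> float:
        """Population median male share, uniparental zeros included."""
        if self.p_uniparental >= 0.5:
            return 0.0
        a, b = self.male_share_beta
        q = (0.5 - self.p_uniparental) / (1.0 - self.p_uniparental)
        return float(self.male_share_max * scipy.stats.beta.ppf(q, a, b))

    @property
    def tz(self) -> dt.timezone:
        return dt.timezone(dt.timedelta(hours=self.utc_offset))


@dataclass
class TrueParams:
    """Ground truth stored alongside a simulated nest for recovery tests."""

    nest_id: str
    male_share: float
    attendance_target: float
    female_attendance_target: float
    uniparental: bool
    compensation: float
    p_male_takeover: float
    day_targets: dict = field(default_factory=dict)  # date iso -> attendance


@dataclass
class Study:
    """A simulated study bundle: inputs for the full pipeline plus truth."""

    config: SimulationConfig
    events: list = field(default_factory=list)
    windows: list = field(default_factory=list)
    metadata: list = field(default_factory=list)
    truth: list = field(default_factory=list)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_events(self.events, outdir / "events.csv")
        io.write_windows(self.windows, outdir / "windows.csv")
        io.write_metadata(self.metadata, outdir / "metadata.csv")
        truth = [dataclasses.asdict(t) for t in self.truth]
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# interval helpers (epoch-second integer arithmetic)


def _subtract(intervals, cuts):
    """Set difference of half-open interval lists (both sorted, disjoint)."""
    out = []
    for s, e in intervals:
        cur = s
        for cs, ce in cuts:
            if ce <= cur or cs >= e:
                continue
            if cs > cur:
                out.append((cur, min(cs, e)))
            cur = max(cur, ce)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return [(s, e) for s, e in out if e > s]


def _overlap_len(a, b):
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


class _NestClock:
    """Night lookup over the monitoring span of one nest."""

    def __init__(self, config: SimulationConfig, span: tuple[int, int]):
        ctx = solar.SolarContext(config.latitude, config.longitude, config.utc_offset)
        tz = config.tz
        d0 = dt.datetime.fromtimestamp(span[0], tz).date() - dt.timedelta(days=1)
        d1 = dt.datetime.fromtimestamp(span[1], tz).date() + dt.timedelta(days=1)
        self.nights: list[tuple[int, int]] = []
        d = d0
        while d <= d1:
            night = solar.night_for_evening(ctx, d)
            if night is not None:
                self.nights.append(
                    (int(night.start.timestamp()), int(night.end.timestamp()))
                )
            d += dt.timedelta(days=1)
        self.ctx = ctx
        self.tz = tz
        self.span = span
        self._sun_cache: dict = {}

    def night_at(self, t: int) -> Optional[tuple[int, int]]:
        for ns, ne in self.nights:
            if ns <= t < ne:
                return (ns, ne)
        return None

    def next_night_start(self, t: int) -> int:
        for ns, ne in self.nights:
            if ns >= t:
                return ns
        return self.span[1] + 86400

    def local_hour(self, t: int) -> float:
        loc = dt.datetime.fromtimestamp(t, self.tz)
        return loc.hour + loc.minute / 60.0 + loc.second / 3600.0

    def sunrise_sunset_at(self, t: int):
        d = dt.datetime.fromtimestamp(t, self.tz).date()
        if d not in self._sun_cache:
            self._sun_cache[d] = solar.sunrise_sunset(self.ctx, d)
        return self._sun_cache[d]

    def day_length_h(self) -> float:
        rs = self.sunrise_sunset_at((self.span[0] + self.span[1]) // 2)
        if rs is None:
            return 24.0
        return max(1.0, (rs[1] - rs[0]).total_seconds() / 3600.0)


def _lognormal(rng, median: float, sigma: float) -> float:
    return float(median * np.exp(sigma * rng.standard_normal()))


def _male_weight(clock: _NestClock, t: int, amp: float, width_h: float) -> float:
    """Circadian multiplier for male take-overs: bumps after sunrise and
    before sunset."""
    rs = clock.sunrise_sunset_at(t)
    if rs is None:
        return 1.0
    rise_h = rs[0].hour + rs[0].minute / 60.0
    set_h = rs[1].hour + rs[1].minute / 60.0
    h = clock.local_hour(t)
    bump = np.exp(-0.5 * ((h - (rise_h + 1.0)) / width_h) ** 2) + np.exp(
        -0.5 * ((h - (set_h - 1.0)) / width_h) ** 2
    )
    return float(1.0 + amp * bump)


def simulate_nest(
    config: SimulationConfig, nest_seed, nest_id: str = "N001"
) -> tuple[list, list, NestMetadata, TrueParams]:
    """Simulate one nest; returns (events, windows, metadata, truth).

    ``nest_seed`` feeds numpy's default_rng; identical (config, seed) give
    identical streams.
    """
    rng = np.random.default_rng(nest_seed)

    # -- nest-level truth ---------------------------------------------------
    season_days = (config.season_end - config.season_start).days
    incubation_start = config.season_start + dt.timedelta(
        days=int(rng.integers(0, max(1, season_days - INCUBATION_PERIOD_DAYS)))
    )
    uniparental = bool(rng.random() < config.p_uniparental)
    if uniparental:
        male_share = 0.0
    else:
        a, b = config.male_share_beta
        male_share = float(config.male_share_max * rng.beta(a, b))
    c = config.compensation
    base_female = config.attendance_median - (1.0 - c) * config.male_share_median
    attendance = float(
        np.clip(
            base_female
            + (1.0 - c) * male_share
            + config.attendance_sd * rng.standard_normal(),
            *config.attendance_range,
        )
    )

    lo, hi = config.monitoring_days_range
    n_days = int(rng.integers(lo, hi + 1))
    day_offset = int(rng.integers(0, max(1, INCUBATION_PERIOD_DAYS - n_days)))
    start_date = incubation_start + dt.timedelta(days=day_offset)
    span_start = int(
        dt.datetime.combine(start_date, dt.time(0), tzinfo=config.tz).timestamp()
    )
    span_end = span_start + n_days * 86400
    clock = _NestClock(config, (span_start, span_end))

    # male take-over probability from the target male share of daytime
    night_secs = sum(
        _overlap_len(n, (span_start, span_end)) for n in clock.nights
    )
    day_secs = (span_end - span_start) - night_secs
    day_frac = day_secs / (span_end - span_start)
    mu_f = config.female_bout_median_s * np.exp(config.bout_sigma**2 / 2)
    mu_m = config.male_bout_median_s * np.exp(config.bout_sigma**2 / 2)
    # daytime attendance implied by the overall target, given full nights
    att_day = np.clip(
        (attendance - config.p_night * (1 - day_frac)) / max(day_frac, 1e-9),
        0.05,
        0.98,
    )
    exp_recess_frac = max(0.0, 1.0 - att_day / 0.96)  # ~4% of daytime is gaps
    s_day = np.clip(
        male_share / max(day_frac * (1.0 - exp_recess_frac), 1e-9), 0.0, 0.95
    )
    p_male = float(s_day * mu_f / (s_day * mu_f + (1.0 - s_day) * mu_m)) if s_day else 0.0

    # -- alternating-renewal bout sequence ---------------------------------
    # normalize the circadian bump so the day-average take-over rate stays p
    w_denom = 1.0 + config.male_peak_amp * (
        2.0 * config.male_peak_width_h * np.sqrt(2.0 * np.pi)
    ) / clock.day_length_h()

    def renewal(r, p: float, s_aim: float = 0.0) -> list[list]:
        def draw_gap() -> int:
            g = _lognormal(r, config.gap_median_s, config.gap_sigma)
            return max(config.gap_min_s, int(round(g)))

        seq: list[list] = []  # [sex, start, end]
        day_secs_by_sex = {FEMALE: 0.0, MALE: 0.0}

        def push(sex: str, s: int, e: int) -> None:
            e = min(e, span_end)
            if e - s >= 1:
                day_len = sum(
                    pe - ps for ps, pe in _subtract([(s, e)], clock.nights)
                )
                day_secs_by_sex[sex] += day_len
                if seq and seq[-1][0] == sex and seq[-1][2] >= s:
                    seq[-1][2] = e  # merge adjoining same-sex pieces
                else:
                    seq.append([sex, s, e])

        t = span_start
        force_male = False
        while t < span_end:
            night = clock.night_at(t)
            if night is not None and r.random() < config.p_night:
                push(FEMALE, t, night[1])
                t = night[1] + draw_gap()
                # the male relieves the female right after dawn (post-sunrise
                # male peak); it also keeps her whole-night bout from merging
                # with her morning bouts
                force_male = not uniparental
                continue
            # daytime (or night with p_night miss): pick a sex and duration
            if uniparental:
                sex = FEMALE
            elif force_male:
                sex = MALE
                force_male = False
            else:
                w = _male_weight(
                    clock, t, config.male_peak_amp, config.male_peak_width_h
                )
                p_t = p * w / w_denom
                tot = day_secs_by_sex[FEMALE] + day_secs_by_sex[MALE]
                if s_aim > 0 and tot > 3600:
                    # proportional control: nudge the take-over rate toward
                    # the target share to damp renewal noise within a nest
                    share_so_far = day_secs_by_sex[MALE] / tot
                    p_t *= 1.0 + 3.0 * (s_aim - share_so_far) / max(s_aim, 0.02)
                sex = MALE if r.random() < float(np.clip(p_t, 0.0, 0.97)) else FEMALE
            dur = max(60, int(round(_lognormal(
                r,
                config.female_bout_median_s
                if sex == FEMALE
                else config.male_bout_median_s,
                config.bout_sigma,
            ))))
            ns = clock.next_night_start(t)
            if t + dur < ns or uniparental or ns >= span_end:
                push(sex, t, min(t + dur, ns if not uniparental else span_end))
                t = min(t + dur, span_end)
                if not uniparental and t < span_end:
                    t += draw_gap()
                continue
            # the bout would cross night-fall: hand the dusk slot to the male
            # so the female takes a clean whole-night bout (pre-sunset peak)
            if sex == FEMALE and ns - t > 900:
                g = min(draw_gap(), (ns - t) // 4)
                cut = t + max(60, (ns - t) // 2)
                push(FEMALE, t, cut)
                push(MALE, cut + g, ns)
            else:
                push(MALE, t, ns)
            t = ns + draw_gap()  # gap before the female's whole-night bout
        return seq

    def male_day_share(seq) -> float:
        day_by_sex = {FEMALE: 0, MALE: 0}
        for sex, s, e in seq:
            pieces = _subtract([(s, e)], clock.nights)
            day_by_sex[sex] += sum(pe - ps for ps, pe in pieces)
        tot = day_by_sex[FEMALE] + day_by_sex[MALE]
        return day_by_sex[MALE] / tot if tot else 0.0

    # one trial pass measures how take-over probability maps to realized
    # daytime share (bout merging and dusk/night truncation distort the
    # renewal-theory odds), then one corrected pass generates the stream
    trial_rng, final_rng = rng.spawn(2)
    if uniparental or s_day <= 0:
        bouts = renewal(final_rng, p_male)
    else:
        # aim ~15% above the target share: the surplus male sitting time is
        # trimmed back by male recesses below, which pins realized male
        # attendance to its target instead of leaving renewal noise in
        # both axes of the female-male coupling
        # overshoot must leave the female enough daytime to reach her own
        # attendance target (night hours included), or her shortfall would
        # leak into the female-male coupling
        f_day_need = max(
            0.0,
            (attendance - male_share - config.p_night * (1.0 - day_frac))
            / max(day_frac, 1e-9),
        )
        s_feas = max(0.0, 0.95 - f_day_need)
        s_aim = min(1.15 * s_day, max(s_feas, s_day), 0.95)
        s1 = male_day_share(renewal(trial_rng, p_male, s_aim))
        if 0.0 < s1 < 0.97:
            k = (p_male / (1.0 - p_male)) / (s1 / (1.0 - s1))
            odds = k * s_aim / (1.0 - s_aim)
            p_male = float(np.clip(odds / (1.0 + odds), 0.0, 0.97))
        bouts = renewal(final_rng, p_male, s_aim)

    # -- recess allocation ---------------------------------------------------
    # Budgets are sex-specific: the male budget trims his (deliberately
    # overshot) sitting time back to the nest's male-attendance target, the
    # female budget trims her time to her own target f = a - m, so the
    # female-male attendance coupling is not contaminated by the other
    # sex's realization error.  Budgets are settled at the nest level first
    # (a day with a sitting-time deficit borrows from surplus days) and then
    # spread over days following the per-day targets.
    day_targets: dict = {}
    recesses_by_bout: dict[int, list] = {i: [] for i in range(len(bouts))}
    # day-to-day jitter: clipped symmetrically around the nest target and
    # re-centred, so the span mean stays on the target even near the
    # feasibility ceiling
    bound_a = max(0.0, min(0.98 - attendance, attendance - 0.05))
    jitter = np.clip(
        config.attendance_day_sd * rng.standard_normal(n_days), -bound_a, bound_a
    )
    bound_m = max(0.0, min(0.6 - male_share, male_share))
    m_jitter = np.clip(
        config.male_day_sd * rng.standard_normal(n_days), -bound_m, bound_m
    )
    if n_days > 1:
        jitter -= jitter.mean()
        m_jitter -= m_jitter.mean()

    day_info = []
    for di in range(n_days):
        ds, de = span_start + di * 86400, span_start + (di + 1) * 86400
        date = dt.datetime.fromtimestamp(ds, config.tz).date()
        a_day = float(np.clip(attendance + jitter[di], 0.05, 0.98))
        m_day = (
            float(np.clip(male_share + m_jitter[di], 0.0, 0.6))
            if not uniparental
            else 0.0
        )
        day_targets[date.isoformat()] = a_day
        # daytime-only bout portions eligible for recesses, per sex
        portions: dict[str, list] = {FEMALE: [], MALE: []}
        on_day = {FEMALE: 0, MALE: 0}
        for i, (sex, s, e) in enumerate(bouts):
            clipped = (max(s, ds), min(e, de))
            if clipped[1] <= clipped[0]:
                continue
            on_day[sex] += clipped[1] - clipped[0]
            for ps, pe in _subtract([clipped], clock.nights):
                if pe - ps > 120:
                    portions[sex].append((i, ps, pe))
        f_day = max(0.0, a_day - m_day)  # the female's own attendance target
        day_info.append(
            {
                "portions": portions,
                "on": on_day,
                "want": {FEMALE: f_day * (de - ds), MALE: m_day * (de - ds)},
                "eligible": {
                    sx: sum(pe - ps for _, ps, pe in portions[sx])
                    for sx in portions
                },
            }
        )

    for sx in (FEMALE, MALE):
        total_trim = sum(d["on"][sx] - d["want"][sx] for d in day_info)
        if total_trim <= 0:
            continue
        # spread the nest-level trim over days proportional to their surplus
        surplus = np.array(
            [max(0.0, d["on"][sx] - d["want"][sx]) for d in day_info]
        )
        cap = np.array(
            [config.max_recess_fraction * d["eligible"][sx] for d in day_info]
        )
        alloc = np.minimum(surplus, cap)
        scale = min(1.0, total_trim / alloc.sum()) if alloc.sum() > 0 else 0.0
        for d, budget in zip(day_info, np.floor(alloc * scale).astype(int)):
            if budget <= 0 or d["eligible"][sx] == 0:
                continue
            for i, ps, pe in d["portions"][sx]:
                share = int(round(budget * (pe - ps) / d["eligible"][sx]))
                share = min(share, int(config.max_recess_fraction * (pe - ps)))
                if share < 30:
                    continue
                recesses_by_bout[i].extend(_place_recesses(rng, ps, pe, share))

    # -- events ---------------------------------------------------------------
    events: list[EventRecord] = []

    def emit(sex: str, transition: str, epoch: int) -> None:
        if span_start <= epoch < span_end:
            events.append(
                EventRecord(
                    nest_id=nest_id,
                    timestamp=dt.datetime.fromtimestamp(epoch, config.tz),
                    actor=sex,
                    transition=transition,
                )
            )

    for i, (sex, s, e) in enumerate(bouts):
        emit(sex, ARRIVAL, s)
        for rs, re_ in sorted(recesses_by_bout[i]):
            emit(sex, DEPARTURE, rs)
            emit(sex, ARRIVAL, re_)
        if e < span_end:
            emit(sex, DEPARTURE, e)

    # -- monitoring windows (hourly dropout) ----------------------------------
    windows: list[MonitoringWindow] = []
    hours = [(span_start + h * 3600, min(span_start + (h + 1) * 3600, span_end))
             for h in range((span_end - span_start + 3599) // 3600)]
    keep = rng.random(len(hours)) >= config.dropout_per_hour
    cur = None
    for (hs, he), k in zip(hours, keep):
        if k:
            cur = [hs, he] if cur is None else cur
            cur[1] = he
        elif cur is not None:
            windows.append(_mk_window(nest_id, cur, config.tz))
            cur = None
    if cur is not None:
        windows.append(_mk_window(nest_id, cur, config.tz))
    win_set = [(int(w.start.timestamp()), int(w.end.timestamp())) for w in windows]
    events = [
        ev
        for ev in events
        if any(s <= int(ev.timestamp.timestamp()) < e for s, e in win_set)
    ]

    metadata = NestMetadata(
        nest_id=nest_id,
        latitude=config.latitude,
        longitude=config.longitude,
        utc_offset=config.utc_offset,
        incubation_start=incubation_start,
        season_start_day=int(incubation_start.timetuple().tm_yday),
    )
    truth = TrueParams(
        nest_id=nest_id,
        male_share=male_share,
        attendance_target=attendance,
        female_attendance_target=attendance - male_share,
        uniparental=uniparental,
        compensation=c,
        p_male_takeover=p_male,
        day_targets=day_targets,
    )
    return events, windows, metadata, truth


def _mk_window(nest_id: str, pair, tz) -> MonitoringWindow:
    return MonitoringWindow(
        nest_id=nest_id,
        start=dt.datetime.fromtimestamp(pair[0], tz),
        end=dt.datetime.fromtimestamp(pair[1], tz),
    )


def _place_recesses(rng, ps: int, pe: int, total: int) -> list[tuple[int, int]]:
    """Disjoint recess intervals totalling ``total`` s inside (ps, pe).

    1-second margins are kept at both ends and between recesses so that
    departure/arrival events never collide.
    """
    length = pe - ps
    k = max(1, min(int(rng.poisson(total / 900.0)) + 1, total // 30, 8))
    total = min(total, length - (k + 2) - 2)
    if total < 30:
        return []
    k = min(k, total // 30)
    parts = rng.multinomial(total - k * 15, [1.0 / k] * k) + 15
    free = length - total - (k + 2)
    spacers = rng.multinomial(free, [1.0 / (k + 1)] * (k + 1))
    out = []
    cursor = ps + 1
    for j in range(k):
        cursor += int(spacers[j])
        out.append((cursor, cursor + int(parts[j])))
        cursor += int(parts[j]) + 1
    return out


def simulate_study(config: SimulationConfig) -> Study:
    """Simulate ``config.n_nests`` independent nests.

    Per-nest seeds are spawned from the master seed via numpy's
    SeedSequence, so streams are independent and reproducible.
    """
    study = Study(config=config)
    children = np.random.SeedSequence(config.seed).spawn(config.n_nests)
    for i, child in enumerate(children):
        nest_id = f"N{i + 1:03d}"
        events, windows, metadata, truth = simulate_nest(config, child, nest_id)
        study.events.extend(events)
        study.windows.extend(windows)
        study.metadata.append(metadata)
        study.truth.append(truth)
    return study


# ---------------------------------------------------------------------------
# direct table generators for estimator-calibration tests


def simulate_daily_attendance(
    n_nests: int,
    n_days: int,
    mean: float = 0.72,
    var_between: float = 0.0054,
    var_resid: float = 0.0046,
    seed: int = 0,
) -> "pd.DataFrame":
    """Gaussian random-intercept daily attendance with known ICC.

    True repeatability R = var_between / (var_between + var_resid).
    Returns a daily-table-like frame (nest_id, attendance_female and
    attendance_male both set to the simulated response).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, np.sqrt(var_between), size=n_nests)
    rows = []
    for i in range(n_nests):
        for d in range(n_days):
            y = mean + b[i] + rng.normal(0.0, np.sqrt(var_resid))
            rows.append(
                {
                    "nest_id": f"N{i + 1:03d}",
                    "day": d,
                    "attendance_female": y,
                    "attendance_male": y,
                    "included": True,
                }
            )
    return pd.DataFrame(rows)


def simulate_hourly_rhythm(
    n_nests: int = 30,
    n_days: int = 3,
    mean: float = 0.5,
    amplitude: float = 0.25,
    peak_hour: float = 4.0,
    sex_amplitude_ratio: float = 1.0,
    noise_sd: float = 0.08,
    nest_sd: float = 0.03,
    seed: int = 0,
) -> "pd.DataFrame":
    """Hourly attendance with an injected 24-h cosine rhythm per sex.

    Female attendance peaks at ``peak_hour``; male attendance is in
    antiphase with amplitude scaled by ``sex_amplitude_ratio``.  Returns an
    hourly-table-like frame usable by the rhythm model.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    d0 = dt.date(2015, 4, 15)
    for i in range(n_nests):
        u = rng.normal(0.0, nest_sd)
        for d in range(n_days):
            date = d0 + dt.timedelta(days=d)
            for h in range(24):
                t = h + 0.5
                f = (
                    mean
                    + u
                    + amplitude * np.cos(2 * np.pi * (t - peak_hour) / 24.0)
                    + rng.normal(0.0, noise_sd)
                )
                m = (
                    mean
                    - u
                    - sex_amplitude_ratio
                    * amplitude
                    * np.cos(2 * np.pi * (t - peak_hour) / 24.0)
                    + rng.normal(0.0, noise_sd)
                )
                rows.append(
                    {
                        "nest_id": f"N{i + 1:03d}",
                        "date": date,
                        "day_in_season": int(date.timetuple().tm_yday),
                        "hour": h,
                        "time_h": t,
                        "attendance_female": f,
                        "attendance_male": m,
                        "included": True,
                    }
                )
    return pd.DataFrame(rows)
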