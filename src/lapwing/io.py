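"""Data model and CSV I/O for nest-camera event logs.

Three flat files describe a monitored nest:

* ``events.csv`` — one row per arrival/departure of a parent at a nest,
  time-stamped to the second, with quality flags;
* ``windows.csv`` — the intervals during which the nest was actually
  observed (cameras start and stop mid-incubation);
* ``metadata.csv`` — site coordinates, UTC offset, and the incubation
  calendar anchors used for seasonal covariates.

Intervals are half-open ``[start, end)`` and durations are integer seconds
throughout, so time budgets sum exactly.  Timestamps are local civil time
with an explicit fixed UTC offset (no daylight-saving transitions inside a
window); solar computations convert to UTC.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "FEMALE",
    "MALE",
    "ARRIVAL",
    "DEPARTURE",
    "EventRecord",
    "MonitoringWindow",
    "NestMetadata",
    "Violation",
    "ValidationReport",
    "ParseError",
    "ValidationError",
    "read_events",
    "write_events",
    "read_windows",
    "write_windows",
    "read_metadata",
    "write_metadata",
    "validate_events",
]

FEMALE = "female"
MALE = "male"
ARRIVAL = "arrival"
DEPARTURE = "departure"

_ACTOR_ALIASES = {"f": FEMALE, "female": FEMALE, "m": MALE, "male": MALE}
_TRANSITION_ALIASES = {
    "arrival": ARRIVAL,
    "arr": ARRIVAL,
    "departure": DEPARTURE,
    "dep": DEPARTURE,
}

EVENT_FIELDS = [
    "nest_id",
    "timestamp",
    "actor",
    "transition",
    "uncertain",
    "observer_disturbance",
]
WINDOW_FIELDS = ["nest_id", "start", "end"]
METADATA_FIELDS = [
    "nest_id",
    "lat",
    "lon",
    "utc_offset",
    "incubation_start",
    "season_start_day",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed input violates a structural invariant."""


@dataclass(frozen=True, order=True)
class EventRecord:
    """One arrival or departure of one parent at one nest."""

    nest_id: str
    timestamp: dt.datetime
    actor: str
    transition: str
    uncertain: bool = False
    observer_disturbance: bool = False

    def __post_init__(self) -> None:
        if self.actor not in (FEMALE, MALE):
            raise ValidationError(f"unknown actor: {self.actor!r}")
        if self.transition not in (ARRIVAL, DEPARTURE):
            raise ValidationError(f"unknown transition: {self.transition!r}")
        if self.timestamp.tzinfo is None:
            raise ValidationError("event timestamps must carry a UTC offset")

    @property
    def flagged(self) -> bool:
        return self.uncertain or self.observer_disturbance


@dataclass(frozen=True, order=True)
class MonitoringWindow:
    """A contiguous interval [start, end) during which a nest was observed."""

    nest_id: str
    start: dt.datetime
    end: dt.datetime

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"window end must follow start: {self.start} .. {self.end}"
            )

    @property
    def seconds(self) -> int:
        return int((self.end - self.start).total_seconds())

    def contains(self, t: dt.datetime) -> bool:
        return self.start <= t < self.end


@dataclass(frozen=True)
class NestMetadata:
    """Site and incubation-calendar information for one nest."""

    nest_id: str
    latitude: float
    longitude: float
    utc_offset: float
    incubation_start: dt.date
    season_start_day: int

    def __post_init__(self) -> None:
        if abs(self.latitude) > 90:
            raise ValidationError(f"latitude out of range: {self.latitude}")
        if abs(self.longitude) > 180:
            raise ValidationError(f"longitude out of range: {self.longitude}")

    @property
    def tz(self) -> dt.timezone:
        return dt.timezone(dt.timedelta(hours=self.utc_offset))


def _parse_timestamp(text: str, path: Path, line_no: int) -> dt.datetime:
    try:
        t = dt.datetime.fromisoformat(text.strip())
    except ValueError as exc:
        raise ParseError(f"{path}:{line_no}: malformed timestamp {text!r}") from exc
    if t.tzinfo is None:
        raise ParseError(f"{path}:{line_no}: timestamp {text!r} lacks a UTC offset")
    if t.microsecond:
        raise ParseError(f"{path}:{line_no}: sub-second timestamp {text!r}")
    return t


def _parse_flag(text: str, path: Path, line_no: int) -> bool:
    v = text.strip().lower()
    if v in ("0", "", "false"):
        return False
    if v in ("1", "true"):
        return True
    raise ParseError(f"{path}:{line_no}: flag must be 0/1, got {text!r}")


def _reader(path: Path, expected: Sequence[str]):
    with open(path, newline="") as fh:
        rows = csv.reader(fh)
        header = next(rows, None)
        if header is None or [h.strip() for h in header] != list(expected):
            raise ParseError(
                f"{path}: expected header {','.join(expected)}, got {header}"
            )
        yield from enumerate(rows, start=2)


def read_events(path) -> list[EventRecord]:
    """Read and canonicalize an event log, sorted by (nest, timestamp).

    Actor and transition strings are case-insensitive and tolerate the
    single-letter / abbreviated forms ``f/m`` and ``arr/dep``; surrounding
    whitespace is stripped.  Duplicate (nest, actor, timestamp, transition)
    rows are rejected.
    """
    path = Path(path)
    records: list[EventRecord] = []
    seen: set[tuple] = set()
    for line_no, row in _reader(path, EVENT_FIELDS):
        if len(row) != len(EVENT_FIELDS):
            raise ParseError(f"{path}:{line_no}: expected {len(EVENT_FIELDS)} fields")
        nest_id = row[0].strip()
        timestamp = _parse_timestamp(row[1], path, line_no)
        actor = _ACTOR_ALIASES.get(row[2].strip().lower())
        if actor is None:
            raise ParseError(f"{path}:{line_no}: unknown actor {row[2]!r}")
        transition = _TRANSITION_ALIASES.get(row[3].strip().lower())
        if transition is None:
            raise ParseError(f"{path}:{line_no}: unknown transition {row[3]!r}")
        key = (nest_id, actor, timestamp, transition)
        if key in seen:
            raise ValidationError(f"{path}:{line_no}: duplicate event {key}")
        seen.add(key)
        records.append(
            EventRecord(
                nest_id=nest_id,
                timestamp=timestamp,
                actor=actor,
                transition=transition,
                uncertain=_parse_flag(row[4], path, line_no),
                observer_disturbance=_parse_flag(row[5], path, line_no),
            )
        )
    records.sort(key=lambda r: (r.nest_id, r.timestamp, r.actor, r.transition))
    return records


def write_events(events: Iterable[EventRecord], path) -> None:
    path = Path(path)
    rows = sorted(events, key=lambda r: (r.nest_id, r.timestamp, r.actor, r.transition))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(EVENT_FIELDS)
        for r in rows:
            w.writerow(
                [
                    r.nest_id,
                    r.timestamp.isoformat(),
                    r.actor,
                    r.transition,
                    int(r.uncertain),
                    int(r.observer_disturbance),
                ]
            )


def read_windows(path) -> list[MonitoringWindow]:
    """Read monitoring windows; windows of one nest must be disjoint."""
    path = Path(path)
    windows: list[MonitoringWindow] = []
    for line_no, row in _reader(path, WINDOW_FIELDS):
        if len(row) != len(WINDOW_FIELDS):
            raise ParseError(f"{path}:{line_no}: expected {len(WINDOW_FIELDS)} fields")
        windows.append(
            MonitoringWindow(
                nest_id=row[0].strip(),
                start=_parse_timestamp(row[1], path, line_no),
                end=_parse_timestamp(row[2], path, line_no),
            )
        )
    windows.sort()
    _check_disjoint(windows)
    return windows


def _check_disjoint(windows: Sequence[MonitoringWindow]) -> None:
    for a, b in zip(windows, windows[1:]):
        if a.nest_id == b.nest_id and b.start < a.end:
            raise ValidationError(
                f"overlapping windows for nest {a.nest_id}: "
                f"[{a.start}, {a.end}) and [{b.start}, {b.end})"
            )


def write_windows(windows: Iterable[MonitoringWindow], path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(WINDOW_FIELDS)
        for win in sorted(windows):
            w.writerow([win.nest_id, win.start.isoformat(), win.end.isoformat()])


def read_metadata(path) -> list[NestMetadata]:
    path = Path(path)
    out: list[NestMetadata] = []
    for line_no, row in _reader(path, METADATA_FIELDS):
        if len(row) != len(METADATA_FIELDS):
            raise ParseError(f"{path}:{line_no}: expected {len(METADATA_FIELDS)} fields")
        try:
            out.append(
                NestMetadata(
                    nest_id=row[0].strip(),
                    latitude=float(row[1]),
                    longitude=float(row[2]),
                    utc_offset=float(row[3]),
                    incubation_start=dt.date.fromisoformat(row[4].strip()),
                    season_start_day=int(row[5]),
                )
            )
        except ValueError as exc:
            if isinstance(exc, (ParseError, ValidationError)):
                raise
            raise ParseError(f"{path}:{line_no}: {exc}") from exc
    out.sort(key=lambda m: m.nest_id)
    return out


def write_metadata(metadata: Iterable[NestMetadata], path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(METADATA_FIELDS)
        for m in sorted(metadata, key=lambda m: m.nest_id):
            w.writerow(
                [
                    m.nest_id,
                    repr(m.latitude),
                    repr(m.longitude),
                    repr(m.utc_offset),
                    m.incubation_start.isoformat(),
                    m.season_start_day,
                ]
            )


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    nest_id: str
    kind: str
    fatal: bool
    message: str
    timestamp: Optional[dt.datetime] = None


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def fatal(self) -> list[Violation]:
        return [v for v in self.violations if v.fatal]

    @property
    def repairable(self) -> list[Violation]:
        return [v for v in self.violations if not v.fatal]

    @property
    def ok(self) -> bool:
        return not self.fatal

    def add(self, *args, **kwargs) -> None:
        self.violations.append(Violation(*args, **kwargs))


def infer_initial_on(
    events: Sequence[EventRecord], window: MonitoringWindow
) -> Optional[str]:
    """Who is on the nest at window start, inferred from the event stream.

    An actor whose first event inside the window is a departure must already
    have been sitting when the camera started ("open-start" convention).
    Returns that actor's sex, or None if nobody can be inferred on.
    """
    first: dict[str, str] = {}
    for ev in events:
        if window.contains(ev.timestamp) and ev.actor not in first:
            first[ev.actor] = ev.transition
    on = [a for a, tr in first.items() if tr == DEPARTURE]
    if len(on) > 1:
        raise ValidationError(
            f"nest {window.nest_id}: both parents imply open-start in window "
            f"starting {window.start}"
        )
    return on[0] if on else None


def validate_events(
    events: Sequence[EventRecord], windows: Sequence[MonitoringWindow]
) -> ValidationReport:
    """Check an event stream against the one-incubator state machine.

    Fatal violations (overlap, broken alternation mid-window, events outside
    every window, simultaneous same-actor events) make the stream unusable
    for segmentation; repairable ones (open-start departures) are resolved
    by convention.
    """
    report = ValidationReport()
    events = sorted(events, key=lambda r: (r.nest_id, r.timestamp))
    windows = sorted(windows)
    win_by_nest: dict[str, list[MonitoringWindow]] = {}
    for w in windows:
        win_by_nest.setdefault(w.nest_id, []).append(w)

    by_nest: dict[str, list[EventRecord]] = {}
    for ev in events:
        by_nest.setdefault(ev.nest_id, []).append(ev)

    for nest_id, evs in by_nest.items():
        nest_windows = win_by_nest.get(nest_id, [])
        for ev in evs:
            if not any(w.contains(ev.timestamp) for w in nest_windows):
                report.add(
                    nest_id,
                    "outside-window",
                    True,
                    f"event at {ev.timestamp} outside every monitoring window",
                    ev.timestamp,
                )
        seen_instants: dict[tuple, str] = {}
        for ev in evs:
            key = (ev.actor, ev.timestamp)
            if key in seen_instants:
                report.add(
                    nest_id,
                    "simultaneous-events",
                    True,
                    f"{ev.actor} has two events at {ev.timestamp}",
                    ev.timestamp,
                )
            seen_instants[key] = ev.transition

        for w in nest_windows:
            in_win = [ev for ev in evs if w.contains(ev.timestamp)]
            on = {FEMALE: False, MALE: False}
            try:
                init = infer_initial_on(in_win, w)
            except ValidationError as exc:
                report.add(nest_id, "double-open-start", True, str(exc), w.start)
                init = None
            if init is not None:
                on[init] = True
                report.add(
                    nest_id,
                    "open-start",
                    False,
                    f"{init} assumed on nest from window start {w.start}",
                    w.start,
                )
            for ev in in_win:
                other = MALE if ev.actor == FEMALE else FEMALE
                if ev.transition == ARRIVAL:
                    if on[ev.actor]:
                        report.add(
                            nest_id,
                            "double-arrival",
                            True,
                            f"{ev.actor} arrival at {ev.timestamp} while already on nest",
                            ev.timestamp,
                        )
                    if on[other]:
                        report.add(
                            nest_id,
                            "overlap",
                            True,
                            f"{ev.actor} arrival at {ev.timestamp} while {other} on nest",
                            ev.timestamp,
                        )
                    on[ev.actor] = True
                else:
                    if not on[ev.actor]:
                        report.add(
                            nest_id,
                            "double-departure",
                            True,
                            f"{ev.actor} departure at {ev.timestamp} with no "
                            "prior arrival",
                            ev.timestamp,
                        )
                    on[ev.actor] = False
    return report
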