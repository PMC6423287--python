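"""Segmentation of validated event streams into bouts, gaps, and recesses.

An *incubation bout* is the total time a nest is allocated to one parent:
from that parent's arrival until its last departure before the partner takes
over.  Off-nest periods of the owner inside a bout are *recesses* (the bout
keeps running through them — there is no maximum recess length, since single
female bouts can span nearly two days).  The interval between one parent's
final departure and the partner's arrival is an *exchange gap*, attributed
to ("preceding") the arriving parent's bout.

Conventions:

* intervals are half-open ``[start, end)``; durations integer seconds;
* a window that starts (ends) with a parent sitting yields an open-start
  (open-end) bout flagged ``complete=False``;
* a bout is complete only when both of its boundaries are observed partner
  exchanges inside one monitoring window;
* a gap cut by a window edge has unknown true length → ``complete=False``;
* a departure and partner arrival in the same second produce a recorded
  0-second gap, which downstream length analyses drop (log-scale models);
* events flagged uncertain or observer-disturbance do not delete anything;
  they taint the enclosing bout, and tainted bouts plus their adjacent gaps
  are moved aside by :func:`apply_quality_exclusions`.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import (
    ARRIVAL,
    DEPARTURE,
    FEMALE,
    MALE,
    EventRecord,
    MonitoringWindow,
    infer_initial_on,
)

__all__ = [
    "Bout",
    "ExchangeGap",
    "Recess",
    "SegmentationError",
    "Segmentation",
    "per_second_state",
    "segment_window",
    "segment_nest",
    "apply_quality_exclusions",
]

STATE_NOBODY = 0
STATE_FEMALE = 1
STATE_MALE = 2


class SegmentationError(ValueError):
    """Raised when the stream is not segmentable; run validate_events first."""


@dataclass(frozen=True)
class Recess:
    nest_id: str
    sex: str
    start: dt.datetime
    end: dt.datetime

    @property
    def seconds(self) -> int:
        return int((self.end - self.start).total_seconds())


@dataclass(frozen=True)
class Bout:
    nest_id: str
    sex: str
    start: dt.datetime
    end: dt.datetime
    recesses: tuple = ()
    complete: bool = True
    tainted: bool = False
    open_start: bool = False
    open_end: bool = False

    @property
    def seconds(self) -> int:
        return int((self.end - self.start).total_seconds())

    @property
    def recess_seconds(self) -> int:
        return sum(r.seconds for r in self.recesses)

    @property
    def attended_seconds(self) -> int:
        return self.seconds - self.recess_seconds


@dataclass(frozen=True)
class ExchangeGap:
    nest_id: str
    start: dt.datetime
    end: dt.datetime
    precedes_sex: Optional[str]  # sex of the arriving parent, if observed
    complete: bool = True
    tainted: bool = False

    @property
    def seconds(self) -> int:
        return int((self.end - self.start).total_seconds())


@dataclass
class Segmentation:
    """Segmented output for one nest (possibly many windows)."""

    bouts: list[Bout] = field(default_factory=list)
    gaps: list[ExchangeGap] = field(default_factory=list)

    @property
    def recesses(self) -> list[Recess]:
        return [r for b in self.bouts for r in b.recesses]


@dataclass(frozen=True)
class _Session:
    """One continuous on-nest sit of one parent (internal)."""

    sex: str
    start: dt.datetime
    end: dt.datetime
    flagged: bool
    open_start: bool
    open_end: bool


def _build_sessions(
    events: Sequence[EventRecord],
    window: MonitoringWindow,
    initial_on: Optional[str],
) -> list[_Session]:
    in_win = sorted(
        (ev for ev in events if window.contains(ev.timestamp)),
        key=lambda e: (e.timestamp, e.transition == ARRIVAL),
    )
    on_since: dict[str, Optional[dt.datetime]] = {FEMALE: None, MALE: None}
    open_flags: dict[str, bool] = {FEMALE: False, MALE: False}
    flagged: dict[str, bool] = {FEMALE: False, MALE: False}
    if initial_on is not None:
        on_since[initial_on] = window.start
        open_flags[initial_on] = True
    sessions: list[_Session] = []

    def close(sex: str, end: dt.datetime, open_end: bool) -> None:
        start = on_since[sex]
        assert start is not None
        if end < start:
            raise SegmentationError(f"negative session for {sex} ending {end}")
        prev = sessions[-1] if sessions else None
        if (
            prev is not None
            and prev.sex == sex
            and prev.end == start
            and not open_end
        ):
            # zero-length recess: departure and re-arrival in the same second
            sessions[-1] = _Session(
                sex, prev.start, end, prev.flagged or flagged[sex],
                prev.open_start, open_end,
            )
        else:
            sessions.append(
                _Session(sex, start, end, flagged[sex], open_flags[sex], open_end)
            )
        on_since[sex] = None
        open_flags[sex] = False
        flagged[sex] = False

    for ev in in_win:
        other = MALE if ev.actor == FEMALE else FEMALE
        if ev.transition == ARRIVAL:
            if on_since[ev.actor] is not None or on_since[other] is not None:
                raise SegmentationError(
                    f"nest {window.nest_id}: arrival at {ev.timestamp} while a "
                    "parent is on the nest; run validate_events"
                )
            on_since[ev.actor] = ev.timestamp
            flagged[ev.actor] = ev.flagged
        else:
            if on_since[ev.actor] is None:
                raise SegmentationError(
                    f"nest {window.nest_id}: departure at {ev.timestamp} with no "
                    "prior arrival; run validate_events"
                )
            flagged[ev.actor] = flagged[ev.actor] or ev.flagged
            close(ev.actor, ev.timestamp, open_end=False)
    for sex in (FEMALE, MALE):
        if on_since[sex] is not None:
            close(sex, window.end, open_end=True)
    sessions.sort(key=lambda s: s.start)
    for a, b in zip(sessions, sessions[1:]):
        if b.start < a.end:
            raise SegmentationError(
                f"nest {window.nest_id}: overlapping sessions at {b.start}"
            )
    return [s for s in sessions if s.end > s.start]


def segment_window(
    events: Sequence[EventRecord],
    window: MonitoringWindow,
    initial_on: Optional[str] = None,
    infer_open_start: bool = True,
) -> Segmentation:
    """Segment one monitoring window into bouts and exchange gaps.

    ``initial_on`` names the parent sitting at window start, if known from
    outside the stream; otherwise it is inferred from a departure-first
    event pattern (open-start convention).
    """
    if initial_on is None and infer_open_start:
        initial_on = infer_initial_on(events, window)
    sessions = _build_sessions(events, window, initial_on)
    nest = window.nest_id
    seg = Segmentation()
    if not sessions:
        # nobody observed on the nest: the whole window is an unattributed,
        # edge-cut gap (unknown parents on both sides)
        seg.gaps.append(
            ExchangeGap(nest, window.start, window.end, None, complete=False)
        )
        return seg

    # group consecutive same-sex sessions into bouts
    groups: list[list[_Session]] = [[sessions[0]]]
    for s in sessions[1:]:
        if s.sex == groups[-1][-1].sex:
            groups[-1].append(s)
        else:
            groups.append([s])

    bouts: list[Bout] = []
    for g in groups:
        recesses = tuple(
            Recess(nest, g[0].sex, a.end, b.start) for a, b in zip(g, g[1:])
        )
        bouts.append(
            Bout(
                nest_id=nest,
                sex=g[0].sex,
                start=g[0].start,
                end=g[-1].end,
                recesses=recesses,
                complete=False,  # fixed below
                tainted=any(s.flagged for s in g),
                open_start=g[0].open_start,
                open_end=g[-1].open_end,
            )
        )

    gaps: list[ExchangeGap] = []
    if bouts[0].start > window.start:
        gaps.append(
            ExchangeGap(
                nest, window.start, bouts[0].start, bouts[0].sex, complete=False
            )
        )
    for a, b in zip(bouts, bouts[1:]):
        gaps.append(
            ExchangeGap(
                nest,
                a.end,
                b.start,
                b.sex,
                complete=True,
                tainted=a.tainted or b.tainted,
            )
        )
    if bouts[-1].end < window.end:
        gaps.append(
            ExchangeGap(nest, bouts[-1].end, window.end, None, complete=False)
        )

    final: list[Bout] = []
    for i, b in enumerate(bouts):
        has_prev = i > 0 and not b.open_start
        has_next = i < len(bouts) - 1 and not b.open_end
        complete = has_prev and has_next
        final.append(
            Bout(
                b.nest_id, b.sex, b.start, b.end, b.recesses,
                complete=complete, tainted=b.tainted,
                open_start=b.open_start, open_end=b.open_end,
            )
        )
    seg.bouts = final
    seg.gaps = gaps
    return seg


def segment_nest(
    events: Sequence[EventRecord],
    windows: Sequence[MonitoringWindow],
    initial_on: Optional[dict] = None,
) -> Segmentation:
    """Segment all monitoring windows of one nest.

    ``initial_on`` optionally maps window start instants to the sex sitting
    at that instant (for windows with no events at all).  Events falling
    outside every window are an error: run validate_events first.
    """
    windows = sorted(windows)
    for ev in events:
        if not any(w.contains(ev.timestamp) for w in windows):
            raise SegmentationError(
                f"event at {ev.timestamp} outside every monitoring window; "
                "run validate_events"
            )
    seg = Segmentation()
    for w in windows:
        hint = (initial_on or {}).get(w.start)
        part = segment_window(events, w, initial_on=hint)
        seg.bouts.extend(part.bouts)
        seg.gaps.extend(part.gaps)
    return seg


def apply_quality_exclusions(seg: Segmentation) -> tuple[Segmentation, Segmentation]:
    """Split a segmentation into (kept, excluded) by quality taint.

    Tainted bouts are excluded, together with the gaps adjacent to them
    (their true context is unreliable) and any gap tainted by a flagged
    boundary event.  Excluded time must be subtracted from observed-time
    denominators downstream.
    """
    tainted_edges = set()
    for b in seg.bouts:
        if b.tainted:
            tainted_edges.add((b.nest_id, b.start))
            tainted_edges.add((b.nest_id, b.end))
    kept, excluded = Segmentation(), Segmentation()
    for b in seg.bouts:
        (excluded if b.tainted else kept).bouts.append(b)
    for g in seg.gaps:
        adjacent = (g.nest_id, g.end) in tainted_edges or (
            g.nest_id,
            g.start,
        ) in tainted_edges
        (excluded if (g.tainted or adjacent) else kept).gaps.append(g)
    return kept, excluded


def per_second_state(
    events: Sequence[EventRecord],
    window: MonitoringWindow,
    initial_on: Optional[str] = None,
    infer_open_start: bool = True,
) -> np.ndarray:
    """Brute-force per-second nest state over a window (test oracle).

    Returns an int8 array of length ``window.seconds`` with values
    0 = nobody on, 1 = female on, 2 = male on.  Implemented as a direct
    state walk over the raw events, independently of the bout-merging
    segmentation logic.
    """
    if initial_on is None and infer_open_start:
        initial_on = infer_initial_on(events, window)
    n = window.seconds
    state = np.zeros(n, dtype=np.int8)
    t0 = window.start
    cur = STATE_NOBODY
    if initial_on == FEMALE:
        cur = STATE_FEMALE
    elif initial_on == MALE:
        cur = STATE_MALE
    pos = 0
    in_win = sorted(
        (ev for ev in events if window.contains(ev.timestamp)),
        key=lambda e: (e.timestamp, e.transition == ARRIVAL),
    )
    for ev in in_win:
        idx = int((ev.timestamp - t0).total_seconds())
        state[pos:idx] = cur
        if ev.transition == ARRIVAL:
            if cur != STATE_NOBODY:
                raise SegmentationError("overlap state in per_second_state")
            cur = STATE_FEMALE if ev.actor == FEMALE else STATE_MALE
        else:
            expected = STATE_FEMALE if ev.actor == FEMALE else STATE_MALE
            if cur != expected:
                raise SegmentationError("departure without matching state")
            cur = STATE_NOBODY
        pos = idx
    state[pos:n] = cur
    return state
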