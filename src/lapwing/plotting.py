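"""Actogram rendering: one row per day, a 24-h ribbon coloured by state."""

from __future__ import annotations

import datetime as dt
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Patch

from . import solar
from .io import FEMALE, MALE, MonitoringWindow, NestMetadata
from .segmentation import Segmentation

STATE_COLOURS = {
    "female": "#c23b3b",
    "male": "#3b6ec2",
    "recess_female": "#ecb7b7",
    "recess_male": "#b7c9ec",
    "gap": "#e8d44d",
    "unmonitored": "#d9d9d9",
}


def _epoch(t: dt.datetime) -> int:
    return int(t.timestamp())


def _clip(iv, lo, hi):
    s, e = max(iv[0], lo), min(iv[1], hi)
    return (s, e) if e > s else None


def actogram_day_segments(
    kept: Segmentation,
    excluded: Segmentation,
    windows: Sequence[MonitoringWindow],
    metadata: NestMetadata,
) -> dict:
    """Per-day state segments (seconds-from-midnight) used for rendering.

    Returns {date: [(state, start_s, end_s), ...]}; segment totals per state
    match the daily attendance decomposition, which tests exploit as a
    cross-total check.
    """
    tz = metadata.tz
    if not windows:
        raise ValueError(f"nest {metadata.nest_id}: no monitoring data")
    pieces = []  # (state, start_epoch, end_epoch)
    for b in kept.bouts + excluded.bouts:
        cursor = _epoch(b.start)
        for r in b.recesses:
            pieces.append((b.sex, cursor, _epoch(r.start)))
            pieces.append((f"recess_{b.sex}", _epoch(r.start), _epoch(r.end)))
            cursor = _epoch(r.end)
        pieces.append((b.sex, cursor, _epoch(b.end)))
    for g in kept.gaps + excluded.gaps:
        pieces.append(("gap", _epoch(g.start), _epoch(g.end)))

    lo = min(w.start for w in windows).astimezone(tz)
    hi = max(w.end for w in windows).astimezone(tz)
    win_ivs = [(_epoch(w.start), _epoch(w.end)) for w in windows]

    out: dict = {}
    day = lo.replace(hour=0, minute=0, second=0)
    while day < hi:
        d0, d1 = _epoch(day), _epoch(day) + 86400
        segs = []
        for state, s, e in pieces:
            c = _clip((s, e), d0, d1)
            if c:
                segs.append((state, c[0] - d0, c[1] - d0))
        covered = sorted((s, e) for _, s, e in segs)
        cursor = 0
        monitored = [
            c for w in win_ivs if (c := _clip(w, d0, d1)) is not None
        ]
        # unmonitored = day minus monitoring windows
        mcur = 0
        for s, e in sorted(monitored):
            if s - d0 > mcur:
                segs.append(("unmonitored", mcur, s - d0))
            mcur = max(mcur, e - d0)
        if mcur < 86400:
            segs.append(("unmonitored", mcur, 86400))
        out[day.date()] = sorted(segs, key=lambda x: x[1])
        day += dt.timedelta(days=1)
    return out


def render_actogram(
    kept: Segmentation,
    excluded: Segmentation,
    windows: Sequence[MonitoringWindow],
    metadata: NestMetadata,
    path,
) -> None:
    """Render the nest's actogram to ``path`` (night span shaded)."""
    segments = actogram_day_segments(kept, excluded, windows, metadata)
    ctx = solar.SolarContext(metadata.latitude, metadata.longitude, metadata.utc_offset)
    days = sorted(segments)
    fig, ax = plt.subplots(figsize=(10, 0.6 + 0.35 * len(days)))
    for row, day in enumerate(days):
        night = solar.night_for_evening(ctx, day - dt.timedelta(days=1))
        for n in (night, solar.night_for_evening(ctx, day)):
            if n is None:
                continue
            d0 = dt.datetime.combine(day, dt.time(0), tzinfo=metadata.tz)
            s = max(0.0, (n.start - d0).total_seconds() / 3600.0)
            e = min(24.0, (n.end - d0).total_seconds() / 3600.0)
            if e > s:
                ax.axhspan(row - 0.5, row + 0.5, s / 24.0, e / 24.0,
                           color="#00000018", zorder=0)
        for state, s, e in segments[day]:
            ax.broken_barh(
                [(s / 3600.0, (e - s) / 3600.0)],
                (row - 0.4, 0.8),
                facecolors=STATE_COLOURS[state],
                zorder=1,
            )
    ax.set_xlim(0, 24)
    ax.set_ylim(len(days) - 0.5, -0.5)
    ax.set_yticks(range(len(days)))
    ax.set_yticklabels([d.isoformat() for d in days], fontsize=7)
    ax.set_xticks(range(0, 25, 2))
    ax.set_xlabel("local time (h)")
    ax.set_title(f"Nest {metadata.nest_id}")
    ax.legend(
        handles=[Patch(color=c, label=s) for s, c in STATE_COLOURS.items()],
        loc="upper right", fontsize=6, ncol=3,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
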