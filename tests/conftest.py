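"""Shared fixtures: randomized valid event streams and small simulated studies."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from lapwing.io import (
    ARRIVAL,
    DEPARTURE,
    FEMALE,
    MALE,
    EventRecord,
    MonitoringWindow,
)

TZ = dt.timezone(dt.timedelta(hours=2))
T0 = dt.datetime(2015, 4, 20, 8, 0, 0, tzinfo=TZ)


def random_stream(rng: np.random.Generator, nest_id: str = "N1"):
    """One random, structurally valid (events, window) pair.

    Covers open-start/open-end truncation, uniparental streams, zero-second
    exchanges, recess-heavy runs, and taint flags.  The walk is a strict
    one-incubator state machine, so validation finds no fatal violations.
    """
    length = int(rng.integers(1800, 6 * 3600))
    start = T0 + dt.timedelta(seconds=int(rng.integers(0, 86400)))
    window = MonitoringWindow(nest_id, start, start + dt.timedelta(seconds=length))
    uniparental = rng.random() < 0.15
    state = rng.choice(["nobody", FEMALE, MALE if not uniparental else FEMALE])
    events = []
    t = 0
    last_sex = None
    while True:
        dur = int(rng.integers(1, 2400))
        t_next = t + dur
        if t_next >= length:
            break
        flagged = rng.random() < 0.05
        kw = dict(
            uncertain=flagged and rng.random() < 0.5,
            observer_disturbance=flagged and rng.random() >= 0.5,
        )
        ts = window.start + dt.timedelta(seconds=t_next)
        if state == "nobody":
            if uniparental:
                sex = FEMALE
            elif last_sex is not None and rng.random() < 0.3:
                # zero-or-short gap exchange to the partner
                sex = FEMALE if last_sex == MALE else MALE
            else:
                sex = rng.choice([FEMALE, MALE])
            events.append(EventRecord(nest_id, ts, sex, ARRIVAL, **kw))
            state = sex
        else:
            events.append(EventRecord(nest_id, ts, state, DEPARTURE, **kw))
            last_sex = state
            state = "nobody"
            if rng.random() < 0.25:  # same-second partner arrival (0-s gap)
                sex = FEMALE if last_sex == MALE else MALE
                if not uniparental:
                    events.append(EventRecord(nest_id, ts, sex, ARRIVAL))
                    state = sex
        t = t_next
    return events, window


@pytest.fixture(scope="session")
def small_study():
    """A 6-nest simulated study reused by pipeline-level tests."""
    from lapwing import synthetic

    cfg = synthetic.SimulationConfig(
        n_nests=6, monitoring_days_range=(2, 4), seed=11
    )
    return synthetic.simulate_study(cfg)
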