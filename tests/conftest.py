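"""Shared fixtures and independent naive oracles.

The oracles here deliberately avoid numpy vectorisation and any code path
shared with the package: they are plain-Python scan-and-count references
against which the implementation is checked.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from flysleep.dam_io import BeamCountSeries


def naive_episodes(counts, min_bout=5):
    """Independent scan: (start, duration) of every zero run >= min_bout."""
    episodes = []
    run_start = None
    for i, c in enumerate(list(counts) + [1]):  # sentinel terminates a trailing run
        if c == 0:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None:
                length = i - run_start
                if length >= min_bout:
                    episodes.append((run_start, length))
                run_start = None
    return episodes


def naive_sleep_params(counts, min_bout=5):
    """Independent tally of the seven parameters for a ZT0-aligned day.

    Walks episode minute lists directly; splits boundary-spanning episodes
    at ZT720 and counts the clipped segment as a bout in each phase.
    """
    assert len(counts) == 1440
    episodes = naive_episodes(counts, min_bout)
    sleep_minutes = set()
    day_bouts = night_bouts = 0
    for start, length in episodes:
        minutes = list(range(start, start + length))
        sleep_minutes.update(minutes)
        if any(m < 720 for m in minutes):
            day_bouts += 1
        if any(m >= 720 for m in minutes):
            night_bouts += 1
    day_sleep = sum(1 for m in sleep_minutes if m < 720)
    night_sleep = sum(1 for m in sleep_minutes if m >= 720)
    day_counts = sum(int(c) for c in counts[:720])
    night_counts = sum(int(c) for c in counts[720:])
    day_wake = 720 - day_sleep
    night_wake = 720 - night_sleep
    profile = [sum(1 for m in sleep_minutes if b * 30 <= m < (b + 1) * 30) for b in range(48)]
    return {
        "day_sleep": day_sleep,
        "night_sleep": night_sleep,
        "day_bout_count": day_bouts,
        "night_bout_count": night_bouts,
        "day_bout_len": day_sleep / day_bouts if day_bouts else 0.0,
        "night_bout_len": night_sleep / night_bouts if night_bouts else 0.0,
        "day_waking_activity": day_counts / day_wake if day_wake else math.nan,
        "night_waking_activity": night_counts / night_wake if night_wake else math.nan,
        "profile": profile,
    }


def make_series(counts, start_zt=0):
    return BeamCountSeries(counts=np.asarray(counts, dtype=np.int64), start_zt=start_zt)


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture
def random_day_series(rng):
    """A batch of random 1440-min series with sleep-like zero-run structure."""
    out = []
    for _ in range(50):
        # mixture: raw binary noise and blocky runs, to exercise run edges
        if rng.random() < 0.5:
            counts = (rng.random(1440) < rng.uniform(0.2, 0.8)).astype(np.int64)
        else:
            counts = np.zeros(1440, dtype=np.int64)
            pos = 0
            while pos < 1440:
                run = int(rng.integers(1, 40))
                if rng.random() < 0.5:
                    counts[pos : pos + run] = rng.poisson(2.0, size=min(run, 1440 - pos))
                pos += run
        out.append(counts)
    return out
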