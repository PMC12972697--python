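"""Sleep scoring from per-minute beam-cross counts.

Fly sleep is operationally defined as any period of complete immobility
(zero beam crossings) lasting at least five consecutive minutes.  From the
scored episodes this module derives the standard per-fly parameters over one
24 h day: total day and night sleep, bout counts, mean bout length per
phase, waking activity (beam crosses per waking minute) per phase, and the
48-bin (30 min) sleep profile.

Day is ZT [0, 720) and night ZT [720, 1440).  Episodes that span the
lights-off boundary are split there: their minutes are apportioned to each
phase and the clipped segment counts as one bout in each phase it overlaps,
which keeps "phase sleep minutes / phase bout count" self-consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from flysleep.dam_io import MINUTES_PER_DAY, BeamCountSeries

DEFAULT_MIN_BOUT_MIN = 5
DAY_MINUTES = 720


@dataclass(frozen=True)
class SleepEpisode:
    """A maximal run of immobile minutes meeting the bout-length threshold."""

    start_zt_min: int
    duration_min: int

    @property
    def end_zt_min(self) -> int:
        """Exclusive end, ZT minutes."""
        return self.start_zt_min + self.duration_min


@dataclass
class FlySleepParams:
    """The per-fly sleep and activity parameters over one 24 h day.

    ``day_waking_activity`` / ``night_waking_activity`` are NaN when the fly
    slept through the whole phase (zero waking minutes): beam crosses per
    waking minute is undefined there, and such flies are excluded from that
    parameter's statistics only.
    """

    day_sleep_min: int
    night_sleep_min: int
    day_bout_count: int
    night_bout_count: int
    day_bout_len: float
    night_bout_len: float
    day_waking_activity: float
    night_waking_activity: float
    profile_30min: np.ndarray  # 48 values, minutes asleep per 30-min bin

    @property
    def total_sleep_min(self) -> int:
        return self.day_sleep_min + self.night_sleep_min


def _zero_runs(counts: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of every maximal run of zeros, in order."""
    immobile = np.asarray(counts) == 0
    if not immobile.any():
        return []
    padded = np.concatenate(([False], immobile, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), (ends - starts).tolist()))


def detect_sleep_episodes(
    series: BeamCountSeries, min_bout_min: int = DEFAULT_MIN_BOUT_MIN
) -> list[SleepEpisode]:
    """Score sleep episodes: maximal zero-count runs of length >= ``min_bout_min``.

    Runs shorter than the threshold contribute nothing.  Episodes truncated
    by the window edges are scored from the observed minutes only.
    """
    if len(series) < 1:
        raise ValueError("series must contain at least one minute")
    if min_bout_min < 1:
        raise ValueError("min_bout_min must be >= 1")
    return [
        SleepEpisode(start_zt_min=series.start_zt + start, duration_min=length)
        for start, length in _zero_runs(series.counts)
        if length >= min_bout_min
    ]


def _sleep_mask(series: BeamCountSeries, min_bout_min: int) -> np.ndarray:
    """Boolean per-minute mask of scored sleep (index space, not ZT)."""
    mask = np.zeros(len(series), dtype=bool)
    for start, length in _zero_runs(series.counts):
        if length >= min_bout_min:
            mask[start : start + length] = True
    return mask


def _require_full_day(series: BeamCountSeries) -> None:
    if len(series) != MINUTES_PER_DAY:
        raise ValueError(f"series must cover exactly {MINUTES_PER_DAY} minutes, got {len(series)}")
    if series.start_zt != 0:
        raise ValueError(f"series must start at ZT0, starts at ZT{series.start_zt}")


def compute_sleep_params(
    series: BeamCountSeries, min_bout_min: int = DEFAULT_MIN_BOUT_MIN
) -> FlySleepParams:
    """Compute the seven per-fly parameters plus the 30-min profile.

    Requires a ZT0-aligned 24 h series.  Waking activity for a phase is the
    sum of beam crosses in that phase divided by its waking minutes; the
    numerator only draws from waking minutes since scored-sleep minutes have
    zero counts by construction.
    """
    _require_full_day(series)
    episodes = detect_sleep_episodes(series, min_bout_min)
    counts = series.counts

    day_sleep = night_sleep = 0
    day_bouts = night_bouts = 0
    for ep in episodes:
        day_part = max(0, min(ep.end_zt_min, DAY_MINUTES) - ep.start_zt_min)
        night_part = ep.duration_min - day_part
        day_sleep += day_part
        night_sleep += night_part
        if day_part > 0:
            day_bouts += 1
        if night_part > 0:
            night_bouts += 1

    day_counts = int(counts[:DAY_MINUTES].sum())
    night_counts = int(counts[DAY_MINUTES:].sum())
    day_wake = DAY_MINUTES - day_sleep
    night_wake = DAY_MINUTES - night_sleep

    return FlySleepParams(
        day_sleep_min=day_sleep,
        night_sleep_min=night_sleep,
        day_bout_count=day_bouts,
        night_bout_count=night_bouts,
        day_bout_len=day_sleep / day_bouts if day_bouts else 0.0,
        night_bout_len=night_sleep / night_bouts if night_bouts else 0.0,
        day_waking_activity=day_counts / day_wake if day_wake else math.nan,
        night_waking_activity=night_counts / night_wake if night_wake else math.nan,
        profile_30min=sleep_profile(series, min_bout_min),
    )


def sleep_profile(
    series: BeamCountSeries,
    min_bout_min: int = DEFAULT_MIN_BOUT_MIN,
    bin_min: int = 30,
) -> np.ndarray:
    """Minutes of scored sleep per ``bin_min``-minute bin across 24 hours."""
    _require_full_day(series)
    if MINUTES_PER_DAY % bin_min != 0:
        raise ValueError(f"bin_min must divide {MINUTES_PER_DAY}, got {bin_min}")
    mask = _sleep_mask(series, min_bout_min)
    return mask.reshape(-1, bin_min).sum(axis=1)


def flag_inactive_fly(series: BeamCountSeries, tail_hours: float = 6.0) -> bool:
    """True iff the fly registered no beam crossing over the final ``tail_hours``.

    A standard guard against scoring a dead or escaped fly as asleep; it is
    up to the caller (pipeline config) whether flagged flies are excluded.
    """
    tail_min = int(round(tail_hours * 60))
    if len(series) < tail_min:
        raise ValueError(f"series shorter than tail window ({len(series)} < {tail_min} min)")
    return int(series.counts[-tail_min:].sum()) == 0
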