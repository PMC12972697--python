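"""Synthetic DAM and ERG data with known ground truth.

Fly locomotion is emulated as a two-state (wake/sleep) Markov chain at
one-minute resolution whose transition probabilities may vary with
Zeitgeber time, so a circadian structure — midday siesta, consolidated
night sleep — is encoded as ZT-dependent rates.  While awake the fly
produces Poisson-distributed beam crossings; asleep it produces none.

For constant rates the scored-sleep fraction has a closed form: with
wake-to-sleep probability ``p_on`` and sleep-to-wake probability ``p_off``
per minute, sleep-state run lengths are Geometric(``p_off``), the stationary
sleep probability is ``pi = p_on / (p_on + p_off)``, and runs shorter than
the bout threshold ``m`` are discarded, giving

    fraction = pi * E[L * 1(L >= m)] / E[L] = pi * q**(m-1) * (m*p_off + q)

with ``q = 1 - p_off``.  This is the oracle for parameter-recovery tests.
It describes the latent state; the scored fraction additionally picks up
the occasional zero-count waking minute adjacent to a sleep run, a bias
that is negligible once the waking Poisson rate is high enough for zero
counts to be rare.

ERG sweeps are built from the canonical waveform: a baseline, a sustained
(plateau) potential while the stimulus is on — persisting through the
short post-offset analysis window, as the real receptor potential decays
over seconds — plus exponentially decaying on- and off-transient spikes
and additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from flysleep.dam_io import (
    MINUTES_PER_DAY,
    N_CHANNELS,
    BeamCountSeries,
    MonitorRecord,
    MonitorRecordSet,
    write_monitor_file,
)
from flysleep.erg_quant import STANDARD_INTENSITIES, ERGTrace

#: Default ZT block boundaries (minutes) and per-minute transition rates for
#: a control male fly: light morning/evening activity around a midday
#: siesta, and consolidated night sleep.  These rates put expected day sleep
#: in the 300-400 min band typical of virgin males.
DEFAULT_BLOCKS = (
    (0, 180, 0.02, 0.10),  # morning: mostly active
    (180, 540, 0.10, 0.03),  # midday siesta
    (540, 720, 0.02, 0.10),  # evening activity
    (720, 1440, 0.15, 0.01),  # night: long consolidated sleep
)


def step_rates(blocks: Sequence[tuple[int, int, float, float]]) -> tuple[np.ndarray, np.ndarray]:
    """Expand (zt_start, zt_end, p_sleep_onset, p_wake_onset) blocks to per-minute arrays."""
    p_on = np.full(MINUTES_PER_DAY, np.nan)
    p_off = np.full(MINUTES_PER_DAY, np.nan)
    for zt0, zt1, on, off in blocks:
        p_on[zt0:zt1] = on
        p_off[zt0:zt1] = off
    if np.isnan(p_on).any():
        raise ValueError("blocks must cover all 1440 ZT minutes")
    return p_on, p_off


@dataclass
class FlyModelParams:
    """Two-state Markov model of one fly's sleep–wake behaviour.

    ``p_sleep_onset`` / ``p_wake_onset`` are per-minute transition
    probabilities, either scalars (constant-rate regime, where the analytic
    sleep-fraction oracle applies) or length-1440 arrays over ZT.
    ``wake_rate`` is the mean beam crosses per waking minute (Poisson).
    ``death_zt`` optionally silences the fly from that absolute minute on.
    """

    p_sleep_onset: float | np.ndarray | None = None
    p_wake_onset: float | np.ndarray | None = None
    wake_rate: float = 4.0
    death_zt: int | None = None
    genotype: str = ""

    def __post_init__(self) -> None:
        if self.p_sleep_onset is None or self.p_wake_onset is None:
            p_on, p_off = step_rates(DEFAULT_BLOCKS)
            if self.p_sleep_onset is None:
                self.p_sleep_onset = p_on
            if self.p_wake_onset is None:
                self.p_wake_onset = p_off
        if self.wake_rate <= 0:
            raise ValueError("wake_rate must be positive")
        for name in ("p_sleep_onset", "p_wake_onset"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"{name} must lie in [0, 1]")

    def rates_by_minute(self) -> tuple[np.ndarray, np.ndarray]:
        p_on = np.broadcast_to(np.asarray(self.p_sleep_onset, float), (MINUTES_PER_DAY,))
        p_off = np.broadcast_to(np.asarray(self.p_wake_onset, float), (MINUTES_PER_DAY,))
        return p_on, p_off

    def scaled(self, *, sleep_onset: float = 1.0, wake_onset: float = 1.0,
               wake_rate: float = 1.0, genotype: str | None = None) -> "FlyModelParams":
        """A mutant variant with multiplicatively scaled rates (clipped to [0, 1])."""
        p_on, p_off = self.rates_by_minute()
        return FlyModelParams(
            p_sleep_onset=np.clip(np.array(p_on) * sleep_onset, 0.0, 1.0),
            p_wake_onset=np.clip(np.array(p_off) * wake_onset, 0.0, 1.0),
            wake_rate=self.wake_rate * wake_rate,
            death_zt=self.death_zt,
            genotype=self.genotype if genotype is None else genotype,
        )


def simulate_fly_activity(
    params: FlyModelParams,
    days: int = 1,
    seed: int | np.random.Generator = 0,
) -> BeamCountSeries:
    """Simulate one fly's per-minute beam-cross counts over ``days`` LD days."""
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_on, p_off = params.rates_by_minute()
    n = days * MINUTES_PER_DAY
    u = rng.random(n)
    # initial state from the stationary probability at ZT0
    pi0 = p_on[0] / (p_on[0] + p_off[0]) if (p_on[0] + p_off[0]) > 0 else 0.0
    asleep = rng.random() < pi0
    sleep_state = np.empty(n, dtype=bool)
    for t in range(n):
        zt = t % MINUTES_PER_DAY
        if asleep:
            if u[t] < p_off[zt]:
                asleep = False
        else:
            if u[t] < p_on[zt]:
                asleep = True
        sleep_state[t] = asleep
    counts = np.where(sleep_state, 0, rng.poisson(params.wake_rate, size=n))
    if params.death_zt is not None:
        counts[params.death_zt:] = 0
    return BeamCountSeries(counts=counts, start_zt=0, genotype=params.genotype)


def expected_scored_sleep_fraction(p_on: float, p_off: float, min_bout: int = 5) -> float:
    """Closed-form long-run scored-sleep fraction for constant transition rates.

    Returns ``pi * q**(m-1) * (m*p_off + q)`` with ``pi = p_on/(p_on+p_off)``
    and ``q = 1 - p_off`` — the stationary sleep fraction retained after
    discarding sleep runs shorter than ``min_bout`` minutes.
    """
    if not (0 < p_on <= 1) or not (0 < p_off <= 1):
        raise ValueError("rates must lie in (0, 1]")
    pi = p_on / (p_on + p_off)
    q = 1.0 - p_off
    return pi * q ** (min_bout - 1) * (min_bout * p_off + q)


@dataclass
class ExperimentTruth:
    """Generated monitor files plus the ground truth behind them."""

    monitor_files: list[Path]
    channel_map: pd.DataFrame  # monitor, channel, genotype, fly_id
    truth: pd.DataFrame  # per-fly programmed parameters and realised sleep
    series: dict[tuple[str, int], BeamCountSeries]
    lights_on_clock: int
    start_date: datetime


def _series_to_records(
    all_counts: np.ndarray, start: datetime
) -> MonitorRecordSet:
    """Stack per-channel count arrays (channels x minutes) into monitor records."""
    n_minutes = all_counts.shape[1]
    rows = [
        MonitorRecord(
            record_index=i + 1,
            timestamp=start + timedelta(minutes=i),
            status=1,
            counts=tuple(int(c) for c in all_counts[:, i]),
        )
        for i in range(n_minutes)
    ]
    return MonitorRecordSet(rows=rows)


def simulate_experiment(
    genotype_map: Mapping[str, tuple[FlyModelParams, int]],
    days: int = 3,
    seed: int = 0,
    out_dir: str | Path | None = None,
    lights_on_clock: int = 480,
    start_date: datetime = datetime(2024, 1, 1),
) -> ExperimentTruth:
    """Simulate a multi-genotype DAM experiment and (optionally) write monitor files.

    Flies are assigned to 32-channel monitors in genotype order; more than
    32 flies spill into additional monitor files.  The truth table records
    each fly's programmed rates and its realised per-minute series is kept
    in memory so downstream results can be validated without re-parsing.
    """
    rng = np.random.default_rng(seed)
    flies: list[tuple[str, FlyModelParams]] = []
    for genotype, (params, n) in genotype_map.items():
        flies.extend((genotype, params) for _ in range(n))

    start = start_date.replace(hour=lights_on_clock // 60, minute=lights_on_clock % 60,
                               second=0, microsecond=0)
    monitor_files: list[Path] = []
    map_rows, truth_rows = [], []
    series: dict[tuple[str, int], BeamCountSeries] = {}
    n_minutes = days * MINUTES_PER_DAY

    for m_idx in range(0, len(flies), N_CHANNELS):
        monitor_id = f"Monitor{m_idx // N_CHANNELS + 1}"
        chunk = flies[m_idx : m_idx + N_CHANNELS]
        all_counts = np.zeros((N_CHANNELS, n_minutes), dtype=np.int64)
        for ch_idx, (genotype, params) in enumerate(chunk):
            fly_seed = int(rng.integers(0, 2**31 - 1))
            s = simulate_fly_activity(params, days=days, seed=fly_seed)
            s.monitor_id, s.channel, s.genotype = monitor_id, ch_idx + 1, genotype
            all_counts[ch_idx] = s.counts
            series[(monitor_id, ch_idx + 1)] = s
            fly_id = f"{monitor_id}_ch{ch_idx + 1:02d}"
            map_rows.append(
                {"monitor": monitor_id, "channel": ch_idx + 1, "genotype": genotype,
                 "fly_id": fly_id}
            )
            p_on, p_off = params.rates_by_minute()
            truth_rows.append(
                {
                    "fly_id": fly_id,
                    "monitor": monitor_id,
                    "channel": ch_idx + 1,
                    "genotype": genotype,
                    "seed": fly_seed,
                    "wake_rate": params.wake_rate,
                    "mean_p_sleep_onset_day": float(p_on[:720].mean()),
                    "mean_p_wake_onset_day": float(p_off[:720].mean()),
                    "mean_p_sleep_onset_night": float(p_on[720:].mean()),
                    "mean_p_wake_onset_night": float(p_off[720:].mean()),
                    "death_zt": params.death_zt if params.death_zt is not None else -1,
                }
            )
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            path = out_dir / f"{monitor_id}.txt"
            write_monitor_file(_series_to_records(all_counts, start), path)
            monitor_files.append(path)

    channel_map = pd.DataFrame(map_rows)
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        channel_map.to_csv(Path(out_dir) / "channel_map.csv", index=False)
        truth.to_csv(Path(out_dir) / "truth.csv", index=False)
    return ExperimentTruth(
        monitor_files=monitor_files,
        channel_map=channel_map,
        truth=truth,
        series=series,
        lights_on_clock=lights_on_clock,
        start_date=start,
    )


@dataclass
class ERGModelParams:
    """Generative model of one genotype's ERG waveform.

    ``plateau_mv`` maps stimulus intensity (W/m^2) to the sustained receptor
    potential amplitude (negative = depolarising, corneal convention);
    ``on_spike_mv`` / ``off_spike_mv`` are transient amplitudes relative to
    the plateau and to the pre-offset level respectively; ``tau_s`` is the
    transient decay constant.
    """

    baseline_mv: float = 0.0
    plateau_mv: Mapping[float, float] = field(
        default_factory=lambda: {0.004: -4.0, 0.02: -6.0, 0.1: -8.0, 0.5: -10.0}
    )
    on_spike_mv: float = -4.0
    off_spike_mv: float = 3.0
    tau_s: float = 0.03
    noise_sd_mv: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd_mv < 0:
            raise ValueError("noise_sd_mv must be >= 0")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")

    def scaled_transients(self, factor: float) -> "ERGModelParams":
        """Variant with on/off transients scaled, plateau untouched (synaptic mutant)."""
        return ERGModelParams(
            baseline_mv=self.baseline_mv,
            plateau_mv=dict(self.plateau_mv),
            on_spike_mv=self.on_spike_mv * factor,
            off_spike_mv=self.off_spike_mv * factor,
            tau_s=self.tau_s,
            noise_sd_mv=self.noise_sd_mv,
        )


def simulate_erg_trace(
    params: ERGModelParams,
    intensity: float,
    seed: int | np.random.Generator = 0,
    sample_rate: float = 2000.0,
    pre_s: float = 0.5,
    stim_s: float = 1.0,
    post_s: float = 0.5,
    fly_id: str = "",
    genotype: str = "",
    repeat_index: int = 0,
) -> ERGTrace:
    """Simulate one ERG sweep at the given stimulus intensity."""
    if intensity not in params.plateau_mv:
        raise ValueError(f"intensity {intensity} not in configured set "
                         f"{sorted(params.plateau_mv)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    onset, offset = pre_s, pre_s + stim_s
    n = int(round((pre_s + stim_s + post_s) * sample_rate))
    t = np.arange(n) / sample_rate
    v = np.full(n, params.baseline_mv)
    plateau = params.plateau_mv[intensity]
    stim_on = t >= onset
    v[stim_on] += plateau  # sustained potential; decays over seconds, flat here
    v[stim_on] += params.on_spike_mv * np.exp(-(t[stim_on] - onset) / params.tau_s)
    post = t >= offset
    v[post] += params.off_spike_mv * np.exp(-(t[post] - offset) / params.tau_s)
    if params.noise_sd_mv > 0:
        v = v + rng.normal(0.0, params.noise_sd_mv, size=n)
    return ERGTrace(
        voltage=v,
        sample_rate=sample_rate,
        stim_onset_s=onset,
        stim_offset_s=offset,
        intensity=intensity,
        fly_id=fly_id,
        genotype=genotype,
        repeat_index=repeat_index,
    )


def simulate_erg_experiment(
    genotype_map: Mapping[str, tuple[ERGModelParams, int]],
    n_repeats: int = 3,
    intensities: Sequence[float] = STANDARD_INTENSITIES,
    seed: int = 0,
) -> tuple[list[ERGTrace], pd.DataFrame]:
    """Simulate a full ERG session: each fly, each intensity, ``n_repeats`` sweeps.

    Returns the traces plus a ground-truth table of programmed component
    amplitudes per (genotype, intensity).
    """
    rng = np.random.default_rng(seed)
    traces: list[ERGTrace] = []
    truth_rows = []
    for genotype, (params, n_flies) in genotype_map.items():
        for intensity in intensities:
            truth_rows.append(
                {
                    "genotype": genotype,
                    "intensity": intensity,
                    "on_transient_mv": params.on_spike_mv,
                    "receptor_potential_mv": params.plateau_mv[intensity],
                    "off_transient_mv": params.off_spike_mv,
                }
            )
        for f in range(n_flies):
            fly_id = f"{genotype}_fly{f + 1:02d}"
            for intensity in intensities:
                for rep in range(n_repeats):
                    traces.append(
                        simulate_erg_trace(
                            params,
                            intensity,
                            seed=rng,
                            fly_id=fly_id,
                            genotype=genotype,
                            repeat_index=rep,
                        )
                    )
    return traces, pd.DataFrame(truth_rows)


def write_erg_traces(traces: Sequence[ERGTrace], out_dir: str | Path) -> Path:
    """Write traces as two-column CSVs plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for i, trace in enumerate(traces):
        name = f"trace_{i:04d}.csv"
        pd.DataFrame({"time_s": trace.time_s, "voltage_mv": trace.voltage}).to_csv(
            out_dir / name, index=False
        )
        manifest_rows.append(
            {
                "file": name,
                "fly_id": trace.fly_id,
                "genotype": trace.genotype,
                "intensity": trace.intensity,
                "repeat_index": trace.repeat_index,
                "stim_onset_s": trace.stim_onset_s,
                "stim_offset_s": trace.stim_offset_s,
                "sample_rate": trace.sample_rate,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest, index=False)
    return manifest
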