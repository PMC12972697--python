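"""Electroretinogram (ERG) component quantification.

A fly ERG to a ~1 s light flash has three canonical components: a fast
on-transient at stimulus onset (synaptic, photoreceptor-to-lamina), a
sustained receptor potential while the light is on (photoreceptor
depolarisation — negative-going at the corneal electrode), and an
off-transient at stimulus end.  This module extracts signed amplitudes for
the three components from sampled voltage traces, averages stimulus
repeats, and runs the pooled-intensity genotype comparison in which each
fly contributes one averaged value per stimulus intensity (so n equals
flies x intensities).

Measurement windows (all configurable via :class:`ComponentWindows`):
baseline is the 0.3 s before onset; the receptor potential is the plateau
mean from 0.3 s after onset to offset, relative to baseline; the
on-transient is the signed extremum in the first 0.15 s after onset
relative to the plateau level (so a transient-free trace scores 0); the
off-transient is the signed extremum in the 0.3 s after offset relative to
the mean of the last 0.1 s of the stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from flysleep.group_stats import GroupComparison, compare_parameter

#: Stimulus irradiances (W/m^2) used in the four-step intensity series.
STANDARD_INTENSITIES = (0.004, 0.02, 0.1, 0.5)

COMPONENT_NAMES = ("on_transient_mv", "receptor_potential_mv", "off_transient_mv")


@dataclass(frozen=True)
class ComponentWindows:
    """Measurement window lengths in seconds."""

    baseline_s: float = 0.3
    on_search_s: float = 0.15
    plateau_start_s: float = 0.3  # after onset
    off_search_s: float = 0.3
    pre_off_s: float = 0.1


@dataclass
class ERGTrace:
    """One sampled ERG sweep with its stimulus markers."""

    voltage: np.ndarray  # mV
    sample_rate: float  # Hz
    stim_onset_s: float
    stim_offset_s: float
    intensity: float  # W/m^2
    fly_id: str = ""
    genotype: str = ""
    repeat_index: int = 0

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.stim_offset_s <= self.stim_onset_s:
            raise ValueError("stimulus offset must follow onset")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.voltage) / self.sample_rate

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.voltage)) / self.sample_rate


@dataclass(frozen=True)
class ERGComponents:
    """Signed component amplitudes in mV.

    Sign convention: a depolarising receptor potential is negative at the
    corneal electrode; on- and off-transients keep the sign of their
    deflection relative to the local reference level.
    """

    on_transient_mv: float
    receptor_potential_mv: float
    off_transient_mv: float

    def as_dict(self) -> dict[str, float]:
        return {
            "on_transient_mv": self.on_transient_mv,
            "receptor_potential_mv": self.receptor_potential_mv,
            "off_transient_mv": self.off_transient_mv,
        }


def _window_slice(trace: ERGTrace, t0: float, t1: float) -> np.ndarray:
    """Samples with time in [t0, t1); errors if the window leaves the trace."""
    if t0 < 0 or t1 > trace.duration_s + 1e-9:
        raise ValueError(
            f"window [{t0:.3f}, {t1:.3f}) s exceeds trace extent (0, {trace.duration_s:.3f}) s"
        )
    i0 = int(np.ceil(t0 * trace.sample_rate - 1e-9))
    i1 = int(np.ceil(t1 * trace.sample_rate - 1e-9))
    if i1 <= i0:
        raise ValueError(f"window [{t0:.3f}, {t1:.3f}) s contains no samples")
    return trace.voltage[i0:i1]


def _signed_extremum(window: np.ndarray, reference: float) -> float:
    """Deviation (signed) of the sample furthest from ``reference``."""
    deviations = window - reference
    return float(deviations[np.argmax(np.abs(deviations))])


def extract_components(
    trace: ERGTrace, windows: ComponentWindows = ComponentWindows()
) -> ERGComponents:
    """Extract the three ERG component amplitudes from one sweep."""
    on, off = trace.stim_onset_s, trace.stim_offset_s
    baseline = float(np.mean(_window_slice(trace, on - windows.baseline_s, on)))
    plateau = float(np.mean(_window_slice(trace, on + windows.plateau_start_s, off)))
    on_window = _window_slice(trace, on, on + windows.on_search_s)
    pre_off = float(np.mean(_window_slice(trace, off - windows.pre_off_s, off)))
    off_window = _window_slice(trace, off, off + windows.off_search_s)
    return ERGComponents(
        on_transient_mv=_signed_extremum(on_window, plateau),
        receptor_potential_mv=plateau - baseline,
        off_transient_mv=_signed_extremum(off_window, pre_off),
    )


def average_repeats(component_table: pd.DataFrame) -> pd.DataFrame:
    """Average repeat presentations per (fly, intensity).

    ``component_table`` needs columns ``fly_id``, ``genotype``, ``intensity``
    and the three component columns; returns one row per (fly, intensity)
    with component means and an ``n_repeats`` count.
    """
    required = {"fly_id", "genotype", "intensity", *COMPONENT_NAMES}
    missing = required - set(component_table.columns)
    if missing:
        raise ValueError(f"component table missing columns: {sorted(missing)}")
    if component_table.empty:
        raise ValueError("component table is empty")
    grouped = (
        component_table.groupby(["genotype", "fly_id", "intensity"], sort=True)
        .agg(
            **{name: (name, "mean") for name in COMPONENT_NAMES},
            n_repeats=("on_transient_mv", "size"),
        )
        .reset_index()
    )
    return grouped


def components_table(traces: Iterable[ERGTrace], windows: ComponentWindows = ComponentWindows()) -> pd.DataFrame:
    """Extract components for every trace into a tidy table (one row per sweep)."""
    rows = []
    for trace in traces:
        comp = extract_components(trace, windows)
        rows.append(
            {
                "fly_id": trace.fly_id,
                "genotype": trace.genotype,
                "intensity": trace.intensity,
                "repeat_index": trace.repeat_index,
                **comp.as_dict(),
            }
        )
    return pd.DataFrame(rows)


def intensity_response_summary(per_fly: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of each component per genotype per intensity."""
    return (
        per_fly.groupby(["genotype", "intensity"], sort=True)[list(COMPONENT_NAMES)]
        .agg(["mean", "std", "count"])
        .reset_index()
    )


def pooled_genotype_compare(
    per_fly: pd.DataFrame, correct: bool | None = None
) -> list[GroupComparison]:
    """Genotype comparisons with values pooled across stimulus intensities.

    Each fly contributes its repeat-averaged value at every intensity, so a
    genotype of 3 flies measured at 4 intensities enters with n = 12.  One
    set of pairwise comparisons is produced per component; with three or
    more genotypes each component's family is Benjamini–Hochberg adjusted.
    """
    if per_fly.empty:
        raise ValueError("per-fly component table is empty")
    results: list[GroupComparison] = []
    for name in COMPONENT_NAMES:
        groups: Mapping[str, Sequence[float]] = {
            genotype: sub[name].to_numpy()
            for genotype, sub in per_fly.groupby("genotype", sort=True)
        }
        results.extend(compare_parameter(name, groups, correct=correct))
    return results
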