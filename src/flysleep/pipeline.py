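"""Config-driven orchestration of the sleep and ERG analyses.

A run configuration maps DAM monitor channels to genotypes, fixes the
protocol parameters (lights-on clock time, analysis day, immobility
threshold, exclusion policy) and points at the ERG trace manifest.  The
pipelines compose the lower-level modules and write the output tables:
a per-fly parameter table, per-genotype 30-min sleep profile means, one
statistics table per parameter family, a per-fly ERG component table, an
intensity-response summary (mean ± SD), and the pooled ERG statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from flysleep.dam_io import MINUTES_PER_DAY, extract_channel_series, parse_monitor_file
from flysleep.erg_quant import (
    ERGTrace,
    average_repeats,
    components_table,
    intensity_response_summary,
    pooled_genotype_compare,
)
from flysleep.group_stats import GroupComparison, compare_parameter
from flysleep.sleep_scoring import compute_sleep_params, flag_inactive_fly

logger = logging.getLogger(__name__)

#: Scalar per-fly parameters tabulated in the statistics tables.
SLEEP_PARAMETERS = (
    "day_sleep",
    "night_sleep",
    "day_bout_len",
    "night_bout_len",
    "day_waking_activity",
    "night_waking_activity",
)


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    monitor_files: list[str] = field(default_factory=list)
    channel_map: dict[str, dict[int, str]] = field(default_factory=dict)  # monitor -> channel -> genotype
    lights_on_clock: int = 480  # minute-of-day of lights-on (480 = 08:00)
    analysis_day: int = 3  # 1-based; the window starts at that day's lights-on
    min_bout_min: int = 5
    exclude_inactive: bool = False
    inactive_tail_hours: float = 6.0
    erg_manifest: str | None = None
    output_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_bout_min < 1:
            raise ValueError("immobility threshold must be >= 1 minute")
        # YAML may deliver channel keys as strings
        self.channel_map = {
            monitor: {int(ch): geno for ch, geno in mapping.items()}
            for monitor, mapping in self.channel_map.items()
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        loc = raw.get("lights_on_clock", 480)
        if isinstance(loc, str):
            hh, mm = loc.split(":")[:2]
            raw["lights_on_clock"] = int(hh) * 60 + int(mm)
        return cls(**raw)


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Statistics rows in the published-table column layout."""
    return pd.DataFrame(
        [
            {
                "parameter": c.parameter,
                "genotype comparison": f"{c.genotype_a} vs {c.genotype_b}",
                "p-value": c.p_adj,
                "effect size r": c.r,
                "n1": c.n1,
                "n2": c.n2,
                "significant r magnitude": c.magnitude,
                "raw p": c.p_raw,
                "kruskal-wallis p": c.kw_p if c.kw_p is not None else "",
            }
            for c in comparisons
        ]
    )


def run_sleep_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Parse monitors, score every mapped fly and run the group statistics.

    Returns (and writes under ``config.output_dir``) the per-fly parameter
    table, the per-fly and per-genotype-mean 30-min profiles, and the
    statistics table across all parameters.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    fly_rows = []
    profile_rows = []
    for monitor_path in config.monitor_files:
        records = parse_monitor_file(monitor_path)
        monitor_name = Path(monitor_path).stem
        mapping = config.channel_map.get(monitor_name, {})
        if not mapping:
            logger.warning("monitor %s has no mapped channels", monitor_name)
            continue
        first = records.rows[0].timestamp
        # lights-on of day 1 = first clock occurrence of lights_on_clock at/after start
        base = first.replace(hour=config.lights_on_clock // 60,
                             minute=config.lights_on_clock % 60)
        if base < first:
            base += timedelta(days=1)
        window_start = base + timedelta(days=config.analysis_day - 1)
        for channel, genotype in sorted(mapping.items()):
            series = extract_channel_series(
                records, channel, window_start, MINUTES_PER_DAY,
                lights_on_clock=config.lights_on_clock, monitor_id=monitor_name,
            )
            fly_id = f"{monitor_name}_ch{channel:02d}"
            inactive = flag_inactive_fly(series, config.inactive_tail_hours)
            excluded = bool(inactive and config.exclude_inactive)
            if excluded:
                logger.info("excluding %s (%s): no activity in final %.1f h",
                            fly_id, genotype, config.inactive_tail_hours)
            params = compute_sleep_params(series, config.min_bout_min)
            fly_rows.append(
                {
                    "fly_id": fly_id,
                    "monitor": monitor_name,
                    "channel": channel,
                    "genotype": genotype,
                    "day_sleep": params.day_sleep_min,
                    "night_sleep": params.night_sleep_min,
                    "day_bout_count": params.day_bout_count,
                    "night_bout_count": params.night_bout_count,
                    "day_bout_len": params.day_bout_len,
                    "night_bout_len": params.night_bout_len,
                    "day_waking_activity": params.day_waking_activity,
                    "night_waking_activity": params.night_waking_activity,
                    "inactive_flag": inactive,
                    "excluded": excluded,
                }
            )
            profile_rows.append(
                {"fly_id": fly_id, "genotype": genotype, "excluded": excluded,
                 **{f"bin_{b:02d}": int(v) for b, v in enumerate(params.profile_30min)}}
            )

    fly_params = pd.DataFrame(fly_rows)
    profiles = pd.DataFrame(profile_rows)
    if fly_params.empty:
        raise ValueError("no mapped channels produced data")

    included = fly_params[~fly_params["excluded"]]
    bin_cols = [c for c in profiles.columns if c.startswith("bin_")]
    profile_means = (
        profiles[~profiles["excluded"]].groupby("genotype")[bin_cols].mean().reset_index()
    )

    counts = included.groupby("genotype").size()
    too_small = counts[counts < 2]
    if not too_small.empty:
        raise ValueError(f"genotypes with <2 flies after exclusions: {list(too_small.index)}")

    comparisons: list[GroupComparison] = []
    if included["genotype"].nunique() >= 2:
        for parameter in SLEEP_PARAMETERS:
            groups = {g: sub[parameter].to_numpy() for g, sub in included.groupby("genotype")}
            comparisons.extend(compare_parameter(parameter, groups))
    else:
        logger.info("single genotype: skipping group statistics")
    stats_table = comparisons_to_frame(comparisons)

    fly_params.to_csv(out_dir / "fly_sleep_params.csv", index=False)
    profiles.to_csv(out_dir / "sleep_profiles.csv", index=False)
    profile_means.to_csv(out_dir / "sleep_profile_genotype_means.csv", index=False)
    stats_table.to_csv(out_dir / "sleep_stats.csv", index=False)
    return {
        "fly_params": fly_params,
        "profiles": profiles,
        "profile_means": profile_means,
        "stats": stats_table,
    }


def _load_traces(manifest_path: str | Path) -> list[ERGTrace]:
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    traces = []
    for row in manifest.itertuples():
        data = pd.read_csv(manifest_path.parent / row.file)
        traces.append(
            ERGTrace(
                voltage=data["voltage_mv"].to_numpy(),
                sample_rate=float(row.sample_rate),
                stim_onset_s=float(row.stim_onset_s),
                stim_offset_s=float(row.stim_offset_s),
                intensity=float(row.intensity),
                fly_id=str(row.fly_id),
                genotype=str(row.genotype),
                repeat_index=int(row.repeat_index),
            )
        )
    return traces


def run_erg_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Quantify every manifest trace and run the pooled-intensity statistics."""
    if config.erg_manifest is None:
        raise ValueError("config.erg_manifest is not set")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    traces = _load_traces(config.erg_manifest)
    per_sweep = components_table(traces)
    per_fly = average_repeats(per_sweep)
    summary = intensity_response_summary(per_fly)
    if per_fly["genotype"].nunique() >= 2:
        comparisons = pooled_genotype_compare(per_fly)
    else:
        logger.info("single genotype: skipping pooled statistics")
        comparisons = []
    stats_table = comparisons_to_frame(comparisons)

    per_sweep.to_csv(out_dir / "erg_components_per_sweep.csv", index=False)
    per_fly.to_csv(out_dir / "erg_components_per_fly.csv", index=False)
    summary.to_csv(out_dir / "erg_intensity_response.csv", index=False)
    stats_table.to_csv(out_dir / "erg_stats.csv", index=False)
    return {
        "per_sweep": per_sweep,
        "per_fly": per_fly,
        "summary": summary,
        "stats": stats_table,
    }
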