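"""Score sleep on analysis day 3 and run the group statistics.

Reads the monitor files written by 01_simulate.py, scores every mapped fly
with the 5-minute immobility rule, and writes under results/sleep/:

* fly_sleep_params.csv — the seven parameters per fly;
* sleep_profiles.csv / sleep_profile_genotype_means.csv — 30-min profiles;
* sleep_stats.csv — Kruskal–Wallis screen + pairwise Wilcoxon with BH
  correction, effect size r and magnitude labels, one row per genotype pair
  per parameter.

Prints the significant comparisons so the programmed effects can be read
off directly: the fragmentation mutant should light up day bout length, the
slow mutant waking activity.
"""

from pathlib import Path

import pandas as pd

from flysleep.pipeline import RunConfig, run_sleep_pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    dam_dir = RESULTS / "synthetic_dam"
    channel_map_df = pd.read_csv(dam_dir / "channel_map.csv")
    channel_map: dict[str, dict[int, str]] = {}
    for row in channel_map_df.itertuples():
        channel_map.setdefault(row.monitor, {})[int(row.channel)] = row.genotype

    config = RunConfig(
        monitor_files=sorted(str(p) for p in dam_dir.glob("Monitor*.txt")),
        channel_map=channel_map,
        lights_on_clock=480,
        analysis_day=3,
        output_dir=str(RESULTS / "sleep"),
    )
    tables = run_sleep_pipeline(config)

    means = tables["fly_params"].groupby("genotype")[
        ["day_sleep", "night_sleep", "day_bout_len", "day_waking_activity"]
    ].mean().round(1)
    print("Per-genotype means (analysis day 3):")
    print(means.to_string())

    stats = tables["stats"]
    significant = stats[stats["significant r magnitude"] != ""]
    print(f"\n{len(significant)} of {len(stats)} comparisons significant "
          "(BH-adjusted p < 0.05):")
    cols = ["parameter", "genotype comparison", "p-value", "effect size r",
            "significant r magnitude"]
    print(significant[cols].to_string(index=False))


if __name__ == "__main__":
    main()
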