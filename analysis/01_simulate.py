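"""Generate the synthetic study: DAM monitor files and ERG traces.

Three behavioural genotypes, 30 virgin-male flies each, 3 LD days:

* ``control`` — the default circadian template (morning/evening activity,
  midday siesta, consolidated night sleep);
* ``fragmented`` — sleep-termination rate x4 (shorter bouts, same pressure);
* ``slow`` — waking beam-cross rate halved, sleep rates untouched (the
  locomotor-confound control: moves less while awake but sleeps the same).

Plus an ERG session: control vs a synaptic-transmission mutant whose on/off
transients are scaled to 10% with the receptor potential intact, 3 flies per
genotype, 4 intensities, 3 repeats.

Outputs under results/synthetic_dam/ and results/synthetic_erg/.
"""

from pathlib import Path

from flysleep.synthetic_data import (
    ERGModelParams,
    FlyModelParams,
    simulate_erg_experiment,
    simulate_experiment,
    write_erg_traces,
)

SEED = 2024
N_FLIES = 30
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    control = FlyModelParams(genotype="control")
    genotypes = {
        "control": (control, N_FLIES),
        "fragmented": (control.scaled(wake_onset=4.0, genotype="fragmented"), N_FLIES),
        "slow": (control.scaled(wake_rate=0.5, genotype="slow"), N_FLIES),
    }
    dam_dir = RESULTS / "synthetic_dam"
    truth = simulate_experiment(genotypes, days=3, seed=SEED, out_dir=dam_dir)
    print(f"Wrote {len(truth.monitor_files)} DAM monitor file(s) "
          f"({len(truth.truth)} flies) to {dam_dir}")

    erg_ctrl = ERGModelParams(noise_sd_mv=0.3)
    traces, erg_truth = simulate_erg_experiment(
        {"control": (erg_ctrl, 3),
         "transmission_mutant": (erg_ctrl.scaled_transients(0.1), 3)},
        seed=SEED + 1,
    )
    erg_dir = RESULTS / "synthetic_erg"
    manifest = write_erg_traces(traces, erg_dir)
    erg_truth.to_csv(erg_dir / "erg_truth.csv", index=False)
    print(f"Wrote {len(traces)} ERG sweeps and manifest to {manifest}")


if __name__ == "__main__":
    main()
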