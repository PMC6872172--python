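"""Detection power of the summary statistics through the stages of a sweep.

For each requested scenario, forward-simulates replicate sweeps at the
desk-scale rescaling, samples every snapshot stage, scores the samples on
the window statistics, and tabulates the fraction detected against the
matching neutral-background thresholds. The panmictic scenario (m0G)
reproduces the two detection windows: haplotype statistics (H1, iHS, nSL)
peak during the ongoing sweep, frequency-spectrum statistics (Tajima's D,
Fay & Wu's H) around and after completion.

Writes results/power_<code>.tsv.
"""

import argparse
from pathlib import Path

from demesweep.experiments import (
    build_scan,
    neutral_background_samples,
    scenario_stage_samples,
    stage_power,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"

STATS = (
    "theta_pi", "theta_w", "theta_h", "tajima_d", "faywu_h",
    "n_hap", "H1", "H12", "H2_H1", "ihs_prop", "nsl_prop",
)

NB_OF = {"m0G": "m0NB", "m20G": "m20NB", "m20L": "m20NB",
         "m2G": "m2NB", "m0.2G": "m0.2NB"}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--codes", nargs="+", default=["m0G"])
    ap.add_argument("--replicates", type=int, default=20)
    ap.add_argument("--samples", type=int, default=10)
    ap.add_argument("--nb-regions", type=int, default=100)
    ap.add_argument("--lam", type=float, default=10.0)
    ap.add_argument("--fpr", type=float, default=0.01)
    ap.add_argument("--seed", type=int, default=4)
    args = ap.parse_args()

    RESULTS.mkdir(exist_ok=True)
    for code in args.codes:
        nb_units, _ = neutral_background_samples(
            NB_OF[code], args.nb_regions, seed=args.seed, lam=args.lam
        )
        scan = build_scan(nb_units, NB_OF[code], STATS)
        panmictic = code == "m0G"
        demes = (0,) if panmictic else (1, 2)
        stage_names = ("neutral", "f20s", "f40s", "f60s", "f80s", "f99.5s",
                       "f100s", "t1Kr", "t2Kr")
        frames = []
        for deme in demes:
            trig = 0 if panmictic else deme - 1
            stages = [(s, 0 if s in ("neutral", "f100s") else trig)
                      for s in stage_names]
            samples = scenario_stage_samples(
                code, stages, args.replicates, args.samples,
                seed=args.seed + 1, lam=args.lam,
            )
            frames.append(stage_power(samples, scan, deme, fpr=args.fpr))
        import pandas as pd

        power = pd.concat(frames, ignore_index=True)
        power.to_csv(RESULTS / f"power_{code}.tsv", sep="\t", index=False)
        print(f"\n{code}: power at FPR {args.fpr} (deme {demes[0]}):")
        print(
            power[power.deme == demes[0]]
            .pivot(index="stage", columns="statistic", values="power")
            .reindex(stage_names)
            .round(2)
        )


if __name__ == "__main__":
    main()
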