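"""Two-stage sweep classification: cross-testing and spatial softening.

Trains the six predictor pairs (p60, p80, p99.5, p100, p100+, pmix) on
panmictic hard/soft/neutral training material, cross-tests every pair
against every stage's hard and soft test sets (temporal misclassification),
and applies the fixation-stage pairs to d2 samples of the global (m20G) and
local (m20L) adaptation scenarios (spatial softening: the imported,
unselected sweep in m20L's d2 draws soft-sweep calls).

Writes results/crosstest.tsv and results/spatial_softening.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from demesweep.classifier import classification_report, classify, cross_test
from demesweep.experiments import (
    deme_subset,
    scenario_stage_samples,
    train_stage_pairs,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--per-class", type=int, default=60)
    ap.add_argument("--neutral", type=int, default=100)
    ap.add_argument("--nb-threshold", type=int, default=300)
    ap.add_argument("--lam", type=float, default=10.0)
    ap.add_argument("--fpr", type=float, default=0.05)
    ap.add_argument("--replicates", type=int, default=8)
    ap.add_argument("--seed", type=int, default=5)
    args = ap.parse_args()

    RESULTS.mkdir(exist_ok=True)
    pairs, featurizer, material = train_stage_pairs(
        seed=args.seed,
        lam=args.lam,
        n_per_class=args.per_class,
        n_neutral=args.neutral,
        n_nb_threshold=args.nb_threshold,
    )
    stages = [p.stage for p in pairs if p.stage != "mix"]
    test_sets = {s: material[s] for s in stages}
    matrix = cross_test(pairs, test_sets, fpr=args.fpr)
    matrix.to_csv(RESULTS / "crosstest.tsv", sep="\t", index=False)
    hard = matrix[matrix.true_class == "hard"]
    print("soft-call proportion on HARD test sets (temporal softening")
    print("peaks where predictor stage and test stage mismatch):")
    print(hard.pivot(index="predictor", columns="test_stage",
                     values="prop_soft").round(2))

    rows = []
    for code in ("m20G", "m20L"):
        samples = scenario_stage_samples(
            code, [("f100s", 0)], args.replicates, 5, seed=args.seed + 1,
            lam=args.lam,
        )[("f100s", 0)]
        X = featurizer.matrix(deme_subset(samples, deme=2))
        for pair in pairs:
            if pair.stage not in ("f80s", "f99.5s", "f100s"):
                continue
            rep = classification_report(classify(X, pair, args.fpr))
            rows.append(dict(scenario=code, predictor=pair.stage, **rep))
    spatial = pd.DataFrame(rows)
    spatial.to_csv(RESULTS / "spatial_softening.tsv", sep="\t", index=False)
    print("\nclassification of d2 at global fixation (spatial softening:")
    print("m20L's migration-imported sweep reads as soft):")
    print(spatial.round(2))


if __name__ == "__main__":
    main()
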