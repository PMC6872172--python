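"""Shared fixtures: the scaled-down simulation campaigns.

The heavy fixtures are session-scoped so each campaign (neutral-background
calibration, the panmictic power curves, the classifier cross-test, the
two-deme comparisons, the FST trajectories) is simulated exactly once per
test run. Genomic campaigns run at the desk-scale rescaling lambda = 10;
the single-site grid runs at full population size. All seeds are fixed.
"""

from __future__ import annotations

import numpy as np
import pytest

from demesweep.experiments import (
    build_scan,
    fst_neutral_baseline,
    fst_trajectories,
    neutral_background_samples,
    scenario_stage_samples,
    single_site_rate_table,
    track_matrices,
    train_stage_pairs,
)

SEED = 20_250_930

POWER_STATS = (
    "theta_pi",
    "theta_w",
    "theta_h",
    "tajima_d",
    "faywu_h",
    "n_hap",
    "H1",
    "H12",
    "H2_H1",
    "ihs_prop",
    "nsl_prop",
)

CHEAP_STATS = ("theta_pi", "theta_w", "tajima_d", "n_hap", "H1")


@pytest.fixture(scope="session")
def single_site_table():
    """Default two-deme scenario, all five migration rates, 1000 conditioned
    replicates each (full population size; runs in seconds)."""
    return single_site_rate_table(replicates=1000, seed=SEED)


@pytest.fixture(scope="session")
def m0g_campaign():
    """Panmictic sweep campaign at lambda = 10: NB calibration set, held-out
    NB, and per-stage track matrices of the m0G scenario."""
    nb_units, _ = neutral_background_samples("m0NB", 70, seed=SEED + 1)
    scan = build_scan(nb_units, "m0NB", POWER_STATS)
    heldout_units, _ = neutral_background_samples("m0NB", 50, seed=SEED + 2)
    heldout_tracks = track_matrices(
        heldout_units, POWER_STATS, scan.ihs_table, scan.nsl_table
    )
    stages = [(s, 0) for s in
              ("neutral", "f20s", "f40s", "f60s", "f80s", "f99.5s", "f100s")]
    stage_samples = scenario_stage_samples(
        "m0G", stages, n_replicates=10, samples_per_snapshot=5, seed=SEED + 3
    )
    stage_tracks = {
        key: track_matrices(samples, POWER_STATS, scan.ihs_table, scan.nsl_table)
        for key, samples in stage_samples.items()
    }
    return dict(
        scan=scan,
        heldout_tracks=heldout_tracks,
        stage_tracks=stage_tracks,
        n_heldout=len(heldout_units),
    )


@pytest.fixture(scope="session")
def classifier_campaign():
    """Stage-specific predictor pairs (200-kb mode) with their featurized
    training material, at the scaled-down training size."""
    pairs, featurizer, material = train_stage_pairs(
        seed=SEED + 4,
        n_per_class=40,
        n_neutral=60,
        n_nb_threshold=150,
        samples_per_population=5,
    )
    return dict(pairs=pairs, featurizer=featurizer, material=material)


@pytest.fixture(scope="session")
def spatial_campaign(classifier_campaign):
    """d2 samples of m20L vs m20G at global fixation, featurized with the
    classifier campaign's featurizer."""
    from demesweep.experiments import deme_subset

    featurizer = classifier_campaign["featurizer"]
    out = {}
    for i, code in enumerate(("m20G", "m20L")):
        samples = scenario_stage_samples(
            code,
            stages=[("f100s", 0)],
            n_replicates=6,
            samples_per_snapshot=5,
            seed=SEED + 5 + i,
        )[("f100s", 0)]
        d2 = deme_subset(samples, deme=2)
        out[code] = featurizer.matrix(d2)
    return out


@pytest.fixture(scope="session")
def m02g_campaign():
    """m0.2G post-fixation stages sampled per deme and as mixed samples,
    with matching separate-deme and mixed NB scan contexts (cheap
    statistics only)."""
    from demesweep.experiments import deme_subset
    from demesweep.io_formats import HaplotypeSample

    stages = [("f100s", 0), ("t1Kr", 0), ("t1Kr", 1)]
    separate = scenario_stage_samples(
        "m0.2G", stages, n_replicates=6, samples_per_snapshot=6, seed=SEED + 7
    )
    mixed = scenario_stage_samples(
        "m0.2G", stages, n_replicates=6, samples_per_snapshot=6, seed=SEED + 7,
        mixed=True,
    )
    nb_units, nb_regions = neutral_background_samples("m0.2NB", 60, seed=SEED + 8)
    scan_sep = build_scan(nb_units, "m0.2NB", CHEAP_STATS)
    rng = np.random.default_rng(SEED + 9)
    mixed_nb = []
    for r in nb_regions:
        idx = np.sort(rng.choice(r.n_hap, size=50, replace=False))
        u = r.subset_haplotypes(idx)
        u.deme_labels = np.zeros(50, dtype=int)
        mixed_nb.append(u)
    scan_mix = build_scan(mixed_nb, "m0.2NB-mixed", CHEAP_STATS)
    tracks = {}
    for key in separate:
        for deme in (1, 2):
            tracks[(key, f"d{deme}")] = track_matrices(
                deme_subset(separate[key], deme), CHEAP_STATS
            )
        tracks[(key, "mixed")] = track_matrices(mixed[key], CHEAP_STATS)
    return dict(scan_sep=scan_sep, scan_mix=scan_mix, tracks=tracks, stages=stages)


@pytest.fixture(scope="session")
def fst_campaign():
    """FST trajectories of m20L and m0.2G with their neutral baselines."""
    stages = (
        [("neutral", 0)]
        + [(s, 0) for s in ("f60s", "f80s", "f99.5s")]
        + [("f100s", 0), ("t1Kr", 0), ("t2Kr", 0)]
    )
    out = {}
    for i, code in enumerate(("m20L", "m0.2G")):
        traj = fst_trajectories(
            code, n_replicates=5, samples_per_snapshot=6, seed=SEED + 10 + i,
            stages=stages,
        )
        nb_code = "m20NB" if code == "m20L" else "m0.2NB"
        baseline = fst_neutral_baseline(
            nb_code, n_replicates=12, samples_per_replicate=6, seed=SEED + 12 + i
        )
        out[code] = dict(traj=traj, baseline=baseline)
    return out
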