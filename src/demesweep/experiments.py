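"""End-to-end experiment drivers over the simulators, statistics, detection
and classification machinery.

Each driver reproduces one of the study's analyses at a configurable scale:
the single-site timing grid runs at full population size (it is cheap); the
genomic-region experiments default to the desk-scale rescaling lambda = 10
with replicate counts chosen so that a full campaign runs in minutes on one
CPU, trading Monte-Carlo precision (not bias) for time. All drivers are
deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import HaplotypeSample, derive_seeds, get_scenario, make_windows
from .single_site import DemeSpec, simulate_timing_batch, trajectory_stats
from .genomic_sim import (
    FREQ_STAGES,
    STAGE_NAMES,
    GenomicConfig,
    SnapshotSchedule,
    draw_samples,
    init_neutral_population,
    make_training_sets,
    neutral_coalescent_samples,
    run_scenario,
)
from .sumstats import (
    NormalisationTable,
    build_normalisation,
    fst_stats,
    ihs_nsl_scores,
    normalise_scores,
    score_sample,
    window_significance,
)
from .detection import ThresholdTable, calibrate_thresholds, detection_rate
from . import classifier as clf

__all__ = [
    "DEFAULT_LAMBDA",
    "single_site_rate_table",
    "single_site_headline",
    "neutral_background_samples",
    "split_demes",
    "ScanContext",
    "build_scan",
    "track_matrices",
    "scenario_stage_samples",
    "stage_power",
    "fst_trajectories",
    "train_stage_pairs",
]

DEFAULT_LAMBDA = 10.0

DEFAULT_RATES = (0.02, 0.2, 2.0, 20.0, 200.0)

_STAGE_ORD = {name: i for i, name in enumerate(STAGE_NAMES)}


def _stage_offset(stage: str, deme: int) -> int:
    """Deterministic per-(stage, deme) seed offset."""
    return 17 * _STAGE_ORD.get(stage, len(STAGE_NAMES)) + deme + 1


# ---------------------------------------------------------------------------
# single-site timing (full scale)


def single_site_rate_table(
    replicates: int = 1000,
    seed: int = 0,
    rates: Sequence[float] = DEFAULT_RATES,
    sizes: tuple[int, int] = (10_000, 10_000),
    s: tuple[float, float] = (0.02, 0.02),
) -> pd.DataFrame:
    """Timing table of the default two-deme scenario across migration rates:
    ``replicates`` conditioned runs per rate, one row each."""
    seeds = derive_seeds(seed, len(rates), key=21)
    frames = []
    for nm, sd in zip(rates, seeds):
        spec = DemeSpec(sizes=sizes, s=s, Nm=nm)
        frames.append(simulate_timing_batch(spec, replicates, int(sd)))
    return pd.concat(frames, ignore_index=True)


def single_site_headline(seed: int = 0, replicates: int = 1000) -> dict:
    """The headline single-site quantities: median time for the allele to
    take over the recipient deme d2 (first passage to fixation) per
    migration rate, and the pooled r-squared of log10(Nm) against the d2
    completion time and selection-phase length across all five rates."""
    table = single_site_rate_table(replicates=replicates, seed=seed)
    medians = {
        float(nm): float(np.median(sub.tfix_d2))
        for nm, sub in table.groupby("Nm")
    }
    return {
        "median_tfix_d2": medians,
        "replicates_per_rate": int(replicates),
        "r2_completion": float(trajectory_stats(table, "t995_d2")["r2"]),
        "r2_phase": float(trajectory_stats(table, "phase_d2")["r2"]),
        "n_pooled": int(len(table)),
    }


# ---------------------------------------------------------------------------
# neutral backgrounds and scan pipelines


def split_demes(sample: HaplotypeSample) -> list[HaplotypeSample]:
    """One-deme 50-haplotype samples from a two-deme sample (each deme of a
    neutral two-deme region is used as an independent NB sample)."""
    if sample.deme_labels is None:
        return [sample]
    out = []
    for d in np.unique(sample.deme_labels):
        out.append(sample.subset_haplotypes(np.flatnonzero(sample.deme_labels == d)))
    return out


def neutral_background_samples(
    code: str,
    n_regions: int,
    seed: int,
    lam: float = DEFAULT_LAMBDA,
    sample_size: int = 50,
) -> tuple[list[HaplotypeSample], list[HaplotypeSample]]:
    """NB samples for one demography.

    Returns ``(units, regions)``: the per-region two-deme (or panmictic)
    samples, and the one-deme analysis units (each deme split out, so a
    two-deme NB of R regions yields 2R units).
    """
    cfg = GenomicConfig.from_scenario(code, lam=lam)
    regions = neutral_coalescent_samples(cfg, n_regions, sample_size, seed)
    units = [u for r in regions for u in split_demes(r)]
    return units, regions


@dataclass
class ScanContext:
    """Everything needed to score and judge samples of one demography:
    iHS/nSL normalisation tables, calibrated thresholds and the NB track
    matrices they came from."""

    demography: str
    stats: tuple[str, ...]
    ihs_table: NormalisationTable | None
    nsl_table: NormalisationTable | None
    thresholds: ThresholdTable
    nb_tracks: dict[str, np.ndarray]
    region_length: float = 600_000.0


def _raw_scores_pooled(samples: Sequence[HaplotypeSample]) -> pd.DataFrame:
    frames = [ihs_nsl_scores(s) for s in samples]
    return frames, pd.concat(frames, ignore_index=True)


def build_scan(
    nb_units: Sequence[HaplotypeSample],
    demography: str,
    stats: Sequence[str],
    fprs: Sequence[float] = (0.05, 0.01, 0.001),
    region_length: float = 600_000.0,
) -> ScanContext:
    """Build the scan pipeline of one demography from its NB units: pool the
    unstandardised iHS/nSL scores into frequency-bin normalisation tables,
    score the NB itself on all requested statistics, and calibrate the
    detection thresholds from those tracks."""
    need_hap_len = "ihs_prop" in stats or "nsl_prop" in stats
    ihs_table = nsl_table = None
    per_sample_raw = None
    if need_hap_len:
        n = nb_units[0].n_hap
        per_sample_raw, pooled = _raw_scores_pooled(nb_units)
        ihs_table = build_normalisation(
            pooled["count"].to_numpy(), pooled["ihs_raw"].to_numpy(), n
        )
        nsl_table = build_normalisation(
            pooled["count"].to_numpy(), pooled["nsl_raw"].to_numpy(), n
        )
    tracks = track_matrices(
        nb_units,
        stats,
        ihs_table,
        nsl_table,
        precomputed_raw=per_sample_raw,
        region_length=region_length,
    )
    thresholds = calibrate_thresholds(
        tracks, demography=demography, region_length=region_length, fprs=fprs
    )
    return ScanContext(
        demography=demography,
        stats=tuple(stats),
        ihs_table=ihs_table,
        nsl_table=nsl_table,
        thresholds=thresholds,
        nb_tracks=tracks,
        region_length=region_length,
    )


def track_matrices(
    samples: Sequence[HaplotypeSample],
    stats: Sequence[str],
    ihs_table: NormalisationTable | None = None,
    nsl_table: NormalisationTable | None = None,
    precomputed_raw: Sequence[pd.DataFrame] | None = None,
    region_length: float = 600_000.0,
) -> dict[str, np.ndarray]:
    """Per-statistic ``(n_samples, n_windows)`` score matrices."""
    grid = make_windows(region_length, 100_000.0, 10_000.0)
    out: dict[str, list[np.ndarray]] = {s: [] for s in stats}
    for i, sample in enumerate(samples):
        tracks = score_sample(
            sample,
            grid=grid,
            stats=stats,
            ihs_table=ihs_table,
            nsl_table=nsl_table,
            precomputed_raw=None if precomputed_raw is None else precomputed_raw[i],
        )
        for s in stats:
            out[s].append(tracks[s].values)
    return {s: np.array(v) for s, v in out.items()}


# ---------------------------------------------------------------------------
# scenario sampling


def scenario_stage_samples(
    code: str,
    stages: Sequence[tuple[str, int]],
    n_replicates: int,
    samples_per_snapshot: int,
    seed: int,
    lam: float = DEFAULT_LAMBDA,
    sample_size: int = 50,
    mixed: bool = False,
) -> dict[tuple[str, int], list[HaplotypeSample]]:
    """Forward-simulate a scenario and sample its snapshots.

    ``stages`` are (stage, trigger_deme) pairs; the special stage "neutral"
    samples the pre-sweep equilibrium state. Returns two-deme samples (or
    mixed/panmictic ones) per stage, pooled over replicates.
    """
    cfg = GenomicConfig.from_scenario(code, lam=lam)
    seeds = derive_seeds(seed, 2 * n_replicates, key=31)
    wanted = [st for st in stages if st[0] != "neutral"]
    want_neutral = any(st[0] == "neutral" for st in stages)
    out: dict[tuple[str, int], list[HaplotypeSample]] = {st: [] for st in stages}
    for r in range(n_replicates):
        run = run_scenario(
            cfg,
            SnapshotSchedule.standard(wanted=wanted),
            seed=int(seeds[2 * r]),
        )
        draw_seed = int(seeds[2 * r + 1])
        if want_neutral:
            neutral_state = run.initial
            out[("neutral", 0)].extend(
                draw_samples(
                    neutral_state,
                    n_samples=samples_per_snapshot,
                    per_deme=sample_size,
                    mixed=mixed,
                    seed=draw_seed,
                )
            )
        for snap in run.snapshots:
            key = (snap.stage, snap.deme)
            if key in out:
                out[key].extend(
                    draw_samples(
                        snap,
                        n_samples=samples_per_snapshot,
                        per_deme=sample_size,
                        mixed=mixed,
                        seed=draw_seed + _stage_offset(*key),
                    )
                )
    return out


def deme_subset(samples: Iterable[HaplotypeSample], deme: int) -> list[HaplotypeSample]:
    """The one-deme analysis units of deme ``deme`` (1-based label) from
    two-deme samples; deme 0 returns samples unchanged (panmictic/mixed)."""
    if deme == 0:
        return list(samples)
    return [
        s.subset_haplotypes(np.flatnonzero(s.deme_labels == deme)) for s in samples
    ]


def stage_power(
    stage_samples: Mapping[tuple[str, int], Sequence[HaplotypeSample]],
    scan: ScanContext,
    deme: int,
    fpr: float = 0.01,
    span: str = "first200k",
) -> pd.DataFrame:
    """Detection power per stage and statistic for one deme's analysis
    units, under one demography's calibrated thresholds."""
    rows = []
    for (stage, trig), samples in stage_samples.items():
        units = deme_subset(samples, deme)
        tracks = track_matrices(
            units,
            scan.stats,
            scan.ihs_table,
            scan.nsl_table,
            region_length=scan.region_length,
        )
        for stat, values in tracks.items():
            rate, n = detection_rate(
                values, stat, scan.thresholds, fpr, span,
                region_length=scan.region_length,
            )
            rows.append(
                dict(stage=stage, trigger_deme=trig, deme=deme, statistic=stat,
                     fpr=fpr, power=rate, n=n)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FST trajectories


def fst_trajectories(
    code: str,
    n_replicates: int,
    samples_per_snapshot: int,
    seed: int,
    lam: float = DEFAULT_LAMBDA,
    stages: Sequence[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Mean first-200-kb FST per replicate and time stage (the per-replicate
    value is the mean over that snapshot's samples); stage "neutral" is the
    pre-sweep baseline."""
    if stages is None:
        stages = [("neutral", 0)] + [
            (s, d) for d in (0, 1) for s in FREQ_STAGES
        ] + [("f100s", 0), ("t1Kr", 0), ("t1Kr", 1)]
    cfg = GenomicConfig.from_scenario(code, lam=lam)
    if cfg.n_demes != 2:
        raise ValueError("FST trajectories need a two-deme scenario")
    seeds = derive_seeds(seed, 2 * n_replicates, key=41)
    rows = []
    wanted = [st for st in stages if st[0] != "neutral"]
    for r in range(n_replicates):
        run = run_scenario(
            cfg, SnapshotSchedule.standard(wanted=wanted), seed=int(seeds[2 * r])
        )
        snaps = [("neutral", 0, 0, run.initial)] + [
            (s.stage, s.deme, s.generation, s.state) for s in run.snapshots
        ]
        for stage, trig, gen, state in snaps:
            if (stage, trig) not in stages:
                continue
            samples = draw_samples(
                state,
                n_samples=samples_per_snapshot,
                per_deme=50,
                seed=int(seeds[2 * r + 1]) + _stage_offset(stage, trig),
            )
            vals = [fst_stats(s) for s in samples]
            rows.append(
                dict(
                    scenario=code,
                    rep=r,
                    stage=stage,
                    trigger_deme=trig,
                    generation=gen * lam,
                    fst=float(np.nanmean(vals)),
                )
            )
    return pd.DataFrame(rows)


def fst_neutral_baseline(
    code: str,
    n_replicates: int,
    samples_per_replicate: int,
    seed: int,
    lam: float = DEFAULT_LAMBDA,
) -> np.ndarray:
    """Per-replicate mean FST of neutral equilibrium populations of one
    two-deme demography (the generation-0 baseline distribution)."""
    cfg = GenomicConfig.from_scenario(code, lam=lam)
    seeds = derive_seeds(seed, 2 * n_replicates, key=42)
    out = []
    for r in range(n_replicates):
        pop = init_neutral_population(cfg, int(seeds[2 * r]))
        samples = draw_samples(
            pop, n_samples=samples_per_replicate, per_deme=50,
            seed=int(seeds[2 * r + 1]),
        )
        out.append(float(np.nanmean([fst_stats(s) for s in samples])))
    return np.array(out)


# ---------------------------------------------------------------------------
# classifier campaign


def train_stage_pairs(
    seed: int,
    lam: float = DEFAULT_LAMBDA,
    n_per_class: int = 60,
    n_neutral: int = 100,
    n_nb_threshold: int = 200,
    samples_per_population: int = 5,
    mode: str = "200kb",
    stages: Sequence[str] = ("f60s", "f80s", "f99.5s", "f100s", "t1Kr"),
    include_mix: bool = True,
) -> tuple[list[clf.PredictorPair], clf.Featurizer, dict]:
    """Train the stage-specific predictor pairs at a chosen scale.

    Returns the pairs (stages plus "mix"), the featurizer (with panmictic-NB
    normalisation tables baked in), and a dict with the featurized training
    material for reuse as cross-test sets.
    """
    cfg = GenomicConfig.from_scenario("m0G", lam=lam)
    seeds = derive_seeds(seed, 6, key=51)
    sets = make_training_sets(
        cfg,
        int(seeds[0]),
        stages=stages,
        n_per_class=n_per_class,
        n_neutral=n_neutral,
        samples_per_population=samples_per_population,
        include_mix=include_mix,
    )
    # panmictic NB for normalisation + an independent NB for thresholds
    norm_units = neutral_coalescent_samples(cfg, max(40, n_neutral // 2), 50,
                                            int(seeds[1]))
    _, pooled = _raw_scores_pooled(norm_units)
    n = norm_units[0].n_hap
    ihs_table = build_normalisation(
        pooled["count"].to_numpy(), pooled["ihs_raw"].to_numpy(), n
    )
    nsl_table = build_normalisation(
        pooled["count"].to_numpy(), pooled["nsl_raw"].to_numpy(), n
    )
    featurizer = clf.Featurizer(mode=mode, ihs_table=ihs_table, nsl_table=nsl_table)

    thr_units = neutral_coalescent_samples(cfg, n_nb_threshold, 50, int(seeds[2]))
    nb_thr_X = featurizer.matrix(thr_units)

    material: dict = {"nb_threshold_X": nb_thr_X, "raw": {}}
    material["raw"]["nb_threshold"] = thr_units
    neutral_X = featurizer.matrix(sets[0].neutral)
    material["neutral_X"] = neutral_X
    material["raw"]["neutral"] = sets[0].neutral
    pairs = []
    for i, ts in enumerate(sets):
        hard_X = featurizer.matrix(ts.hard)
        soft_X = featurizer.matrix(ts.soft)
        material[ts.stage] = {"hard": hard_X, "soft": soft_X}
        material["raw"][ts.stage] = {"hard": ts.hard, "soft": ts.soft}
        pairs.append(
            clf.train_pair(
                ts.stage,
                neutral_X,
                hard_X,
                soft_X,
                nb_thr_X,
                seed=int(seeds[3]) + i,
                mode=mode,
            )
        )
    return pairs, featurizer, material
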