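"""Genomic forward engine: drift/selection/migration oracles, neutral
equilibrium, rescaling, snapshot schedules and sampling."""

import numpy as np
import pytest

from demesweep.genomic_sim import (
    GenomicConfig,
    PopulationState,
    SnapshotSchedule,
    draw_samples,
    init_neutral_population,
    make_training_sets,
    neutral_coalescent_samples,
    rescale,
    run_scenario,
    step_generation,
    _soft_candidate,
)
from demesweep.sumstats import sfs_stats


def small_config(**kw):
    defaults = dict(
        deme_sizes=(200,), s=(0.0,), migration=0.0, mu=0.05, rec=0.05,
        region_length=10_000.0, sel_pos=5_000.0,
    )
    defaults.update(kw)
    return GenomicConfig(**defaults)


# ---------------------------------------------------------------------------
# rescaling


def test_rescale_preserves_population_compounds():
    cfg = GenomicConfig.from_scenario("m2G")
    r = rescale(cfg, 10)
    assert r.deme_sizes == (1000, 1000)
    for a, b in zip(cfg.deme_sizes, r.deme_sizes):
        assert a * cfg.s[0] == pytest.approx(b * r.s[0])
        assert a * cfg.migration == pytest.approx(b * r.migration)
    assert cfg.deme_sizes[0] * cfg.mu == pytest.approx(r.deme_sizes[0] * r.mu)
    assert rescale(cfg, 1) is cfg


def test_rescale_refuses_strong_selection():
    cfg = GenomicConfig.from_scenario("m0G")
    with pytest.raises(ValueError, match="weak-selection"):
        rescale(cfg, 30)  # s * lam = 0.6


# ---------------------------------------------------------------------------
# neutral equilibrium


def test_zero_mutation_burn_in_has_no_sites():
    cfg = small_config(mu=0.0)
    pop = init_neutral_population(cfg, seed=1, backend="burn-in",
                                  burnin_generations=50)
    assert pop.positions.size == 0


def test_watterson_expectation_in_coalescent_samples():
    """E[S] for a 50-chromosome sample of the panmictic scenario is
    theta * a_49 with theta = 2 N mu = 240 (invariant under rescaling)."""
    cfg = GenomicConfig.from_scenario("m0G", lam=10)
    samples = neutral_coalescent_samples(cfg, 12, 50, seed=2)
    a49 = np.sum(1.0 / np.arange(1, 50))
    expected = 2 * cfg.deme_sizes[0] * cfg.mu * a49
    assert expected == pytest.approx(240 * a49)
    mean_s = np.mean([s.n_snp for s in samples])
    assert abs(mean_s - expected) / expected < 0.10


def test_burnin_and_coalescent_backends_agree_on_diversity():
    """Mean pairwise diversity of the forward neutral burn-in matches the
    coalescent backend at a tiny population size."""
    cfg = small_config(deme_sizes=(40,), mu=0.05, rec=0.05)
    reps = 25
    pis = {b: [] for b in ("coalescent", "burn-in")}
    for backend in pis:
        for r in range(reps):
            pop = init_neutral_population(
                cfg, seed=100 + r, backend=backend,
                burnin_generations=20 * 40,
            )
            counts = pop.haps.sum(axis=0)
            res = sfs_stats(counts, pop.haps.shape[0])
            pis[backend].append(res["theta_pi"])
    m_coal = np.mean(pis["coalescent"])
    m_fwd = np.mean(pis["burn-in"])
    assert abs(m_fwd - m_coal) / m_coal < 0.15


# ---------------------------------------------------------------------------
# one-generation oracles


def test_neutral_one_generation_drift_matches_binomial_variance():
    """Allele-frequency change of a neutral column over one generation has
    mean ~ 0 and variance ~ p(1-p)/N."""
    N = 200
    cfg = small_config(deme_sizes=(N,), mu=0.0, rec=0.0)
    p0 = 0.3
    haps = np.zeros((N, 1), dtype=np.uint8)
    haps[: int(N * p0)] = 1
    state = PopulationState(
        haps=haps, positions=np.array([5_000.0]), ind_deme=np.zeros(N // 2, int),
        config=cfg, sel_pos=5_000.0,
    )
    rng = np.random.default_rng(3)
    dps = []
    for _ in range(600):
        new = step_generation(state, cfg, rng)
        dps.append(new.sel_frequency() - p0)
    dps = np.asarray(dps)
    assert abs(dps.mean()) < 4 * np.sqrt(p0 * (1 - p0) / N / len(dps))
    var_expect = p0 * (1 - p0) / N
    assert abs(dps.var() - var_expect) / var_expect < 0.25


def test_selection_one_generation_matches_codominant_update():
    """With co-dominant selection the expected one-generation change matches
    p(1+s)/(1+ps) within Monte-Carlo error."""
    N, s, p0 = 400, 0.2, 0.3
    cfg = small_config(deme_sizes=(N,), s=(s,), mu=0.0, rec=0.0)
    haps = np.zeros((N, 1), dtype=np.uint8)
    haps[: int(N * p0)] = 1
    rng0 = np.random.default_rng(4)
    perm = rng0.permutation(N)  # random genotype pairing
    state = PopulationState(
        haps=haps[perm], positions=np.array([5_000.0]),
        ind_deme=np.zeros(N // 2, int), config=cfg, sel_pos=5_000.0,
    )
    rng = np.random.default_rng(5)
    freqs = [step_generation(state, cfg, rng).sel_frequency() for _ in range(500)]
    # conditional expectation given the realized diploid pairing (a single
    # pairing deviates from Hardy-Weinberg by O(1/sqrt(N)))
    g = state.haps[0::2, 0].astype(int) + state.haps[1::2, 0]
    w = (1 + s) ** g
    expected_exact = float(np.sum(w * g / 2) / np.sum(w))
    # ... which itself sits within MC error of the haploid-map expectation
    assert expected_exact == pytest.approx(p0 * (1 + s) / (1 + p0 * s), abs=0.02)
    se = np.sqrt(p0 * (1 - p0) / N / len(freqs))
    assert abs(np.mean(freqs) - expected_exact) < 4 * se


def test_migration_swaps_expected_individual_count():
    N = 200
    cfg = GenomicConfig(
        deme_sizes=(N, N), s=(0.0, 0.0), migration=0.1, mu=0.0, rec=0.0,
        region_length=10_000.0,
    )
    haps = np.zeros((2 * N, 1), dtype=np.uint8)
    haps[:N] = 1  # deme-0 chromosomes marked
    state = PopulationState(
        haps=haps, positions=np.array([5_000.0]),
        ind_deme=np.repeat([0, 1], N // 2), config=cfg, sel_pos=5_000.0,
    )
    rng = np.random.default_rng(6)
    moved = []
    for _ in range(200):
        new = step_generation(state, cfg, rng)
        # marked chromosomes now sitting in deme 1
        moved.append(new.haps[new.chrom_deme == 1, 0].sum())
    # balanced swap of Binomial(N/2, m) individuals = N m marked chromosomes
    # expected per direction
    assert np.mean(moved) == pytest.approx(N * cfg.migration, rel=0.25)


# ---------------------------------------------------------------------------
# schedules, scenario runs, sampling


def test_standard_schedule_snapshot_counts():
    sched = SnapshotSchedule.standard()
    assert sched.n_snapshots(2) == 21
    assert sched.n_snapshots(1) == 11
    assert SnapshotSchedule.fixed(100, 20_000).n_snapshots(2) == 200


def test_panmictic_run_collects_all_stages_and_triggers_fire_correctly():
    cfg = GenomicConfig.from_scenario("m0G", lam=20)
    run = run_scenario(cfg, SnapshotSchedule.standard(), seed=7)
    assert len(run.snapshots) == 11
    stages = {s.stage for s in run.snapshots}
    assert stages == {"f20s", "f40s", "f60s", "f80s", "f99.5s", "f100s",
                      "t1Kr", "t2Kr", "t3Kr", "t4Kr", "t5Kr"}
    f80 = next(s for s in run.snapshots if s.stage == "f80s")
    # trigger correctness: the first generation at/above 80%
    assert 0.8 <= f80.state.sel_frequency() < 0.9
    f100 = next(s for s in run.snapshots if s.stage == "f100s")
    samples = draw_samples(f100, n_samples=3, per_deme=50, seed=8)
    for s in samples:
        j = np.flatnonzero(np.isclose(s.positions, cfg.sel_pos))
        assert j.size == 1
        assert s.matrix[:, j[0]].mean() == 1.0  # fixed in every sample


def test_fixed_interval_mode_counts_and_truncates():
    cfg = GenomicConfig.from_scenario("m0.2L", lam=20)
    run = run_scenario(cfg, SnapshotSchedule.fixed(100, 2_000), seed=9)
    assert run.truncated
    assert len(run.snapshots) == 2_000 // 100


def test_draw_samples_shapes_and_determinism():
    cfg = GenomicConfig.from_scenario("m20G", lam=20)
    pop = init_neutral_population(cfg, seed=10)
    samples = draw_samples(pop, n_samples=4, per_deme=50, seed=11)
    assert len(samples) == 4
    assert samples[0].n_hap == 100
    assert set(np.unique(samples[0].deme_labels)) == {1, 2}
    again = draw_samples(pop, n_samples=4, per_deme=50, seed=11)
    assert np.array_equal(samples[0].matrix, again[0].matrix)
    mixed = draw_samples(pop, n_samples=1, per_deme=50, mixed=True, seed=12)[0]
    assert mixed.n_hap == 50 and set(np.unique(mixed.deme_labels)) == {0}
    with pytest.raises(ValueError, match="exceeds"):
        draw_samples(pop, n_samples=1, per_deme=10_000, seed=13)


def test_soft_candidate_selection_and_failure():
    cfg = small_config()
    rng = np.random.default_rng(14)
    haps = np.zeros((200, 3), dtype=np.uint8)
    haps[:20, 0] = 1  # 10% at 4000 bp
    haps[:20, 1] = 1  # 10% at 5200 bp (closer to the 5 kb focus)
    haps[:100, 2] = 1  # 50%
    state = PopulationState(
        haps=haps, positions=np.array([4_000.0, 5_200.0, 8_000.0]),
        ind_deme=np.zeros(100, int), config=cfg,
    )
    assert _soft_candidate(state, cfg) == 5_200.0
    state.haps = haps[:, 2:]
    state.positions = np.array([8_000.0])
    with pytest.raises(KeyError):
        _soft_candidate(state, cfg)


def test_training_sets_composition():
    cfg = GenomicConfig.from_scenario("m0G", lam=20)
    sets = make_training_sets(
        cfg, seed=15, stages=("f60s", "f100s"), n_per_class=4,
        n_neutral=6, samples_per_population=2,
    )
    stages = [t.stage for t in sets]
    assert stages == ["f60s", "f100s", "mix"]
    for t in sets[:2]:
        assert len(t.hard) == 4 and len(t.soft) == 4 and len(t.neutral) == 6
        for s in t.soft:
            # the selected column is a standing variant near the focal site
            assert s.selected_pos is not None
    mix = sets[-1]
    assert len(mix.hard) == 2 * 2 and len(mix.soft) == 2 * 2
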