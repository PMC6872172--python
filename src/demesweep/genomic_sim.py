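"""Forward infinite-sites simulation of a 600-kb region under a selective
sweep in a panmictic or two-deme population.

The population holds ``N_e`` haploid chromosomes per deme. Chromosomes are
paired into transient diploid individuals each generation (monoecious random
mating, selfing allowed); individual fitness is co-dominant in the selected
mutation: wild-type homozygote 1, heterozygote ``1+s``, mutant homozygote
``(1+s)^2``. Each offspring chromosome picks a parent individual in its deme
with probability proportional to fitness and receives one of the parent's two
chromosomes, recombined with probability ``c`` at a single uniform breakpoint
(``c = 0.006`` per transmitted chromosome per generation makes multiple
crossovers negligible). New mutations arrive as Poisson(``mu = 0.006``) per
transmitted chromosome, each creating a brand-new SNP at a uniform continuous
position (infinite sites). Whole individuals then migrate between demes with
probability ``m``, balanced so deme sizes stay exact; with deme size ``N``
this passes ``Nm`` chromosomes per generation per direction on average.

The region corresponds to 600 kb of human-like sequence (mutation rate
1e-8/bp, recombination 1 cM/Mb). The selected mutation arises on one
chromosome of deme d1 at 100 kb from the left region end; a run that loses it
is reset to the initial neutral state and re-run.

Rescaling by a factor ``lam`` (N/lam, s*lam, m*lam, mu*lam, c*lam) preserves
the population-scaled compounds N*s, N*m, N*mu, N*c; times shrink by lam.
The package's desk-scale default for tests and scaled studies is lam = 10.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .io_formats import HaplotypeSample, ScenarioConfig, derive_seeds, get_scenario

__all__ = [
    "GenomicConfig",
    "PopulationState",
    "Snapshot",
    "SnapshotSchedule",
    "TrainingSet",
    "rescale",
    "init_neutral_population",
    "step_generation",
    "run_scenario",
    "draw_samples",
    "make_training_sets",
    "STAGE_NAMES",
]

REGION_LENGTH = 600_000.0
SEL_POS = 100_000.0

FREQ_STAGES = {"f20s": 0.2, "f40s": 0.4, "f60s": 0.6, "f80s": 0.8, "f99.5s": 0.995}
OFFSET_STAGES = {"t1Kr": 1000, "t2Kr": 2000, "t3Kr": 3000, "t4Kr": 4000, "t5Kr": 5000}
STAGE_NAMES = ("neutral", *FREQ_STAGES, "f100s", *OFFSET_STAGES)


@dataclass(frozen=True)
class GenomicConfig:
    """Parameters of one genomic forward run (after any rescaling)."""

    deme_sizes: tuple[int, ...]  # haploid chromosomes per deme
    s: tuple[float, ...]  # per-deme selection coefficient of the mutant
    migration: float  # per-individual per-generation migration probability
    mu: float = 0.006  # region mutation rate per transmitted chromosome
    rec: float = 0.006  # region recombination probability per transmission
    region_length: float = REGION_LENGTH
    sel_pos: float = SEL_POS
    lam: float = 1.0

    def __post_init__(self) -> None:
        if any(n % 2 for n in self.deme_sizes):
            raise ValueError("deme sizes must be even (chromosome pairs)")
        if len(self.s) != len(self.deme_sizes):
            raise ValueError("one selection coefficient per deme")

    @property
    def n_demes(self) -> int:
        return len(self.deme_sizes)

    @property
    def total_chromosomes(self) -> int:
        return sum(self.deme_sizes)

    @classmethod
    def from_scenario(cls, scenario: ScenarioConfig | str, lam: float = 1.0):
        if isinstance(scenario, str):
            scenario = get_scenario(scenario)
        if scenario.n_demes == 1:
            sizes, s = (scenario.deme_size,), (scenario.s_d1,)
        else:
            sizes, s = (scenario.deme_size,) * 2, (scenario.s_d1, scenario.s_d2)
        cfg = cls(deme_sizes=sizes, s=s, migration=scenario.migration_rate)
        return rescale(cfg, lam) if lam != 1.0 else cfg


def rescale(config: GenomicConfig, lam: float) -> GenomicConfig:
    """Rescale population size down and rates up by ``lam``; generation times
    reported by rescaled runs compare to full scale after multiplying by
    ``lam``. Refuses to leave the weak-selection regime."""
    if lam < 1:
        raise ValueError("lam must be >= 1")
    if lam == 1:
        return config
    s = tuple(sd * lam for sd in config.s)
    if any(sd >= 0.5 for sd in s):
        raise ValueError("s*lam >= 0.5 breaks weak-selection rescaling")
    sizes = []
    for n in config.deme_sizes:
        scaled = int(round(n / lam))
        sizes.append(scaled + scaled % 2)
    return replace(
        config,
        deme_sizes=tuple(sizes),
        s=s,
        migration=config.migration * lam,
        mu=config.mu * lam,
        rec=config.rec * lam,
        lam=config.lam * lam,
    )


@dataclass
class PopulationState:
    """Whole-population haplotypes at one generation.

    ``haps`` rows are chromosomes, two consecutive rows per individual;
    ``ind_deme`` maps individuals to demes. ``sel_pos`` is set while the
    selected mutation is being tracked (its column is exempt from pruning and
    kept even when fixed).
    """

    haps: np.ndarray  # uint8 (n_chrom, n_sites)
    positions: np.ndarray  # float bp, strictly increasing
    ind_deme: np.ndarray  # int (n_chrom // 2,)
    config: GenomicConfig
    generation: int = 0
    sel_pos: float | None = None

    @property
    def chrom_deme(self) -> np.ndarray:
        return np.repeat(self.ind_deme, 2)

    def sel_column(self) -> int:
        if self.sel_pos is None:
            raise ValueError("no selected site is being tracked")
        j = int(np.searchsorted(self.positions, self.sel_pos))
        if j >= self.positions.size or self.positions[j] != self.sel_pos:
            raise KeyError("selected site not present")
        return j

    def sel_frequency(self, deme: int | None = None) -> float:
        try:
            col = self.haps[:, self.sel_column()]
        except KeyError:
            return 0.0
        if deme is None:
            return float(col.mean())
        return float(col[self.chrom_deme == deme].mean())

    def copy(self) -> "PopulationState":
        return PopulationState(
            haps=self.haps.copy(),
            positions=self.positions.copy(),
            ind_deme=self.ind_deme.copy(),
            config=self.config,
            generation=self.generation,
            sel_pos=self.sel_pos,
        )

    def insert_mutation(self, chromosome: int, position: float) -> None:
        """Add a new SNP carried by one chromosome (the sweep origin)."""
        j = int(np.searchsorted(self.positions, position))
        if j < self.positions.size and self.positions[j] == position:
            raise ValueError("position already segregating")
        col = np.zeros((self.haps.shape[0], 1), dtype=np.uint8)
        col[chromosome] = 1
        self.haps = np.concatenate(
            [self.haps[:, :j], col, self.haps[:, j:]], axis=1
        )
        self.positions = np.insert(self.positions, j, position)


# ---------------------------------------------------------------------------
# neutral initial state


def init_neutral_population(
    config: GenomicConfig, seed: int, backend: str = "coalescent",
    burnin_generations: int | None = None,
) -> PopulationState:
    """Equilibrium neutral population of all chromosomes in all demes.

    ``coalescent`` uses msprime (the ms-style backend: island model with the
    scenario's deme sizes and migration, infinite-sites mutations at
    continuous positions). ``burn-in`` starts from a blank population and
    runs the forward engine neutrally for ``burnin_generations`` (default
    20 * total chromosomes) - much slower, used as a cross-check.
    """
    if backend == "coalescent":
        return _coalescent_init(config, seed)
    if backend in ("burn-in", "burnin"):
        return _burnin_init(config, seed, burnin_generations)
    raise ValueError(f"unknown backend {backend!r}")


def _coalescent_init(config: GenomicConfig, seed: int) -> PopulationState:
    import msprime

    demog = msprime.Demography()
    for d, n in enumerate(config.deme_sizes):
        demog.add_population(name=f"d{d + 1}", initial_size=n)
    if config.n_demes > 1:
        if config.migration <= 0:
            raise ValueError("multi-deme neutral init requires migration > 0")
        demog.set_symmetric_migration_rate(
            [f"d{d + 1}" for d in range(config.n_demes)], config.migration
        )
    ts = msprime.sim_ancestry(
        samples={f"d{d + 1}": n for d, n in enumerate(config.deme_sizes)},
        demography=demog,
        ploidy=1,
        sequence_length=config.region_length,
        recombination_rate=config.rec / config.region_length,
        discrete_genome=False,
        random_seed=(seed % (2**31 - 2)) + 1,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=config.mu / config.region_length,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=(seed % (2**31 - 2)) + 2,
    )
    haps = ts.genotype_matrix().T.astype(np.uint8)
    positions = np.array([site.position for site in ts.sites()])
    ind_deme = np.repeat(
        np.arange(config.n_demes), np.array(config.deme_sizes) // 2
    )
    return PopulationState(
        haps=np.ascontiguousarray(haps),
        positions=positions,
        ind_deme=ind_deme,
        config=config,
    )


def neutral_coalescent_samples(
    config: GenomicConfig, n_samples: int, sample_size: int, seed: int
) -> list[HaplotypeSample]:
    """Independent neutral samples drawn directly from the coalescent.

    For a panmictic configuration each sample is ``sample_size`` chromosomes;
    for a two-deme configuration ``sample_size`` chromosomes are simulated
    per deme and returned as one two-deme sample (callers may split demes
    into independent one-deme samples, as the neutral-background protocol
    does). Far cheaper than materialising whole populations.
    """
    import msprime

    demog = msprime.Demography()
    for d, n in enumerate(config.deme_sizes):
        demog.add_population(name=f"d{d + 1}", initial_size=n)
    if config.n_demes > 1:
        demog.set_symmetric_migration_rate(
            [f"d{d + 1}" for d in range(config.n_demes)], config.migration
        )
    seeds = derive_seeds(seed, 2 * n_samples, key=11)
    out = []
    for i in range(n_samples):
        ts = msprime.sim_ancestry(
            samples={f"d{d + 1}": sample_size for d in range(config.n_demes)},
            demography=demog,
            ploidy=1,
            sequence_length=config.region_length,
            recombination_rate=config.rec / config.region_length,
            discrete_genome=False,
            random_seed=int(seeds[2 * i]) + 1,
        )
        ts = msprime.sim_mutations(
            ts,
            rate=config.mu / config.region_length,
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
            random_seed=int(seeds[2 * i + 1]) + 1,
        )
        haps = ts.genotype_matrix().T.astype(np.uint8)
        labels = np.repeat(np.arange(config.n_demes) + 1, sample_size)
        if config.n_demes == 1:
            labels = np.zeros(sample_size, dtype=int)
        out.append(
            HaplotypeSample(
                matrix=np.ascontiguousarray(haps),
                positions=np.array([s.position for s in ts.sites()]),
                region_length=config.region_length,
                deme_labels=labels,
            )
        )
    return out


def _burnin_init(
    config: GenomicConfig, seed: int, generations: int | None
) -> PopulationState:
    rng = np.random.default_rng(seed)
    if generations is None:
        generations = 20 * config.total_chromosomes
    state = PopulationState(
        haps=np.zeros((config.total_chromosomes, 0), dtype=np.uint8),
        positions=np.empty(0),
        ind_deme=np.repeat(
            np.arange(config.n_demes), np.array(config.deme_sizes) // 2
        ),
        config=config,
    )
    for _ in range(generations):
        state = step_generation(state, config, rng)
    return state


# ---------------------------------------------------------------------------
# one generation


def step_generation(
    state: PopulationState, config: GenomicConfig, rng: np.random.Generator
) -> PopulationState:
    """Advance the population by one generation: fitness-weighted diploid
    reproduction with recombination and mutation, then balanced individual
    migration, then pruning of columns fixed or lost population-wide."""
    L = config.region_length
    positions = state.positions
    haps = state.haps
    n_total = haps.shape[0]

    try:
        sel_col = state.sel_column() if state.sel_pos is not None else None
    except KeyError:
        sel_col = None
    sel_alleles = haps[:, sel_col] if sel_col is not None else None

    children_blocks: list[np.ndarray] = []
    deme_order: list[int] = []
    for d in range(config.n_demes):
        ind_ids = np.flatnonzero(state.ind_deme == d)
        n_ind = ind_ids.size
        chrom_a = 2 * ind_ids
        chrom_b = chrom_a + 1
        n_off = config.deme_sizes[d]

        if sel_alleles is not None and config.s[d] != 0:
            g = sel_alleles[chrom_a].astype(np.int64) + sel_alleles[chrom_b]
            w = (1.0 + config.s[d]) ** g
            p = w / w.sum()
            parent = rng.choice(n_ind, size=n_off, p=p)
        else:
            parent = rng.integers(0, n_ind, size=n_off)

        first = rng.integers(0, 2, size=n_off, dtype=np.int64)
        chosen = np.where(first == 0, chrom_a[parent], chrom_b[parent])
        homolog = np.where(first == 0, chrom_b[parent], chrom_a[parent])
        children = haps[chosen].copy()
        rec_rows = np.flatnonzero(rng.random(n_off) < config.rec)
        for r in rec_rows:
            bp = rng.uniform(0.0, L)
            right = positions >= bp
            children[r, right] = haps[homolog[r], right]
        children_blocks.append(children)
        deme_order.append(d)

    children = (
        np.concatenate(children_blocks, axis=0)
        if len(children_blocks) > 1
        else children_blocks[0]
    )
    ind_deme = np.repeat(
        np.array(deme_order), np.array([config.deme_sizes[d] for d in deme_order]) // 2
    )

    # new mutations: Poisson(mu) per transmitted chromosome
    n_mut = rng.poisson(config.mu * children.shape[0])
    if n_mut:
        mut_rows = rng.integers(0, children.shape[0], size=n_mut)
        mut_pos = rng.uniform(0.0, L, size=n_mut)
        while np.isin(mut_pos, positions).any() or np.unique(mut_pos).size < n_mut:
            mut_pos = rng.uniform(0.0, L, size=n_mut)  # infinite-sites collision
        cols = np.zeros((children.shape[0], n_mut), dtype=np.uint8)
        cols[mut_rows, np.arange(n_mut)] = 1
        children = np.concatenate([children, cols], axis=1)
        positions = np.concatenate([positions, mut_pos])

    # balanced migration of whole individuals (label swap keeps sizes exact)
    if config.n_demes == 2 and config.migration > 0:
        n_ind_deme = config.deme_sizes[0] // 2
        k = rng.binomial(n_ind_deme, config.migration)
        if k:
            ids0 = rng.choice(np.flatnonzero(ind_deme == 0), size=k, replace=False)
            ids1 = rng.choice(np.flatnonzero(ind_deme == 1), size=k, replace=False)
            ind_deme[ids0] = 1
            ind_deme[ids1] = 0

    # prune fixed/lost columns (selected site exempt) and keep columns sorted
    counts = children.sum(axis=0)
    keep = (counts > 0) & (counts < children.shape[0])
    if state.sel_pos is not None:
        keep |= positions == state.sel_pos
    order = np.argsort(positions[keep], kind="stable")
    sel = np.flatnonzero(keep)[order]
    return PopulationState(
        haps=np.ascontiguousarray(children[:, sel]),
        positions=positions[sel],
        ind_deme=ind_deme,
        config=config,
        generation=state.generation + 1,
        sel_pos=state.sel_pos,
    )


# ---------------------------------------------------------------------------
# snapshot schedules and scenario runs


@dataclass(frozen=True)
class SnapshotSchedule:
    """When to photograph the population during a sweep run.

    The standard schedule fires per deme at within-deme frequencies
    20/40/60/80/99.5% and at 1000..5000 (full-scale) generations after that
    deme reached 99.5%, plus once at global fixation: 21 in-run snapshots for
    a two-deme run, 11 for a panmictic one (the initial neutral state is the
    extra time point that completes the 22/12 analysis stages). Fixed-interval
    mode (used for m0.2L) snapshots every ``fixed_interval`` full-scale
    generations up to ``max_generations`` regardless of fixation.
    """

    freq_triggers: tuple[float, ...] = tuple(FREQ_STAGES.values())
    offsets: tuple[int, ...] = tuple(OFFSET_STAGES.values())
    fixation: bool = True
    fixed_interval: int | None = None
    max_generations: int | None = None
    wanted: frozenset | None = None  # {(stage, deme)} subset to collect

    @classmethod
    def standard(cls, wanted: Iterable[tuple[str, int]] | None = None):
        return cls(wanted=None if wanted is None else frozenset(wanted))

    @classmethod
    def fixed(cls, interval: int = 100, max_generations: int = 20_000):
        return cls(
            freq_triggers=(),
            offsets=(),
            fixation=False,
            fixed_interval=interval,
            max_generations=max_generations,
        )

    def n_snapshots(self, n_demes: int) -> int:
        if self.fixed_interval is not None:
            return self.max_generations // self.fixed_interval
        return n_demes * (len(self.freq_triggers) + len(self.offsets)) + int(
            self.fixation
        )


@dataclass
class Snapshot:
    stage: str
    deme: int  # deme whose trigger fired (0 for global/panmictic stages)
    generation: int  # forward generations since sweep start (rescaled units)
    state: PopulationState


@dataclass
class ScenarioRun:
    snapshots: list[Snapshot]
    resets: int
    truncated: bool
    initial: PopulationState  # the neutral state the sweep started from
    final: PopulationState


def run_scenario(
    config: GenomicConfig,
    schedule: SnapshotSchedule,
    seed: int,
    initial: PopulationState | None = None,
    safety_cap: int = 500_000,
) -> ScenarioRun:
    """Run one sweep replicate, restarting from the initial neutral state
    whenever the adaptive allele is lost, and collect scheduled snapshots.

    The adaptive mutation is inserted on one chromosome of deme d1 at the
    focal position (100 kb). Snapshot generations are counted from sweep
    start; offsets are interpreted as full-scale generations and divided by
    the rescaling factor.
    """
    rng = np.random.default_rng(seed)
    if initial is None:
        initial = init_neutral_population(config, int(rng.integers(2**31 - 1)))
    base = initial.copy()
    origin_ind = np.flatnonzero(base.ind_deme == 0)[0]
    base.insert_mutation(2 * origin_ind, config.sel_pos)
    base.sel_pos = config.sel_pos
    base.generation = 0

    lam = config.lam
    scaled_offsets = [max(1, int(round(o / lam))) for o in schedule.offsets]
    max_gen = (
        None
        if schedule.max_generations is None
        else max(1, int(round(schedule.max_generations / lam)))
    )
    interval = (
        None
        if schedule.fixed_interval is None
        else max(1, int(round(schedule.fixed_interval / lam)))
    )

    def wanted(stage: str, deme: int) -> bool:
        return schedule.wanted is None or (stage, deme) in schedule.wanted

    resets = 0
    while True:  # restart loop
        state = base.copy()
        snaps: list[Snapshot] = []
        fired: set[tuple[str, int]] = set()
        t995: dict[int, int] = {}
        lost = False
        pending = {
            (stage, d)
            for d in range(config.n_demes)
            for stage in (*FREQ_STAGES, *OFFSET_STAGES)
            if (FREQ_STAGES.get(stage) is not None and FREQ_STAGES[stage] in schedule.freq_triggers)
            or (OFFSET_STAGES.get(stage) is not None and OFFSET_STAGES[stage] in schedule.offsets)
        }
        if schedule.fixation:
            pending.add(("f100s", 0))
        if schedule.wanted is not None:
            pending &= set(schedule.wanted)

        while True:
            state = step_generation(state, config, rng)
            gen = state.generation
            freq_all = state.sel_frequency()
            if freq_all == 0.0:
                lost = True
                break

            if interval is not None:
                if gen % interval == 0:
                    snaps.append(Snapshot(f"g{gen * int(lam)}", 0, gen, state.copy()))
                if max_gen is not None and gen >= max_gen:
                    break
                continue

            for d in range(config.n_demes):
                fd = state.sel_frequency(d)
                for stage, thr in FREQ_STAGES.items():
                    if thr in schedule.freq_triggers and (stage, d) not in fired:
                        if fd >= thr:
                            fired.add((stage, d))
                            pending.discard((stage, d))
                            if wanted(stage, d):
                                snaps.append(Snapshot(stage, d, gen, state.copy()))
                            if stage == "f99.5s":
                                t995[d] = gen
                for (stage, off), so in zip(OFFSET_STAGES.items(), scaled_offsets):
                    if off in schedule.offsets and (stage, d) not in fired:
                        if d in t995 and gen >= t995[d] + so:
                            fired.add((stage, d))
                            pending.discard((stage, d))
                            if wanted(stage, d):
                                snaps.append(Snapshot(stage, d, gen, state.copy()))
            if schedule.fixation and ("f100s", 0) not in fired and freq_all >= 1.0:
                fired.add(("f100s", 0))
                pending.discard(("f100s", 0))
                if wanted("f100s", 0):
                    snaps.append(Snapshot("f100s", 0, gen, state.copy()))
            if not pending:
                break
            if gen >= safety_cap or (max_gen is not None and gen >= max_gen):
                return ScenarioRun(snaps, resets, True, initial, state)

        if not lost:
            return ScenarioRun(
                snaps, resets, interval is not None and bool(max_gen), initial, state
            )
        resets += 1


# ---------------------------------------------------------------------------
# sampling


def draw_samples(
    snapshot: Snapshot | PopulationState,
    n_samples: int = 50,
    per_deme: int = 50,
    mixed: bool = False,
    seed: int = 0,
) -> list[HaplotypeSample]:
    """Random samples of chromosomes from a population snapshot.

    Default: ``per_deme`` chromosomes from each deme without replacement
    (deme labels 1, 2). ``mixed`` draws ``per_deme`` chromosomes from the
    pooled population without deme stratification (labels 0). Columns
    monomorphic within a sample are dropped, except the selected site.
    """
    state = snapshot.state if isinstance(snapshot, Snapshot) else snapshot
    rng = np.random.default_rng(seed)
    cfg = state.config
    chrom_deme = state.chrom_deme
    pool = HaplotypeSample(
        matrix=state.haps,
        positions=state.positions,
        region_length=cfg.region_length,
        deme_labels=chrom_deme + 1,
        selected_pos=state.sel_pos,
    )
    out = []
    for _ in range(n_samples):
        if mixed or cfg.n_demes == 1:
            if per_deme > state.haps.shape[0]:
                raise ValueError("sample size exceeds population")
            idx = rng.choice(state.haps.shape[0], size=per_deme, replace=False)
            sample = pool.subset_haplotypes(np.sort(idx))
            if mixed:
                sample.deme_labels = np.zeros(per_deme, dtype=int)
        else:
            parts = []
            for d in range(cfg.n_demes):
                ids = np.flatnonzero(chrom_deme == d)
                if per_deme > ids.size:
                    raise ValueError("sample size exceeds deme")
                parts.append(np.sort(rng.choice(ids, size=per_deme, replace=False)))
            sample = pool.subset_haplotypes(np.concatenate(parts))
        out.append(sample)
    return out


# ---------------------------------------------------------------------------
# classifier training material


#: training stages and the snapshot stage each one photographs
TRAIN_STAGES = ("f60s", "f80s", "f99.5s", "f100s", "t1Kr")

SOFT_START_FREQ = 0.10
SOFT_FREQ_TOL = 0.02


@dataclass
class TrainingSet:
    """Per-stage hard/soft sweep samples plus the shared neutral set."""

    stage: str  # one of TRAIN_STAGES or "mix"
    hard: list[HaplotypeSample]
    soft: list[HaplotypeSample]
    neutral: list[HaplotypeSample]


def _soft_candidate(state: PopulationState, config: GenomicConfig) -> float:
    """Standing neutral variant with frequency closest to 10% (within the
    tolerance band) nearest to the focal 100-kb position; KeyError if none."""
    freqs = state.haps.mean(axis=0)
    ok = np.abs(freqs - SOFT_START_FREQ) <= SOFT_FREQ_TOL
    if not ok.any():
        raise KeyError("no standing variant near 10% frequency")
    cand = np.flatnonzero(ok)
    j = cand[np.argmin(np.abs(state.positions[cand] - config.sel_pos))]
    return float(state.positions[j])


def _sweep_stage_snapshots(
    config: GenomicConfig,
    soft: bool,
    seed: int,
    stages: Sequence[str],
    max_redraws: int = 20,
) -> dict[str, PopulationState]:
    """One panmictic sweep run snapshotted at the requested training stages.

    Hard sweeps start from a brand-new mutation at 100 kb; soft sweeps start
    selecting a standing variant at ~10% sample frequency near 100 kb (the
    population is re-drawn if no eligible variant exists).
    """
    rng = np.random.default_rng(seed)
    lam = config.lam
    want = set(stages)
    for _ in range(max_redraws):
        initial = init_neutral_population(config, int(rng.integers(2**31 - 1)))
        base = initial.copy()
        if soft:
            try:
                base.sel_pos = _soft_candidate(base, config)
            except KeyError:
                continue
        else:
            base.insert_mutation(0, config.sel_pos)
            base.sel_pos = config.sel_pos
        base.generation = 0

        state = base.copy()
        out: dict[str, PopulationState] = {}
        t995 = None
        lost = False
        while True:
            state = step_generation(state, config, rng)
            f = state.sel_frequency()
            if f == 0.0:
                lost = True
                break
            for stage, thr in FREQ_STAGES.items():
                if stage in want and stage not in out and f >= thr:
                    out[stage] = state.copy()
            if f >= 0.995 and t995 is None:
                t995 = state.generation
            if "f100s" in want and "f100s" not in out and f >= 1.0:
                out["f100s"] = state.copy()
            if (
                "t1Kr" in want
                and "t1Kr" not in out
                and t995 is not None
                and state.generation >= t995 + max(1, int(round(1000 / lam)))
            ):
                out["t1Kr"] = state.copy()
            if want <= set(out):
                return out
        if lost and not soft:
            continue  # hard sweep lost: restart with a fresh population
        if lost and soft:
            continue  # lost standing variant: re-draw
    raise RuntimeError("could not complete a sweep run for training data")


def make_training_sets(
    config: GenomicConfig,
    seed: int,
    stages: Sequence[str] = TRAIN_STAGES,
    n_per_class: int = 1000,
    n_neutral: int = 2000,
    samples_per_population: int = 50,
    sample_size: int = 50,
    include_mix: bool = True,
) -> list[TrainingSet]:
    """Stage-labelled training material for the two-stage classifier.

    Per stage: ``n_per_class`` hard-sweep and ``n_per_class`` soft-sweep
    samples of ``sample_size`` haplotypes from independent panmictic sweep
    runs (``samples_per_population`` samples drawn per run), plus a shared
    set of ``n_neutral`` neutral samples. The ``mix`` set pools one fifth of
    each stage per class.
    """
    if config.n_demes != 1:
        raise ValueError("training sets use a panmictic configuration")
    n_pops = -(-n_per_class // samples_per_population)
    hard_seeds = derive_seeds(seed, n_pops, key=1)
    soft_seeds = derive_seeds(seed, n_pops, key=2)
    neutral_seeds = derive_seeds(seed, n_neutral, key=3)
    draw_seeds = derive_seeds(seed, 4 * n_pops + 8, key=4)

    per_stage_hard: dict[str, list[HaplotypeSample]] = {s: [] for s in stages}
    per_stage_soft: dict[str, list[HaplotypeSample]] = {s: [] for s in stages}
    di = 0
    for soft, seeds, store in (
        (False, hard_seeds, per_stage_hard),
        (True, soft_seeds, per_stage_soft),
    ):
        for sd in seeds:
            snaps = _sweep_stage_snapshots(config, soft, int(sd), stages)
            for stage in stages:
                store[stage].extend(
                    draw_samples(
                        snaps[stage],
                        n_samples=samples_per_population,
                        per_deme=sample_size,
                        seed=int(draw_seeds[di % len(draw_seeds)]),
                    )
                )
            di += 1
    neutral: list[HaplotypeSample] = []
    for sd in neutral_seeds:
        pop = init_neutral_population(config, int(sd))
        neutral.extend(
            draw_samples(pop, n_samples=1, per_deme=sample_size, seed=int(sd))
        )

    sets = [
        TrainingSet(
            stage=s,
            hard=per_stage_hard[s][:n_per_class],
            soft=per_stage_soft[s][:n_per_class],
            neutral=neutral,
        )
        for s in stages
    ]
    if include_mix:
        fifth = max(1, n_per_class // len(stages))
        sets.append(
            TrainingSet(
                stage="mix",
                hard=[x for s in stages for x in per_stage_hard[s][:fifth]],
                soft=[x for s in stages for x in per_stage_soft[s][:fifth]],
                neutral=neutral,
            )
        )
    return sets
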