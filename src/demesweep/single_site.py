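"""Forward-in-time Wright-Fisher dynamics of a single adaptive allele in
2-3 demes with migration, selection and drift.

Model
-----
Each deme holds ``N_e`` haploid chromosomes. Per generation, in order:

1. *migration* - deterministic mixing of allele frequencies along the deme
   graph, each edge passing an expected ``Nm`` chromosomes per direction;
2. *selection* - deterministic haploid genic update
   ``p' = p (1+s) / (1 + p s)`` with a per-deme coefficient ``s_d``;
3. *drift* - one binomial draw of the allele count per deme.

The allele arises as a single copy in the origin deme (d1 for two-deme
models, the hidden deme d0 for three-deme models). A run in which the
allele is lost from every deme is discarded and restarted with fresh
randomness, which conditions the reported trajectories on eventual global
fixation without biasing the within-run dynamics. "Completion" of
adaptation within a deme is the first generation its frequency reaches
99.5% (the last half percent is drift-dominated and highly variable), and
the *selection phase* of a deme is the time from 5% to 99.5%.

Three-deme migration layouts: ``connected`` (all pairs), ``forked``
(d0-d1 and d0-d2), ``stepping`` (d0-d1-d2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DemeSpec",
    "Trajectory",
    "TimingSummary",
    "simulate_single_site",
    "simulate_timing_batch",
    "summarize_timing",
    "run_grid",
    "trajectory_stats",
    "logistic_phase_time",
    "log_ne_phase_ratio",
    "two_deme_rows",
    "three_deme_rows",
    "COMPLETION_FREQ",
    "PHASE_START_FREQ",
]

COMPLETION_FREQ = 0.995
PHASE_START_FREQ = 0.05

LAYOUTS = ("connected", "forked", "stepping")

# default per-replicate generation cap; at Nm = 0.02 the waiting time for a
# successful migrant is exponential with mean of order 1/(Nm * 2s) ~ 1e3
# generations, so the cap is far in the tail
MAX_GENERATIONS = 2_000_000


@dataclass(frozen=True)
class DemeSpec:
    """Parameters of one single-site scenario.

    ``sizes`` and ``s`` are per deme, ordered (d1, d2) for two-deme models
    and (d0, d1, d2) for three-deme models. ``Nm`` is the expected number of
    migrant chromosomes per generation per direction along every edge of the
    migration graph.
    """

    sizes: tuple[int, ...]
    s: tuple[float, ...]
    Nm: float
    layout: str = "two-deme"  # or connected / forked / stepping
    origin: int = 0

    def __post_init__(self) -> None:
        if len(self.sizes) != len(self.s):
            raise ValueError("sizes and s must have equal length")
        if len(self.sizes) not in (1, 2, 3):
            raise ValueError("1-3 demes supported")
        if any(n < 2 for n in self.sizes):
            raise ValueError("deme sizes must be >= 2")
        if any(sd < 0 for sd in self.s):
            raise ValueError("selection coefficients must be >= 0")
        if len(self.sizes) == 3 and self.layout not in LAYOUTS:
            raise ValueError(f"three-deme layout must be one of {LAYOUTS}")

    @property
    def n_demes(self) -> int:
        return len(self.sizes)

    def migration_matrix(self) -> np.ndarray:
        """Row-stochastic mixing matrix M with ``p' = M @ p``.

        Deme i receives an expected Nm chromosomes per generation from each
        neighbour, i.e. a fraction Nm / N_i of its next generation.
        """
        d = self.n_demes
        edges: list[tuple[int, int]]
        if d == 1:
            edges = []
        elif d == 2:
            edges = [(0, 1)]
        elif self.layout == "connected":
            edges = [(0, 1), (0, 2), (1, 2)]
        elif self.layout == "forked":
            edges = [(0, 1), (0, 2)]
        else:  # stepping stone d0 - d1 - d2
            edges = [(0, 1), (1, 2)]
        M = np.eye(d)
        for i, j in edges:
            mi = self.Nm / self.sizes[i]
            mj = self.Nm / self.sizes[j]
            M[i, i] -= mi
            M[i, j] += mi
            M[j, j] -= mj
            M[j, i] += mj
        if np.any(np.diag(M) < 0):
            raise ValueError("Nm too large for deme sizes (emigration > deme)")
        return M


@dataclass
class Trajectory:
    """Per-generation allele frequency per deme of one conditioned run."""

    freqs: np.ndarray  # (generations+1, n_demes); row 0 = initial state
    spec: DemeSpec
    seed: int
    restarts: int  # discarded runs (allele lost everywhere) before this one

    @property
    def n_generations(self) -> int:
        return self.freqs.shape[0] - 1


@dataclass
class TimingSummary:
    """First-passage timing of one trajectory (generations; NaN = never).

    ``t995`` marks "completion" of adaptation at the 99.5% threshold; ``tfix``
    is the literal first passage to frequency 1 within the deme (the last half
    percent is a drift-dominated tail that can add a noticeable delay).
    """

    t5: np.ndarray  # per deme, first generation frequency >= 5%
    t995: np.ndarray  # per deme, first generation frequency >= 99.5%
    tfix: np.ndarray  # per deme, first generation frequency = 1
    waiting_period: float  # last generation with no adaptive copy in d1/d2

    @property
    def selection_phase(self) -> np.ndarray:
        return self.t995 - self.t5


def _first_passage(freqs: np.ndarray, threshold: float) -> np.ndarray:
    hit = freqs >= threshold
    out = np.full(freqs.shape[1], np.nan)
    for d in range(freqs.shape[1]):
        idx = np.flatnonzero(hit[:, d])
        if idx.size:
            out[d] = idx[0]
    return out


def summarize_timing(traj: Trajectory) -> TimingSummary:
    """Timing summary of a completed trajectory.

    The waiting period is the last generation at which the recipient demes
    (all demes except a three-deme model's hidden origin d0) contain no copy
    of the adaptive allele; for two-deme models, where the allele is present
    in d1 from generation 0 on, it is 0.
    """
    t5 = _first_passage(traj.freqs, PHASE_START_FREQ)
    t995 = _first_passage(traj.freqs, COMPLETION_FREQ)
    tfix = _first_passage(traj.freqs, 1.0)
    recipients = slice(1, None) if traj.spec.n_demes == 3 else slice(None)
    present = traj.freqs[:, recipients].sum(axis=1) > 0
    arrival = np.flatnonzero(present)
    waiting = float(arrival[0] - 1) if arrival.size else np.nan
    return TimingSummary(
        t5=t5, t995=t995, tfix=tfix, waiting_period=max(waiting, 0.0)
    )


def simulate_single_site(
    spec: DemeSpec, seed: int, max_generations: int = MAX_GENERATIONS
) -> Trajectory:
    """One full trajectory, conditioned on global fixation, with the
    per-generation frequency record kept.

    Runs in which the allele is lost everywhere are discarded and restarted
    with fresh derived seeds; the returned trajectory ends at the first
    generation every deme is at frequency 1 (or, if a deme is truncated by
    ``max_generations``, at the cap, flagged by the missing fixation row).
    """
    rng = np.random.default_rng(seed)
    N = np.array(spec.sizes)
    s = np.array(spec.s)
    M = spec.migration_matrix()
    restarts = 0
    while True:
        counts = np.zeros(spec.n_demes, dtype=np.int64)
        counts[spec.origin] = 1
        rows = [counts / N]
        lost = False
        for _ in range(max_generations):
            p = M @ (counts / N)
            p = p * (1 + s) / (1 + p * s)
            counts = rng.binomial(N, p)
            rows.append(counts / N)
            if counts.sum() == 0:
                lost = True
                break
            if np.all(counts == N):
                break
        if not lost:
            return Trajectory(
                freqs=np.array(rows), spec=spec, seed=seed, restarts=restarts
            )
        restarts += 1


def simulate_timing_batch(
    spec: DemeSpec,
    replicates: int,
    seed: int,
    max_generations: int = MAX_GENERATIONS,
) -> pd.DataFrame:
    """Vectorised timing of many conditioned replicates.

    All replicates advance in lock-step as numpy arrays; a replicate that
    loses the allele everywhere is reset in place (equivalent to discarding
    and re-running it), and one that reaches global fixation (the absorbing
    state) is frozen. Returns one row per replicate with per-deme
    t5 / t99.5 / tfix / selection phase, the waiting period and the restart
    count.
    """
    rng = np.random.default_rng(seed)
    R, D = replicates, spec.n_demes
    N = np.array(spec.sizes)
    s = np.array(spec.s)
    M = spec.migration_matrix()
    recipients = np.arange(1, D) if D == 3 else np.arange(D)

    counts = np.zeros((R, D), dtype=np.int64)
    counts[:, spec.origin] = 1
    gen = np.zeros(R, dtype=np.int64)  # generations since current run start
    t5 = np.full((R, D), np.nan)
    t995 = np.full((R, D), np.nan)
    tfix = np.full((R, D), np.nan)
    arrival = np.full(R, np.nan)  # first generation with a copy in d1/d2
    if spec.origin in recipients:
        arrival[:] = 0.0
    restarts = np.zeros(R, dtype=np.int64)
    active = np.ones(R, dtype=bool)

    while active.any():
        idx = np.flatnonzero(active)
        c = counts[idx]
        p = (c / N) @ M.T
        p = p * (1 + s) / (1 + p * s)
        c = rng.binomial(N[None, :], p)
        counts[idx] = c
        gen[idx] += 1

        freq = c / N
        g = gen[idx, None]
        hit5 = np.isnan(t5[idx]) & (freq >= PHASE_START_FREQ)
        t5[idx] = np.where(hit5, g, t5[idx])
        hit995 = np.isnan(t995[idx]) & (freq >= COMPLETION_FREQ)
        t995[idx] = np.where(hit995, g, t995[idx])
        hitfix = np.isnan(tfix[idx]) & (c == N[None, :])
        tfix[idx] = np.where(hitfix, g, tfix[idx])
        arrived = np.isnan(arrival[idx]) & (c[:, recipients].sum(axis=1) > 0)
        arrival[idx] = np.where(arrived, g[:, 0], arrival[idx])

        # restart replicates that lost the allele everywhere
        lost = c.sum(axis=1) == 0
        if lost.any():
            li = idx[lost]
            counts[li] = 0
            counts[li, spec.origin] = 1
            gen[li] = 0
            t5[li] = np.nan
            t995[li] = np.nan
            tfix[li] = np.nan
            arrival[li] = 0.0 if spec.origin in recipients else np.nan
            restarts[li] += 1

        # a replicate is finished once globally fixed (absorbing state)
        done = (counts[idx] == N[None, :]).all(axis=1)
        truncated = gen[idx] >= max_generations
        active[idx[done | truncated]] = False

    data: dict[str, np.ndarray] = {"rep": np.arange(R), "Nm": np.full(R, spec.Nm)}
    names = (
        ["d1", "d2"]
        if D == 2
        else (["d0", "d1", "d2"] if D == 3 else ["d1"])
    )
    for d, name in enumerate(names):
        data[f"t5_{name}"] = t5[:, d]
        data[f"t995_{name}"] = t995[:, d]
        data[f"tfix_{name}"] = tfix[:, d]
        data[f"phase_{name}"] = t995[:, d] - t5[:, d]
    data["waiting_period"] = np.maximum(arrival - 1.0, 0.0)
    data["restarts"] = restarts
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# the parameter grid


def two_deme_rows() -> list[dict]:
    """The 11 two-deme scenario rows (sizes and per-deme s); rows flagged
    ``skip_lowest_nm`` are not executed at Nm = 0.02 (an s = 0 deme would
    wait practically forever for fixation there)."""
    rows = [
        dict(sizes=(10_000, 10_000), s=(0.005, 0.005)),
        dict(sizes=(10_000, 10_000), s=(0.02, 0.02)),
        dict(sizes=(10_000, 10_000), s=(0.05, 0.05)),
        dict(sizes=(10_000, 10_000), s=(0.1, 0.1)),
        dict(sizes=(10_000, 10_000), s=(0.02, 0.05)),
        dict(sizes=(10_000, 10_000), s=(0.02, 0.0), skip_lowest_nm=True),
        dict(sizes=(10_000, 10_000), s=(0.05, 0.02)),
        dict(sizes=(5_000, 10_000), s=(0.02, 0.02)),
        dict(sizes=(1_000, 10_000), s=(0.02, 0.02)),
        dict(sizes=(10_000, 5_000), s=(0.02, 0.02)),
        dict(sizes=(10_000, 1_000), s=(0.02, 0.02)),
    ]
    for i, r in enumerate(rows):
        r.setdefault("skip_lowest_nm", False)
        r["row"] = i
    return rows


def three_deme_rows() -> list[dict]:
    """The 8 three-deme scenario rows (s ordered d0, d1, d2)."""
    rows = [
        dict(s=(0.005, 0.005, 0.005)),
        dict(s=(0.02, 0.02, 0.02)),
        dict(s=(0.05, 0.05, 0.05)),
        dict(s=(0.1, 0.1, 0.1)),
        dict(s=(0.02, 0.0, 0.02), skip_lowest_nm=True),
        dict(s=(0.02, 0.005, 0.02)),
        dict(s=(0.02, 0.05, 0.02)),
        dict(s=(0.02, 0.05, 0.05)),
    ]
    for i, r in enumerate(rows):
        r.setdefault("skip_lowest_nm", False)
        r["sizes"] = (10_000, 10_000, 10_000)
        r["row"] = i
    return rows


MIGRATION_RATES = (0.02, 0.2, 2.0, 20.0, 200.0)


def enumerate_grid(
    rows: Iterable[dict] | None = None,
    rates: Iterable[float] = MIGRATION_RATES,
    layouts: Iterable[str] | None = None,
) -> list[dict]:
    """Enumerate rows x rates (x layouts) into per-combination records with
    an ``execute`` flag implementing the low-migration exclusion rule.

    The default two-deme grid yields 55 combinations, the three-deme grid
    (all three layouts) 120.
    """
    if rows is None:
        rows = two_deme_rows()
    combos = []
    for r in rows:
        for nm in rates:
            layout_list = (
                list(layouts) if layouts is not None else (
                    list(LAYOUTS) if len(r["sizes"]) == 3 else ["two-deme"]
                )
            )
            for lay in layout_list:
                combos.append(
                    dict(
                        row=r["row"],
                        sizes=r["sizes"],
                        s=r["s"],
                        Nm=nm,
                        layout=lay,
                        execute=not (r["skip_lowest_nm"] and nm == min(rates)),
                    )
                )
    return combos


def run_grid(
    rows: Iterable[dict] | None = None,
    rates: Iterable[float] = MIGRATION_RATES,
    layouts: Iterable[str] | None = None,
    replicates: int = 1000,
    seed: int = 0,
    max_generations: int = MAX_GENERATIONS,
) -> pd.DataFrame:
    """Run the single-site grid; one output row per executed replicate."""
    from .io_formats import derive_seeds

    combos = enumerate_grid(rows, rates, layouts)
    seeds = derive_seeds(seed, len(combos))
    frames = []
    for combo, sd in zip(combos, seeds):
        if not combo["execute"]:
            continue
        spec = DemeSpec(
            sizes=combo["sizes"],
            s=combo["s"],
            Nm=combo["Nm"],
            layout=combo["layout"],
        )
        df = simulate_timing_batch(
            spec, replicates, int(sd), max_generations=max_generations
        )
        df.insert(0, "layout", combo["layout"])
        df.insert(0, "row_id", combo["row"])
        df["seed"] = int(sd)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def trajectory_stats(table: pd.DataFrame, y: str) -> dict:
    """Pearson correlation of log10(Nm) with a timing column, pooled over
    replicates. Returns r, r-squared and the p-value; a zero-variance y gives
    r-squared 0 with a ``degenerate`` flag."""
    sub = table[["Nm", y]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 rows")
    x = np.log10(sub["Nm"].to_numpy())
    yv = sub[y].to_numpy(dtype=float)
    if np.ptp(yv) == 0 or np.ptp(x) == 0:
        return {"r": 0.0, "r2": 0.0, "p": np.nan, "degenerate": True}
    r, p = stats.pearsonr(x, yv)
    return {"r": float(r), "r2": float(r * r), "p": float(p), "degenerate": False}


# ---------------------------------------------------------------------------
# closed forms


def logistic_phase_time(
    s: float, p0: float = PHASE_START_FREQ, p1: float = COMPLETION_FREQ
) -> float:
    """Deterministic haploid-selection travel time from frequency p0 to p1:
    (logit(p1) - logit(p0)) / ln(1+s); ~ 412 generations for s = 0.02 with
    the 1/s small-s approximation."""
    logit = lambda p: np.log(p / (1 - p))
    return float((logit(p1) - logit(p0)) / np.log1p(s))


def log_ne_phase_ratio(ne: float, ne_ref: float = 10_000.0) -> float:
    """Expected selection-phase ratio between population sizes under the
    log(Ne)/s law for the sojourn time of a favoured allele."""
    return float(np.log(ne) / np.log(ne_ref))
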