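"""Haplotype-sample containers, ms-dialect text I/O, window grids and
scenario bookkeeping.

The in-memory currency of the package is :class:`HaplotypeSample`: a binary
haplotype-by-SNP matrix with continuous bp positions (infinite-sites
coordinates are never rounded to integers), per-haplotype deme labels and,
when known from simulation truth, the position of the selected site.
Samples are exchanged on disk as Hudson ``ms``-style text (``segsites:`` /
``positions:`` blocks with fractional positions), the de-facto plain-text
interchange format for coalescent and forward simulators.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "HaplotypeSample",
    "WindowGrid",
    "ScenarioConfig",
    "read_ms",
    "write_ms",
    "make_windows",
    "scenario_table",
    "derive_seeds",
]

#: positions are written with this many decimals of the unit interval
MS_POSITION_DECIMALS = 8


@dataclass
class HaplotypeSample:
    """A sample of haplotypes over one simulated region.

    Parameters
    ----------
    matrix
        uint8 array of shape ``(n_hap, n_snp)``; 0 = ancestral, 1 = derived.
    positions
        bp coordinates in ``[0, L)``, strictly increasing, float (continuous).
    region_length
        total region length L in bp.
    deme_labels
        integer per haplotype; 0 for panmictic/pooled samples, 1/2 for demes.
    selected_pos
        bp position of the selected site if known, else ``None``.
    """

    matrix: np.ndarray
    positions: np.ndarray
    region_length: float
    deme_labels: np.ndarray | None = None
    selected_pos: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.ascontiguousarray(np.asarray(self.matrix, dtype=np.uint8))
        self.positions = np.asarray(self.positions, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (n_hap x n_snp)")
        if self.positions.shape != (self.matrix.shape[1],):
            raise ValueError("positions length must equal number of SNP columns")
        if self.positions.size and (
            np.any(self.positions < 0) or np.any(self.positions >= self.region_length)
        ):
            raise ValueError("positions must lie in [0, region_length)")
        if self.positions.size > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")
        if self.deme_labels is not None:
            self.deme_labels = np.asarray(self.deme_labels, dtype=int)
            if self.deme_labels.shape != (self.matrix.shape[0],):
                raise ValueError("deme_labels length must equal number of haplotypes")

    @property
    def n_hap(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_snp(self) -> int:
        return self.matrix.shape[1]

    def derived_counts(self) -> np.ndarray:
        """Derived-allele count per SNP column in the pooled sample."""
        return self.matrix.sum(axis=0).astype(np.int64)

    def subset_haplotypes(self, index: np.ndarray) -> "HaplotypeSample":
        """Row subset, dropping columns monomorphic in the subset.

        The selected site, when tracked, is kept even if fixed in the subset.
        """
        sub = self.matrix[index]
        counts = sub.sum(axis=0)
        keep = (counts > 0) & (counts < sub.shape[0])
        if self.selected_pos is not None:
            keep |= np.isclose(self.positions, self.selected_pos)
        labels = None if self.deme_labels is None else self.deme_labels[index]
        return HaplotypeSample(
            matrix=sub[:, keep],
            positions=self.positions[keep],
            region_length=self.region_length,
            deme_labels=labels,
            selected_pos=self.selected_pos,
        )


@dataclass
class WindowGrid:
    """Half-open sliding windows ``[start, end)`` tiling ``[0, L)``."""

    region_length: float
    width: float
    step: float
    windows: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def assign(self, positions: np.ndarray) -> list[np.ndarray]:
        """Boolean membership mask per window (windows overlap, so a SNP can
        belong to several)."""
        positions = np.asarray(positions, dtype=float)
        return [
            (positions >= start) & (positions < end) for start, end in self.windows
        ]


def make_windows(region_length: float, width: float, step: float) -> WindowGrid:
    """Sliding-window grid; count = floor((L - width)/step) + 1.

    The canonical scan uses 100 kb windows with 10 kb step over a 600 kb
    region, giving 51 windows.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    if width > region_length:
        raise ValueError("window width exceeds region length")
    count = int(np.floor((region_length - width) / step)) + 1
    windows = [(i * step, i * step + width) for i in range(count)]
    return WindowGrid(region_length, width, step, windows)


# ---------------------------------------------------------------------------
# ms-dialect text I/O


def _dedupe_positions(pos: np.ndarray, L: float, replicate: int) -> np.ndarray:
    """Jitter ties produced by position quantisation by minimal increments."""
    if pos.size < 2 or np.all(np.diff(pos) > 0):
        return pos
    warnings.warn(
        f"replicate {replicate}: tied positions after quantisation; jittering",
        stacklevel=3,
    )
    out = pos.copy()
    eps = L * 10.0 ** (-MS_POSITION_DECIMALS)
    for i in range(1, out.size):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + eps
    return np.minimum(out, np.nextafter(L, 0))


def read_ms(stream, region_length: float, n_hap: int | None = None) -> list[HaplotypeSample]:
    """Parse ms-dialect output into :class:`HaplotypeSample` objects.

    Parameters
    ----------
    stream
        text stream or string with ``//`` replicate separators.
    region_length
        bp length L; fractional positions are scaled by L.
    n_hap
        expected haplotype count (used for ``segsites: 0`` replicates where no
        rows follow); if None it is taken from the ms command header when
        present.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = stream.read().splitlines()
    if lines and lines[0].split() and lines[0].split()[0].endswith("ms"):
        toks = lines[0].split()
        if n_hap is None and len(toks) >= 2:
            try:
                n_hap = int(toks[1])
            except ValueError:
                pass

    samples: list[HaplotypeSample] = []
    i = 0
    rep = -1
    while i < len(lines):
        if not lines[i].startswith("//"):
            i += 1
            continue
        rep += 1
        i += 1
        while i < len(lines) and not lines[i].startswith("segsites:"):
            i += 1
        if i >= len(lines):
            raise ValueError(f"replicate {rep}: missing 'segsites:' line")
        segsites = int(lines[i].split(":", 1)[1])
        i += 1
        if segsites == 0:
            nh = n_hap if n_hap is not None else 0
            samples.append(
                HaplotypeSample(
                    matrix=np.zeros((nh, 0), dtype=np.uint8),
                    positions=np.empty(0),
                    region_length=region_length,
                )
            )
            continue
        while i < len(lines) and not lines[i].startswith("positions:"):
            i += 1
        if i >= len(lines):
            raise ValueError(f"replicate {rep}: missing 'positions:' line")
        frac = np.array([float(x) for x in lines[i].split(":", 1)[1].split()])
        i += 1
        rows = []
        while i < len(lines) and lines[i].strip() and not lines[i].startswith("//"):
            row = lines[i].strip()
            if len(row) != segsites:
                raise ValueError(
                    f"replicate {rep}: row of length {len(row)} != segsites {segsites}"
                )
            rows.append(np.frombuffer(row.encode(), dtype=np.uint8) - ord("0"))
            i += 1
        pos = _dedupe_positions(frac * region_length, region_length, rep)
        samples.append(
            HaplotypeSample(
                matrix=np.array(rows, dtype=np.uint8),
                positions=pos,
                region_length=region_length,
            )
        )
    return samples


def write_ms(samples: Sequence[HaplotypeSample], header: str | None = None) -> str:
    """Emit ms-dialect text parseable by :func:`read_ms` and third-party ms
    consumers; positions are written as fractions of L."""
    out: list[str] = []
    if header is None:
        nh = samples[0].n_hap if samples else 0
        header = f"ms {nh} {len(samples)}"
    out.append(header)
    out.append("0 0 0")  # seed line, kept for dialect compatibility
    for s in samples:
        out.append("")
        out.append("//")
        out.append(f"segsites: {s.n_snp}")
        if s.n_snp:
            frac = s.positions / s.region_length
            out.append(
                "positions: "
                + " ".join(f"{p:.{MS_POSITION_DECIMALS}f}" for p in frac)
            )
            for row in s.matrix:
                out.append("".join("1" if v else "0" for v in row))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# scenario table


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario of the two-deme genomic study.

    ``code`` follows the mNX convention: the number is Nm (migrants per
    generation per direction), G = global adaptation (s in both demes),
    L = local (s only in the native deme d1), NB = neutral background.
    ``m0G``/``m0NB`` are panmictic with Ne = 20,000.
    """

    code: str
    n_demes: int
    deme_size: int  # haploid chromosomes per deme
    Nm: float  # migrants per generation per direction (0 = panmictic)
    s_d1: float
    s_d2: float
    replicates: int
    resamples: int
    time_points: int
    neutral: bool = False
    fixed_interval: int | None = None  # generations between snapshots (m0.2L)
    max_generations: int | None = None

    @property
    def migration_rate(self) -> float:
        """Per-individual migration probability m = Nm / deme size."""
        return 0.0 if self.Nm == 0 else self.Nm / self.deme_size


_SELECTION_ROWS = [
    # code, Nm, s_d1, s_d2
    ("m20G", 20.0, 0.02, 0.02),
    ("m2G", 2.0, 0.02, 0.02),
    ("m0.2G", 0.2, 0.02, 0.02),
    ("m0G", 0.0, 0.02, 0.02),
    ("m20L", 20.0, 0.02, 0.0),
    ("m2L", 2.0, 0.02, 0.0),
    ("m0.2L", 0.2, 0.02, 0.0),
]

_NEUTRAL_ROWS = [
    ("m20NB", 20.0),
    ("m2NB", 2.0),
    ("m0.2NB", 0.2),
    ("m0NB", 0.0),
]


def scenario_table() -> list[ScenarioConfig]:
    """The seven selection scenarios and four neutral backgrounds with their
    replicate counts, resamples and snapshot time-point counts."""
    out: list[ScenarioConfig] = []
    for code, nm, s1, s2 in _SELECTION_ROWS:
        panmictic = nm == 0.0
        if code == "m0.2L":
            tp, fixed, maxgen = 200, 100, 20_000
        else:
            tp, fixed, maxgen = (12 if panmictic else 22), None, None
        out.append(
            ScenarioConfig(
                code=code,
                n_demes=1 if panmictic else 2,
                deme_size=20_000 if panmictic else 10_000,
                Nm=nm,
                s_d1=s1,
                s_d2=s2,
                replicates=100,
                resamples=50,
                time_points=tp,
                fixed_interval=fixed,
                max_generations=maxgen,
            )
        )
    for code, nm in _NEUTRAL_ROWS:
        panmictic = nm == 0.0
        out.append(
            ScenarioConfig(
                code=code,
                n_demes=1 if panmictic else 2,
                deme_size=20_000 if panmictic else 10_000,
                Nm=nm,
                s_d1=0.0,
                s_d2=0.0,
                # two-deme NB: each deme of 2,500 replicates is used as an
                # independent one-deme sample, effectively 5,000 samples
                replicates=5_000 if panmictic else 2_500,
                resamples=1,
                time_points=1,
                neutral=True,
            )
        )
    return out


def get_scenario(code: str) -> ScenarioConfig:
    for cfg in scenario_table():
        if cfg.code == code:
            return cfg
    raise KeyError(f"unknown scenario code: {code!r}")


def derive_seeds(master_seed: int, n: int, key: int = 0) -> np.ndarray:
    """Per-replicate 31-bit seeds derived from a master seed via a counter.

    All randomised operations in the package take explicit seeds; replicate
    seeds are derived (and recorded in output tables) so that any single
    replicate can be re-run in isolation.
    """
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(key,))
    return ss.generate_state(n, dtype=np.uint32) % (2**31 - 1)
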