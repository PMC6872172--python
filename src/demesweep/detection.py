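"""Neutral-background threshold calibration and sweep detection power.

False positives are controlled empirically: each neutral-background (NB)
region is cut into three non-overlapping 200-kb blocks and each block is
represented by the most extreme value (in the statistic's sweep direction)
of the windows lying entirely inside it, pooling 3 values per region (15,000
for the full 5,000-region NB sets). Detection cutoffs at nominal false
positive rates of 5%, 1% and 0.1% are the corresponding order statistics of
that pool, so applying a cutoff back to its calibration set detects exactly
the nominal fraction (absent ties). Whole-region thresholds use the extreme
over all 51 windows instead. A sample is "detected" if at least one window
of the scanned span - the first 11 windows (200 kb centred on the selected
locus), or all 51 - is at or beyond the cutoff in the tail direction.

Thresholds are demography-specific: separate tables are calibrated for the
panmictic NB and for each migration rate, and a deliberately mismatched
(e.g. panmictic-on-subdivided) calibration is available as an explicit mode
to reproduce its inflated false-positive behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import WindowGrid, make_windows
from .sumstats import STAT_DIRECTIONS

__all__ = [
    "ThresholdTable",
    "calibrate_thresholds",
    "detect",
    "detection_rate",
    "power_table",
    "DEFAULT_FPRS",
    "block_windows",
]

DEFAULT_FPRS = (0.05, 0.01, 0.001)
BLOCK_SIZE = 200_000.0


def block_windows(
    supports: Sequence[tuple[float, float]], region_length: float = 600_000.0
) -> list[np.ndarray]:
    """Indices of windows (or grid points, as degenerate intervals) entirely
    inside each consecutive 200-kb block."""
    n_blocks = int(round(region_length / BLOCK_SIZE))
    out = []
    for b in range(n_blocks):
        lo, hi = b * BLOCK_SIZE, (b + 1) * BLOCK_SIZE
        out.append(
            np.array(
                [i for i, (s, e) in enumerate(supports) if s >= lo and e <= hi],
                dtype=int,
            )
        )
    return out


def _extreme(values: np.ndarray, direction: int, axis: int = -1) -> np.ndarray:
    with np.errstate(all="ignore"):
        if direction > 0:
            return np.nanmax(values, axis=axis)
        return np.nanmin(values, axis=axis)


def _tail_quantile(pool: np.ndarray, alpha: float, direction: int) -> float:
    """Order-statistic cutoff: the floor(alpha n)-th most extreme pooled
    value, so that 'at or beyond' detects exactly that many of the pool."""
    pool = pool[~np.isnan(pool)]
    if pool.size == 0:
        raise ValueError("no finite calibration values")
    k = max(1, int(np.floor(alpha * pool.size)))
    srt = np.sort(pool)
    return float(srt[-k] if direction > 0 else srt[k - 1])


@dataclass
class ThresholdTable:
    """Per (statistic, FPR, span) cutoffs for one demography's NB set."""

    demography: str
    cutoffs: dict[tuple[str, float, str], float] = field(default_factory=dict)
    directions: dict[str, int] = field(default_factory=dict)
    skipped_blocks: dict[str, int] = field(default_factory=dict)
    pool_sizes: dict[str, int] = field(default_factory=dict)  # pooled block extremes

    def cutoff(self, statistic: str, fpr: float, span: str) -> float:
        return self.cutoffs[(statistic, float(fpr), span)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                demography=self.demography,
                statistic=s,
                fpr=f,
                span=span,
                cutoff=c,
                direction=self.directions[s],
            )
            for (s, f, span), c in self.cutoffs.items()
        ]
        return pd.DataFrame(rows)


def calibrate_thresholds(
    tracks: Mapping[str, np.ndarray],
    demography: str = "",
    supports: Mapping[str, Sequence[tuple[float, float]]] | None = None,
    region_length: float = 600_000.0,
    fprs: Sequence[float] = DEFAULT_FPRS,
) -> ThresholdTable:
    """Calibrate detection cutoffs from NB score tracks.

    ``tracks`` maps statistic name to an ``(n_samples, n_windows)`` array of
    per-window values; ``supports`` optionally gives each statistic's window
    intervals (default: the 100-kb/10-kb grid). Cutoffs are monotone across
    FPR levels by construction of the order statistics.
    """
    default_supports = make_windows(region_length, 100_000.0, 10_000.0).windows
    table = ThresholdTable(demography=demography)
    for stat, values in tracks.items():
        direction = STAT_DIRECTIONS[stat]
        table.directions[stat] = direction
        sup = list(supports[stat]) if supports and stat in supports else default_supports
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[1] != len(sup):
            raise ValueError(f"{stat}: track shape does not match supports")
        blocks = block_windows(sup, region_length)
        pooled = []
        skipped = 0
        for idx in blocks:
            if idx.size == 0:
                continue
            ext = _extreme(values[:, idx], direction)
            skipped += int(np.isnan(ext).sum())
            pooled.append(ext[~np.isnan(ext)])
        pool = np.concatenate(pooled) if pooled else np.empty(0)
        whole = _extreme(values, direction)
        whole = whole[~np.isnan(whole)]
        table.skipped_blocks[stat] = skipped
        table.pool_sizes[stat] = int(pool.size)
        for f in fprs:
            table.cutoffs[(stat, float(f), "first200k")] = _tail_quantile(
                pool, f, direction
            )
            table.cutoffs[(stat, float(f), "whole")] = _tail_quantile(
                whole, f, direction
            )
    return table


def _span_indices(
    supports: Sequence[tuple[float, float]], span: str
) -> np.ndarray:
    if span == "whole":
        return np.arange(len(supports))
    if span == "first200k":
        return np.array(
            [i for i, (s, e) in enumerate(supports) if s >= 0 and e <= BLOCK_SIZE],
            dtype=int,
        )
    raise ValueError(f"unknown span {span!r}")


def detect(
    values: np.ndarray,
    statistic: str,
    table: ThresholdTable,
    fpr: float,
    span: str = "first200k",
    supports: Sequence[tuple[float, float]] | None = None,
    region_length: float = 600_000.0,
) -> bool | None:
    """Is one sample's score track beyond the cutoff anywhere in the span?

    Returns None (undetermined) when every in-span window is missing; such
    samples are excluded from power denominators.
    """
    if supports is None:
        supports = make_windows(region_length, 100_000.0, 10_000.0).windows
    idx = _span_indices(supports, span)
    v = np.asarray(values, dtype=float)[idx]
    v = v[~np.isnan(v)]
    if v.size == 0:
        return None
    c = table.cutoff(statistic, fpr, span)
    if table.directions[statistic] > 0:
        return bool(np.any(v >= c))
    return bool(np.any(v <= c))


def detection_rate(
    values: np.ndarray,
    statistic: str,
    table: ThresholdTable,
    fpr: float,
    span: str = "first200k",
    supports: Sequence[tuple[float, float]] | None = None,
    region_length: float = 600_000.0,
) -> tuple[float, int]:
    """Detected fraction over an ``(n_samples, n_windows)`` track matrix and
    the number of determined samples (the denominator)."""
    results = [
        detect(row, statistic, table, fpr, span, supports, region_length)
        for row in np.atleast_2d(values)
    ]
    valid = [r for r in results if r is not None]
    if not valid:
        return float("nan"), 0
    return float(np.mean(valid)), len(valid)


def power_table(
    scored: Mapping[tuple, Mapping[str, np.ndarray]],
    table: ThresholdTable,
    fprs: Sequence[float] = DEFAULT_FPRS,
    span: str = "first200k",
    supports: Mapping[str, Sequence[tuple[float, float]]] | None = None,
    region_length: float = 600_000.0,
) -> pd.DataFrame:
    """Power per (scenario, deme, stage) cell, statistic and FPR level.

    ``scored`` maps cell keys (scenario, deme, stage) to per-statistic track
    matrices; undetermined samples are excluded from the denominator and
    reported in ``n``.
    """
    rows = []
    for key, tracks in scored.items():
        scenario, deme, stage = key
        for stat, values in tracks.items():
            sup = supports.get(stat) if supports else None
            for f in fprs:
                rate, n = detection_rate(
                    values, stat, table, f, span, sup, region_length
                )
                rows.append(
                    dict(
                        scenario=scenario,
                        deme=deme,
                        stage=stage,
                        statistic=stat,
                        fpr=f,
                        span=span,
                        power=rate,
                        n=n,
                    )
                )
    return pd.DataFrame(rows)
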