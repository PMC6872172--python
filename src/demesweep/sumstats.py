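"""Window and grid statistics for selective-sweep scans.

Thirteen statistics are computed per sample, each over the 100-kb/10-kb
sliding-window grid (or a 10-kb grid for the composite-likelihood scans):

* site-frequency-spectrum: theta_pi (mean pairwise differences), theta_w
  (Watterson), theta_h (high-frequency-weighted, sum over sites of
  2 k^2 / (n (n-1))), Tajima's D, Fay & Wu's H (theta_pi - theta_h, raw);
* haplotype spectrum: number of distinct haplotypes n_hap, H1, H12, H2/H1;
* haplotype length: iHS and nSL, summarised per window as the proportion of
  SNPs whose normalised score exceeds |z| > 2 (normalisation by
  derived-frequency bin against a neutral background);
* composite likelihood: a simplified Nielsen-style CLR grid scan and a
  simplified cross-population XP-CLR using the other deme as control;
* differentiation: mean per-site Hudson FST over the first 200 kb.

iHS/nSL use the pairwise shared-extent formulation of extended haplotype
homozygosity: EHH_g(p, q) is the fraction of chromosome pairs within carrier
group g (derived or ancestral at the pivot p) identical over all sites
between p and q; iHH integrates EHH outward by trapezoid until it decays
below 0.05 or the last SNP, in bp for iHS and in segregating-site units for
nSL; the score is ln(iHH_ancestral / iHH_derived).

The CLR and XP-CLR here are deliberately simplified re-implementations of
the cited model families: their contract is neutral-null calibration and
directional behaviour, not numeric parity with the released binaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import HaplotypeSample, WindowGrid, make_windows

__all__ = [
    "STAT_DIRECTIONS",
    "sfs_stats",
    "haplotype_stats",
    "ihs_nsl_scores",
    "NormalisationTable",
    "build_normalisation",
    "normalise_scores",
    "window_significance",
    "sf2_clr",
    "xpclr",
    "fst_stats",
    "ScoreTrack",
    "score_sample",
    "PIVOT_FREQ_MIN",
    "PIVOT_FREQ_MAX",
    "EHH_CUTOFF",
]

#: tail direction per statistic: +1 = higher values indicate a sweep
STAT_DIRECTIONS: dict[str, int] = {
    "theta_pi": -1,
    "theta_w": -1,
    "theta_h": +1,
    "tajima_d": -1,
    "faywu_h": -1,
    "n_hap": -1,
    "H1": +1,
    "H12": +1,
    "H2_H1": -1,
    "ihs_prop": +1,
    "nsl_prop": +1,
    "clr": +1,
    "xpclr": +1,
}

PIVOT_FREQ_MIN = 0.06
PIVOT_FREQ_MAX = 0.94
EHH_CUTOFF = 0.05
Z_SIGNIFICANT = 2.0


# ---------------------------------------------------------------------------
# site-frequency-spectrum statistics


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return c1 / a1, c2 / (a1**2 + a2)


def sfs_stats(counts: np.ndarray, n: int, min_s_for_d: int = 3) -> dict[str, float]:
    """SFS estimators from derived-allele counts of the polymorphic sites in
    one window of an ``n``-haplotype sample.

    Returns theta_pi, theta_w, theta_h, tajima_d and faywu_h; with no
    segregating sites the thetas are 0 and D/H are NaN, and D is NaN below
    ``min_s_for_d`` sites (its normalisation is meaningless there).
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[(counts > 0) & (counts < n)]
    S = counts.size
    pairs = n * (n - 1) / 2
    a1 = np.sum(1.0 / np.arange(1, n))
    theta_pi = float(np.sum(counts * (n - counts)) / pairs)
    theta_w = float(S / a1)
    theta_h = float(np.sum(counts.astype(float) ** 2) / pairs)
    if S == 0:
        return dict(
            theta_pi=0.0, theta_w=0.0, theta_h=0.0, tajima_d=np.nan, faywu_h=np.nan
        )
    faywu_h = theta_pi - theta_h
    if S < min_s_for_d:
        tajima_d = np.nan
    else:
        e1, e2 = _tajima_constants(n)
        denom = np.sqrt(e1 * S + e2 * S * (S - 1))
        tajima_d = (theta_pi - theta_w) / denom if denom > 0 else np.nan
    return dict(
        theta_pi=theta_pi,
        theta_w=theta_w,
        theta_h=theta_h,
        tajima_d=float(tajima_d),
        faywu_h=float(faywu_h),
    )


def haplotype_stats(matrix: np.ndarray) -> dict[str, float]:
    """Haplotype-spectrum statistics of one window's 0/1 matrix.

    H1 = sum p_i^2 over distinct-haplotype frequencies, H12 pools the two
    most frequent haplotypes, H2 = H1 - p_1^2; a monomorphic window has
    n_hap = 1, H1 = H12 = 1 and H2/H1 = 0.
    """
    matrix = np.ascontiguousarray(matrix, dtype=np.uint8)
    n = matrix.shape[0]
    if matrix.shape[1] == 0:
        freqs = np.array([1.0])
    else:
        _, cnts = np.unique(
            matrix.view([("", matrix.dtype)] * matrix.shape[1]).ravel(),
            return_counts=True,
        )
        freqs = np.sort(cnts / n)[::-1]
    h1 = float(np.sum(freqs**2))
    h12 = float((freqs[0] + (freqs[1] if freqs.size > 1 else 0.0)) ** 2
                + np.sum(freqs[2:] ** 2))
    h2 = h1 - float(freqs[0] ** 2)
    return dict(n_hap=float(freqs.size), H1=h1, H12=h12, H2_H1=h2 / h1)


# ---------------------------------------------------------------------------
# iHS / nSL


def _pairwise_extents(matrix: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per chromosome pair and pivot site, the index of the nearest
    mismatching site strictly right (sentinel S) and left (sentinel -1) of
    the pivot. Identity of a pair over (p, q] holds iff e_right[pair, p] > q.
    """
    n, S = matrix.shape
    i_idx, j_idx = np.triu_indices(n, k=1)
    diff = matrix[i_idx] != matrix[j_idx]  # (n_pairs, S)
    sites = np.arange(S, dtype=np.int32)
    # running minimum of mismatch indices from the right -> nearest mismatch
    # at or after each site; shift by one for "strictly right of the pivot"
    at_or_after = np.where(diff, sites, np.int32(S))
    at_or_after = np.minimum.accumulate(at_or_after[:, ::-1], axis=1)[:, ::-1]
    e_right = np.concatenate(
        [at_or_after[:, 1:], np.full((diff.shape[0], 1), S, dtype=np.int32)],
        axis=1,
    )
    at_or_before = np.where(diff, sites, np.int32(-1))
    at_or_before = np.maximum.accumulate(at_or_before, axis=1)
    e_left = np.concatenate(
        [np.full((diff.shape[0], 1), -1, dtype=np.int32), at_or_before[:, :-1]],
        axis=1,
    )
    return i_idx, j_idx, e_right, e_left


def _ihh_one_side(
    extents: np.ndarray,
    pivot: int,
    x: np.ndarray,
    direction: int,
) -> float:
    """Trapezoidal integral of one-sided EHH from the pivot outward.

    ``extents`` are the per-pair nearest-mismatch site indices for this side;
    ``x`` the coordinate of every site (bp for iHS, site index for nSL).
    Integration runs over successive SNPs away from the pivot, starting at
    EHH = 1 at the pivot itself, and stops after the first evaluation below
    the 0.05 cutoff or at the last SNP.
    """
    (total,) = _ihh_one_side_multi(extents, pivot, (x,), direction)
    return total


def _ihh_one_side_multi(
    extents: np.ndarray,
    pivot: int,
    coords: tuple[np.ndarray, ...],
    direction: int,
) -> tuple[float, ...]:
    """As :func:`_ihh_one_side` but integrating the same EHH decay against
    several coordinate systems at once (bp for iHS, site units for nSL)."""
    P = extents.size
    if P == 0:
        return tuple(0.0 for _ in coords)
    S = coords[0].size
    if direction > 0:
        qs = np.arange(pivot + 1, S)
    else:
        qs = np.arange(pivot - 1, -1, -1)
    if qs.size == 0:
        return tuple(0.0 for _ in coords)
    # EHH(q) = fraction of pairs whose identity extends past q; counted by
    # rank lookup in the sorted extents, chunked with early stop at decay
    ext = np.sort(extents)
    totals = [0.0] * len(coords)
    prev_ehh = 1.0
    prev_q = pivot
    chunk = 64
    for lo in range(0, qs.size, chunk):
        q = qs[lo : lo + chunk]
        if direction > 0:
            ehh = (P - np.searchsorted(ext, q, side="right")) / P
        else:
            ehh = np.searchsorted(ext, q, side="left") / P
        prev_es = np.concatenate([[prev_ehh], ehh[:-1]])
        below = np.flatnonzero(ehh < EHH_CUTOFF)
        stop = below[0] + 1 if below.size else ehh.size
        q_full = np.concatenate([[prev_q], q])
        for ci, x in enumerate(coords):
            xs = np.abs(x[q_full] - x[pivot])
            seg = 0.5 * (prev_es + ehh) * np.diff(xs)
            totals[ci] += float(seg[:stop].sum())
        if below.size:
            return tuple(totals)
        prev_ehh = float(ehh[-1])
        prev_q = int(q[-1])
    return tuple(totals)


def ihs_nsl_scores(
    sample: HaplotypeSample,
    pivots: np.ndarray | None = None,
) -> pd.DataFrame:
    """Unstandardised iHS and nSL per eligible pivot SNP.

    Pivots are SNPs with derived sample frequency in [0.06, 0.94] (the range
    over which frequency-binned normalisation is defined); ``pivots`` may
    restrict to a subset of site indices (e.g. one sub-region). Scores are
    NaN where either integrated homozygosity vanishes.
    """
    m = sample.matrix
    n, S = m.shape
    counts = sample.derived_counts()
    eligible = (counts >= PIVOT_FREQ_MIN * n) & (counts <= PIVOT_FREQ_MAX * n)
    if pivots is not None:
        mask = np.zeros(S, dtype=bool)
        mask[pivots] = True
        eligible &= mask
    piv = np.flatnonzero(eligible)
    rows = []
    if piv.size == 0 or S < 2:
        return pd.DataFrame(
            columns=["site", "pos", "count", "ihs_raw", "nsl_raw"]
        ).astype({"site": int, "count": int})

    i_idx, j_idx, e_right, e_left = _pairwise_extents(m)
    carrier = m.astype(bool)
    site_x = np.arange(S, dtype=float)
    for p in piv:
        der = carrier[:, p]
        res = {}
        for label, group_mask in (("d", der), ("a", ~der)):
            pair_sel = group_mask[i_idx] & group_mask[j_idx]
            er = e_right[pair_sel, p]
            el = e_left[pair_sel, p]
            coords = (sample.positions, site_x)
            r_bp, r_sites = _ihh_one_side_multi(er, p, coords, +1)
            l_bp, l_sites = _ihh_one_side_multi(el, p, coords, -1)
            res[label] = (r_bp + l_bp, r_sites + l_sites)
        ihs = (
            np.log(res["a"][0] / res["d"][0])
            if res["d"][0] > 0 and res["a"][0] > 0
            else np.nan
        )
        nsl = (
            np.log(res["a"][1] / res["d"][1])
            if res["d"][1] > 0 and res["a"][1] > 0
            else np.nan
        )
        rows.append(
            dict(site=p, pos=sample.positions[p], count=counts[p], ihs_raw=ihs,
                 nsl_raw=nsl)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# normalisation and per-window significance proportion


@dataclass
class NormalisationTable:
    """Mean/SD of an unstandardised score per derived-count bin, estimated
    from neutral-background samples of a fixed sample size ``n``."""

    n: int
    mean: dict[int, float]
    sd: dict[int, float]

    def normalise(self, counts: np.ndarray, raw: np.ndarray) -> np.ndarray:
        """z-scores; NaN (with a warning count) where a bin is missing."""
        z = np.full(raw.shape, np.nan)
        missing = 0
        for i, (k, v) in enumerate(zip(counts, raw)):
            if np.isnan(v):
                continue
            k = int(k)
            if k in self.mean:
                z[i] = (v - self.mean[k]) / self.sd[k]
            else:
                missing += 1
        if missing:
            warnings.warn(f"{missing} scores dropped: unpopulated frequency bins")
        return z


def build_normalisation(
    counts: np.ndarray, raw: np.ndarray, n: int, min_bin: int = 2
) -> NormalisationTable:
    """Frequency-binned normalisation table from pooled neutral-background
    scores; raises if any populated bin is degenerate (zero spread)."""
    counts = np.asarray(counts, dtype=int)
    raw = np.asarray(raw, dtype=float)
    ok = ~np.isnan(raw)
    mean: dict[int, float] = {}
    sd: dict[int, float] = {}
    for k in np.unique(counts[ok]):
        vals = raw[ok & (counts == k)]
        if vals.size < min_bin:
            continue
        s = float(vals.std(ddof=1))
        if s == 0:
            raise ValueError(f"degenerate normalisation bin at count {k}")
        mean[int(k)] = float(vals.mean())
        sd[int(k)] = s
    return NormalisationTable(n=n, mean=mean, sd=sd)


def normalise_scores(
    scores: pd.DataFrame, table: NormalisationTable, column: str
) -> np.ndarray:
    return table.normalise(scores["count"].to_numpy(), scores[column].to_numpy())


def window_significance(
    z: np.ndarray, positions: np.ndarray, grid: WindowGrid
) -> np.ndarray:
    """Per window, the fraction of scored SNPs with |z| > 2; NaN where the
    window holds no scored SNP."""
    z = np.asarray(z, dtype=float)
    ok = ~np.isnan(z)
    out = np.full(grid.n_windows, np.nan)
    for w, (start, end) in enumerate(grid.windows):
        inw = ok & (positions >= start) & (positions < end)
        if inw.any():
            out[w] = float(np.mean(np.abs(z[inw]) > Z_SIGNIFICANT))
    return out


# ---------------------------------------------------------------------------
# composite-likelihood scans


DEFAULT_ALPHAS = np.logspace(-6.5, -2.5, 17)  # sweep intensity, 1/bp


def sf2_clr(
    sample: HaplotypeSample,
    grid_step: float = 10_000.0,
    alphas: np.ndarray = DEFAULT_ALPHAS,
) -> tuple[np.ndarray, np.ndarray]:
    """Simplified Nielsen-style composite-likelihood sweep scan.

    The background site-frequency spectrum is the sample's own full-region
    spectrum. Under a sweep of intensity alpha at grid point g, a SNP at
    distance d escapes with probability ``1 - exp(-alpha d)`` and then draws
    from the background spectrum; a non-escaping SNP draws from a swept
    spectrum with all mass on counts n-1 (with probability equal to the
    background mean derived frequency) and 1. The statistic per grid point is
    ``2 (max_alpha log CL - log CL_background)``, with the background model
    (alpha -> infinity) included in the maximisation, hence >= 0.

    Returns (grid positions, CLR values); all-NaN with fewer than 2 SNPs.
    """
    L = sample.region_length
    grid_pos = np.arange(0.0, L, grid_step)
    n = sample.n_hap
    counts = sample.derived_counts()
    sel = (counts > 0) & (counts < n)
    counts = counts[sel]
    pos = sample.positions[sel]
    if counts.size < 2:
        return grid_pos, np.full(grid_pos.size, np.nan)

    sfs = np.bincount(counts, minlength=n + 1)[1:n].astype(float)
    bg = sfs / sfs.sum()  # background P(count = k), k = 1..n-1
    beta = float(np.sum(np.arange(1, n) * bg) / n)  # mean derived frequency
    swept = np.zeros(n - 1)
    swept[0] = 1 - beta  # count 1
    swept[-1] = beta  # count n-1
    p_bg = bg[counts - 1]
    p_sw = swept[counts - 1]
    log_bg = float(np.sum(np.log(p_bg)))

    clr = np.empty(grid_pos.size)
    for gi, g in enumerate(grid_pos):
        d = np.abs(pos - g)
        best = log_bg
        for a in alphas:
            pe = -np.expm1(-a * d)
            ll = np.sum(np.log(pe * p_bg + (1 - pe) * p_sw + 1e-300))
            if ll > best:
                best = ll
        clr[gi] = 2.0 * (best - log_bg)
    return grid_pos, clr


DEFAULT_XP_SCALE = 50_000.0  # bp decay scale of the sweep variance inflation
DEFAULT_XP_STRENGTHS = np.concatenate([[0.0], np.logspace(-1, 2.5, 15)])


def xpclr(
    sample: HaplotypeSample,
    focal_deme: int,
    grid_step: float = 10_000.0,
    strengths: np.ndarray = DEFAULT_XP_STRENGTHS,
    scale: float = DEFAULT_XP_SCALE,
) -> tuple[np.ndarray, np.ndarray]:
    """Simplified cross-population composite-likelihood scan.

    Uses the other deme's allele frequency as the prior for the focal deme's
    under Gaussian drift: under the null p_focal ~ N(p_control, sigma^2) with
    sigma^2 fitted by moments genome-wide; a sweep of strength s at grid
    point g inflates the variance of a SNP at distance d by
    ``1 + s exp(-d/scale)``. Score per grid point is
    ``2 (max_s log CL - log CL at s = 0)`` (s = 0 included, hence >= 0).
    """
    if sample.deme_labels is None:
        raise ValueError("xpclr needs a two-deme sample")
    demes = np.unique(sample.deme_labels)
    if demes.size != 2:
        raise ValueError("xpclr needs exactly two demes")
    control_deme = demes[demes != focal_deme][0]
    mf = sample.matrix[sample.deme_labels == focal_deme]
    mc = sample.matrix[sample.deme_labels == control_deme]
    pf = mf.mean(axis=0)
    pc = mc.mean(axis=0)
    poly = (sample.derived_counts() > 0) & (
        sample.derived_counts() < sample.n_hap
    )
    L = sample.region_length
    grid_pos = np.arange(0.0, L, grid_step)
    if not poly.any():
        return grid_pos, np.full(grid_pos.size, np.nan)
    pf, pc, pos = pf[poly], pc[poly], sample.positions[poly]
    resid2 = (pf - pc) ** 2
    sigma2 = max(float(resid2.mean()), 1e-6)

    score = np.empty(grid_pos.size)
    for gi, g in enumerate(grid_pos):
        w = np.exp(-np.abs(pos - g) / scale)
        best = -np.inf
        ll0 = None
        for s in strengths:
            v = sigma2 * (1.0 + s * w)
            ll = float(np.sum(-0.5 * np.log(v) - 0.5 * resid2 / v))
            if s == 0.0:
                ll0 = ll
            if ll > best:
                best = ll
        score[gi] = 2.0 * (best - ll0)
    return grid_pos, score


# ---------------------------------------------------------------------------
# FST


def fst_stats(sample: HaplotypeSample, span: float = 200_000.0) -> float:
    """Mean per-site Hudson plug-in FST (1 - H_within / H_between) over the
    polymorphic sites in the first ``span`` bp; NaN without such sites."""
    if sample.deme_labels is None:
        raise ValueError("fst needs deme labels")
    demes = np.unique(sample.deme_labels)
    if demes.size != 2:
        raise ValueError("fst needs exactly two demes")
    m1 = sample.matrix[sample.deme_labels == demes[0]]
    m2 = sample.matrix[sample.deme_labels == demes[1]]
    p1 = m1.mean(axis=0)
    p2 = m2.mean(axis=0)
    counts = sample.derived_counts()
    ok = (
        (counts > 0)
        & (counts < sample.n_hap)
        & (sample.positions < span)
    )
    if not ok.any():
        return float("nan")
    p1, p2 = p1[ok], p2[ok]
    hw = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2.0
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    valid = hb > 0
    if not valid.any():
        return float("nan")
    return float(np.mean(1.0 - hw[valid] / hb[valid]))


# ---------------------------------------------------------------------------
# assembling score tracks


@dataclass
class ScoreTrack:
    """Per-window (or per-grid-point) values of one statistic for one
    sample, with the statistic's sweep tail direction."""

    statistic: str
    values: np.ndarray
    direction: int  # +1 high-is-sweep, -1 low-is-sweep

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


WINDOW_STATS = (
    "theta_pi",
    "theta_w",
    "theta_h",
    "tajima_d",
    "faywu_h",
    "n_hap",
    "H1",
    "H12",
    "H2_H1",
)


def score_sample(
    sample: HaplotypeSample,
    grid: WindowGrid | None = None,
    stats: Sequence[str] = WINDOW_STATS,
    ihs_table: NormalisationTable | None = None,
    nsl_table: NormalisationTable | None = None,
    precomputed_raw: pd.DataFrame | None = None,
    restrict_pivots: tuple[float, float] | None = None,
) -> dict[str, ScoreTrack]:
    """All requested window statistics of one (single-deme or pooled) sample.

    ``ihs_prop``/``nsl_prop`` require the corresponding normalisation table;
    ``clr`` runs the grid scan (its track is indexed by grid point, same
    10-kb pitch). ``restrict_pivots`` limits iHS/nSL pivots (not their EHH
    integration) to the given bp range, for sub-region feature modes.
    """
    if grid is None:
        grid = make_windows(sample.region_length, 100_000.0, 10_000.0)
    out: dict[str, ScoreTrack] = {}
    window_stats = [s for s in stats if s in WINDOW_STATS]
    if window_stats:
        vals = {s: np.full(grid.n_windows, np.nan) for s in window_stats}
        counts = sample.derived_counts()
        for w, (start, end) in enumerate(grid.windows):
            inw = (sample.positions >= start) & (sample.positions < end)
            res: dict[str, float] = {}
            if any(s in window_stats for s in WINDOW_STATS[:5]):
                res.update(sfs_stats(counts[inw], sample.n_hap))
            if any(s in window_stats for s in WINDOW_STATS[5:]):
                res.update(haplotype_stats(sample.matrix[:, inw]))
            for s in window_stats:
                vals[s][w] = res[s]
        for s in window_stats:
            out[s] = ScoreTrack(s, vals[s], STAT_DIRECTIONS[s])

    if "ihs_prop" in stats or "nsl_prop" in stats:
        if precomputed_raw is not None:
            raw = precomputed_raw
        else:
            pivots = None
            if restrict_pivots is not None:
                lo, hi = restrict_pivots
                pivots = np.flatnonzero(
                    (sample.positions >= lo) & (sample.positions < hi)
                )
            raw = ihs_nsl_scores(sample, pivots=pivots)
        for name, col, table in (
            ("ihs_prop", "ihs_raw", ihs_table),
            ("nsl_prop", "nsl_raw", nsl_table),
        ):
            if name not in stats:
                continue
            if table is None:
                raise ValueError(f"{name} requires a normalisation table")
            if len(raw):
                z = normalise_scores(raw, table, col)
                track = window_significance(z, raw["pos"].to_numpy(), grid)
            else:
                track = np.full(grid.n_windows, np.nan)
            out[name] = ScoreTrack(name, track, STAT_DIRECTIONS[name])

    if "clr" in stats:
        _, clr = sf2_clr(sample)
        out["clr"] = ScoreTrack("clr", clr, STAT_DIRECTIONS["clr"])
    return out
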