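"""Statistics against brute-force oracles and their structural invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from demesweep.io_formats import HaplotypeSample, make_windows
from demesweep.sumstats import (
    NormalisationTable,
    build_normalisation,
    fst_stats,
    haplotype_stats,
    ihs_nsl_scores,
    sf2_clr,
    sfs_stats,
    window_significance,
    xpclr,
)


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_sfs(matrix):
    n, S = matrix.shape
    pi = 0.0
    for i, j in itertools.combinations(range(n), 2):
        pi += np.sum(matrix[i] != matrix[j])
    pairs = n * (n - 1) / 2
    pi /= pairs
    a1 = sum(1.0 / k for k in range(1, n))
    counts = matrix.sum(axis=0)
    counts = counts[(counts > 0) & (counts < n)]
    th = sum(2 * int(k) ** 2 for k in counts) / (n * (n - 1))
    return pi, len(counts) / a1, th


def brute_haplotype(matrix):
    seen = {}
    for row in matrix:
        seen[row.tobytes()] = seen.get(row.tobytes(), 0) + 1
    freqs = sorted((v / matrix.shape[0] for v in seen.values()), reverse=True)
    h1 = sum(p * p for p in freqs)
    h12 = (freqs[0] + (freqs[1] if len(freqs) > 1 else 0)) ** 2 + sum(
        p * p for p in freqs[2:]
    )
    h2 = h1 - freqs[0] ** 2
    return len(freqs), h1, h12, h2 / h1


def brute_fst(m1, m2, positions, span):
    vals = []
    n1, n2 = m1.shape[0], m2.shape[0]
    for j in range(m1.shape[1]):
        if positions[j] >= span:
            continue
        tot = m1[:, j].sum() + m2[:, j].sum()
        if tot == 0 or tot == n1 + n2:
            continue
        p1, p2 = m1[:, j].mean(), m2[:, j].mean()
        hw = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
        hb = p1 * (1 - p2) + p2 * (1 - p1)
        if hb > 0:
            vals.append(1 - hw / hb)
    return np.mean(vals) if vals else np.nan


def random_sample(rng, n_max=8, s_max=8, two_demes=False):
    n = int(rng.integers(4 if two_demes else 2, n_max + 1))
    if two_demes and n % 2:
        n += 1
    S = int(rng.integers(1, s_max + 1))
    m = rng.integers(0, 2, (n, S)).astype(np.uint8)
    counts = m.sum(axis=0)
    keep = (counts > 0) & (counts < n)
    m = m[:, keep]
    pos = np.sort(rng.uniform(0, 1000, m.shape[1]))
    while np.unique(pos).size < pos.size:
        pos = np.sort(rng.uniform(0, 1000, m.shape[1]))
    labels = None
    if two_demes:
        labels = np.repeat([1, 2], n // 2)
    return HaplotypeSample(
        matrix=m, positions=pos, region_length=1000.0, deme_labels=labels
    )


def test_estimators_match_brute_force_to_1e10():
    """theta_pi / theta_w / theta_h, the haplotype spectrum and FST agree
    with exhaustive enumeration on random small matrices."""
    rng = np.random.default_rng(17)
    checked = 0
    for _ in range(200):
        s = random_sample(rng, two_demes=bool(rng.integers(2)))
        if s.n_snp == 0:
            continue
        res = sfs_stats(s.derived_counts(), s.n_hap)
        pi, tw, th = brute_sfs(s.matrix)
        assert abs(res["theta_pi"] - pi) < 1e-10
        assert abs(res["theta_w"] - tw) < 1e-10
        assert abs(res["theta_h"] - th) < 1e-10
        if not np.isnan(res["faywu_h"]):
            assert abs(res["faywu_h"] - (pi - th)) < 1e-10
        hres = haplotype_stats(s.matrix)
        nh, h1, h12, h21 = brute_haplotype(s.matrix)
        assert hres["n_hap"] == nh
        assert abs(hres["H1"] - h1) < 1e-10
        assert abs(hres["H12"] - h12) < 1e-10
        assert abs(hres["H2_H1"] - h21) < 1e-10
        if s.deme_labels is not None:
            f = fst_stats(s, span=1000.0)
            b = brute_fst(s.matrix[s.deme_labels == 1], s.matrix[s.deme_labels == 2],
                          s.positions, 1000.0)
            if np.isnan(b):
                assert np.isnan(f)
            else:
                assert abs(f - b) < 1e-10
        checked += 1
    assert checked > 100


# ---------------------------------------------------------------------------
# worked examples


def test_sfs_example_four_haplotypes():
    m = np.array([[0, 0, 1], [0, 1, 1], [1, 0, 0], [0, 0, 0]], dtype=np.uint8)
    res = sfs_stats(m.sum(axis=0), 4)
    assert res["theta_pi"] == pytest.approx(10 / 6)
    assert res["theta_w"] == pytest.approx(3 / (1 + 0.5 + 1 / 3))
    assert res["theta_h"] == pytest.approx(1.0)
    assert res["faywu_h"] == pytest.approx(10 / 6 - 1.0)


def test_sfs_edge_policies():
    res = sfs_stats(np.array([], dtype=int), 10)
    assert res["theta_pi"] == 0 and np.isnan(res["tajima_d"]) and np.isnan(res["faywu_h"])
    res = sfs_stats(np.array([1]), 2)
    assert res["theta_pi"] == pytest.approx(1.0)
    assert res["theta_w"] == pytest.approx(1.0)  # a_1 = 1
    assert np.isnan(res["tajima_d"])  # S < 3 policy


def test_haplotype_examples():
    four = np.eye(4, dtype=np.uint8)
    res = haplotype_stats(four)
    assert (res["n_hap"], res["H1"], res["H12"], res["H2_H1"]) == (4, 0.25, 0.375, 0.75)
    mono = np.zeros((5, 3), dtype=np.uint8)
    res = haplotype_stats(mono)
    assert (res["n_hap"], res["H1"], res["H12"], res["H2_H1"]) == (1, 1, 1, 0)
    freqs = np.repeat(np.array([[0, 0], [0, 1], [1, 1]], np.uint8), [5, 3, 2], axis=0)
    res = haplotype_stats(freqs)
    assert res["H1"] == pytest.approx(0.38)
    assert res["H12"] == pytest.approx(0.68)
    assert res["H2_H1"] == pytest.approx((0.38 - 0.25) / 0.38)


def test_fst_examples():
    # fixed difference
    s = HaplotypeSample(
        matrix=np.array([[1], [1], [0], [0]], np.uint8),
        positions=np.array([10.0]),
        region_length=100.0,
        deme_labels=np.array([1, 1, 2, 2]),
    )
    assert fst_stats(s, span=100.0) == pytest.approx(1.0)
    # p1 = 0.8, p2 = 0.2 -> 1 - 0.32/0.68
    m = np.concatenate([np.repeat([1, 0], [8, 2]), np.repeat([1, 0], [2, 8])])
    s = HaplotypeSample(
        matrix=m[:, None].astype(np.uint8),
        positions=np.array([10.0]),
        region_length=100.0,
        deme_labels=np.repeat([1, 2], 10),
    )
    assert fst_stats(s, span=100.0) == pytest.approx(1 - 0.32 / 0.68)
    # equal frequencies -> plug-in FST 0
    m = np.concatenate([np.repeat([1, 0], [5, 5]), np.repeat([1, 0], [5, 5])])
    s = HaplotypeSample(
        matrix=m[:, None].astype(np.uint8),
        positions=np.array([10.0]),
        region_length=100.0,
        deme_labels=np.repeat([1, 2], 10),
    )
    assert fst_stats(s, span=100.0) == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# iHS / nSL


def test_identical_decay_gives_zero_score():
    # derived and ancestral carriers have mirror-image haplotype structure
    m = np.array(
        [
            [1, 1, 0, 1],
            [1, 1, 0, 0],
            [0, 0, 1, 1],
            [0, 0, 1, 0],
        ],
        dtype=np.uint8,
    )
    pos = np.array([10.0, 50.0, 60.0, 90.0])
    s = HaplotypeSample(matrix=m, positions=pos, region_length=100.0)
    df = ihs_nsl_scores(s)
    mid = df[df.site == 1]
    assert mid["ihs_raw"].iloc[0] == pytest.approx(0.0)
    assert mid["nsl_raw"].iloc[0] == pytest.approx(0.0)


def test_rare_pivot_excluded():
    rng = np.random.default_rng(5)
    m = rng.integers(0, 2, (50, 20)).astype(np.uint8)
    m[:, 3] = 0
    m[0, 3] = 1  # frequency 0.02 < 0.06
    pos = np.sort(rng.uniform(0, 1000, 20))
    s = HaplotypeSample(matrix=m, positions=pos, region_length=1000.0)
    df = ihs_nsl_scores(s)
    assert 3 not in set(df["site"])


def test_homogeneous_derived_block_scores_negative():
    """Two identical derived carriers next to diverse ancestral carriers:
    iHH_D > iHH_A so the log-ratio is negative."""
    m = np.array(
        [
            [1, 1, 0, 0, 1],
            [1, 1, 0, 0, 1],
            [0, 0, 1, 0, 1],
            [1, 0, 0, 1, 0],
        ],
        dtype=np.uint8,
    )
    # pivot site 1: derived rows 0,1 identical everywhere; ancestral rows 2,3
    # differ at every other site
    pos = np.array([10.0, 30.0, 50.0, 70.0, 90.0])
    s = HaplotypeSample(matrix=m, positions=pos, region_length=100.0)
    df = ihs_nsl_scores(s)
    row = df[df.site == 1]
    assert row["ihs_raw"].iloc[0] < 0


def test_nsl_ranks_match_ihs_under_uniform_spacing():
    rng = np.random.default_rng(6)
    m = rng.integers(0, 2, (20, 30)).astype(np.uint8)
    counts = m.sum(axis=0)
    m = m[:, (counts > 0) & (counts < 20)]
    pos = 10.0 * np.arange(1, m.shape[1] + 1)  # exactly uniform spacing
    s = HaplotypeSample(matrix=m, positions=pos, region_length=pos[-1] + 10)
    df = ihs_nsl_scores(s).dropna()
    ihs_rank = df["ihs_raw"].rank().to_numpy()
    nsl_rank = df["nsl_raw"].rank().to_numpy()
    assert len(df) > 5
    np.testing.assert_allclose(ihs_rank, nsl_rank)


def test_single_snp_sample_has_no_scores():
    s = HaplotypeSample(
        matrix=np.array([[1], [0], [1], [0]], np.uint8),
        positions=np.array([10.0]),
        region_length=100.0,
    )
    assert len(ihs_nsl_scores(s)) == 0


# ---------------------------------------------------------------------------
# normalisation and window significance


def test_normalising_nb_against_itself_gives_unit_bins():
    rng = np.random.default_rng(7)
    counts = rng.integers(3, 48, 500)
    raw = rng.normal(size=500) + counts * 0.1
    table = build_normalisation(counts, raw, n=50)
    z = table.normalise(counts, raw)
    for k in np.unique(counts):
        zz = z[counts == k]
        if zz.size >= 2:
            assert abs(zz.mean()) < 1e-9
            assert abs(zz.std(ddof=1) - 1) < 1e-9


def test_degenerate_bin_rejected_and_missing_bin_dropped():
    counts = np.array([10, 10, 10])
    with pytest.raises(ValueError, match="degenerate"):
        build_normalisation(counts, np.array([1.0, 1.0, 1.0]), n=50)
    table = NormalisationTable(n=50, mean={10: 0.0}, sd={10: 1.0})
    with pytest.warns(UserWarning, match="unpopulated"):
        z = table.normalise(np.array([10, 20]), np.array([1.0, 1.0]))
    assert z[0] == 1.0 and np.isnan(z[1])


def test_window_significance_examples():
    grid = make_windows(100.0, 100.0, 10.0)
    z = np.array([2.5, -1.0, 0.3, -2.2])
    pos = np.array([10.0, 20.0, 30.0, 40.0])
    assert window_significance(z, pos, grid)[0] == pytest.approx(0.5)
    assert window_significance(np.array([1.0, -1.9]), pos[:2], grid)[0] == 0.0
    assert np.isnan(window_significance(np.array([]), np.array([]), grid)[0])


# ---------------------------------------------------------------------------
# composite-likelihood scans


def test_clr_nonnegative_and_peaks_at_high_frequency_cluster():
    rng = np.random.default_rng(8)
    n, S = 20, 60
    m = rng.integers(0, 2, (n, S)).astype(np.uint8)
    pos = np.sort(rng.uniform(0, 600_000, S))
    # plant near-fixed derived sites around the centre
    centre = np.abs(pos - 300_000) < 50_000
    m[:, centre] = 1
    m[0, centre] = 0  # derived count n-1
    counts = m.sum(axis=0)
    keep = (counts > 0) & (counts < n)
    s = HaplotypeSample(matrix=m[:, keep], positions=pos[keep],
                        region_length=600_000.0)
    grid, clr = sf2_clr(s)
    assert np.nanmin(clr) >= 0.0
    centre_score = np.nanmax(clr[(grid > 250_000) & (grid < 350_000)])
    edge_score = np.nanmax(clr[grid < 50_000])
    assert centre_score > edge_score


def test_clr_too_few_snps_missing():
    s = HaplotypeSample(
        matrix=np.array([[1], [0]], np.uint8),
        positions=np.array([10.0]),
        region_length=600_000.0,
    )
    _, clr = sf2_clr(s)
    assert np.isnan(clr).all()


def _two_deme_sample(m1, m2, positions, L=600_000.0):
    m = np.vstack([m1, m2]).astype(np.uint8)
    labels = np.repeat([1, 2], [len(m1), len(m2)])
    return HaplotypeSample(
        matrix=m, positions=positions, region_length=L, deme_labels=labels
    )


def test_xpclr_null_on_identical_demes_and_positive_on_fixed_difference():
    rng = np.random.default_rng(9)
    base = rng.integers(0, 2, (25, 40)).astype(np.uint8)
    pos = np.sort(rng.uniform(0, 600_000, 40))
    s = _two_deme_sample(base, base, pos)
    _, score = xpclr(s, focal_deme=1)
    assert np.nanmax(np.abs(score)) == pytest.approx(0.0, abs=1e-9)

    m1 = base.copy()
    near = np.abs(pos - 100_000) < 60_000
    m1[:, near] = 1  # focal deme fixed derived near 100 kb
    m2 = base.copy()
    m2[: 12, near] = 1
    m2[12:, near] = 0  # control at intermediate frequency
    s = _two_deme_sample(m1, m2, pos)
    grid, score = xpclr(s, focal_deme=1)
    assert np.nanmin(score) >= 0.0
    assert np.nanmax(score[grid < 200_000]) > np.nanmax(score[grid > 400_000])


# ---------------------------------------------------------------------------
# invariances


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_statistics_invariant_to_row_and_column_order(seed):
    rng = np.random.default_rng(seed)
    s = random_sample(rng, n_max=8, s_max=8)
    if s.n_snp == 0:
        return
    res = sfs_stats(s.derived_counts(), s.n_hap)
    hap = haplotype_stats(s.matrix)
    perm = rng.permutation(s.n_hap)
    m2 = s.matrix[perm]
    res2 = sfs_stats(m2.sum(axis=0), s.n_hap)
    hap2 = haplotype_stats(m2)
    for k in res:
        np.testing.assert_allclose(res[k], res2[k], equal_nan=True)
    for k in hap:
        np.testing.assert_allclose(hap[k], hap2[k])
    cperm = rng.permutation(s.n_snp)
    hap3 = haplotype_stats(s.matrix[:, cperm])
    for k in hap:
        np.testing.assert_allclose(hap[k], hap3[k])


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_haplotype_spectrum_inequalities(seed):
    rng = np.random.default_rng(seed)
    s = random_sample(rng, n_max=8, s_max=8)
    res = haplotype_stats(s.matrix)
    h1, h12, h21 = res["H1"], res["H12"], res["H2_H1"]
    assert 0 <= h1 <= 1 and 0 <= h12 <= 1 and 0 <= h21 <= 1
    assert h12 >= h1 - 1e-12
    assert res["n_hap"] <= min(s.n_hap, 2 ** max(s.n_snp, 0))
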