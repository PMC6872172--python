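"""Single-site Wright-Fisher dynamics: drift/selection oracles, timing
summaries and the parameter grid."""

import numpy as np
import pandas as pd
import pytest

from demesweep.single_site import (
    DemeSpec,
    Trajectory,
    enumerate_grid,
    logistic_phase_time,
    log_ne_phase_ratio,
    simulate_single_site,
    simulate_timing_batch,
    summarize_timing,
    three_deme_rows,
    trajectory_stats,
    two_deme_rows,
)


def test_no_migration_keeps_recipient_deme_empty():
    """With migration numerically zero the allele never appears in d2 (the
    run is truncated: global fixation is unreachable)."""
    spec = DemeSpec(sizes=(200, 200), s=(0.05, 0.05), Nm=1e-12)
    traj = simulate_single_site(spec, seed=1, max_generations=2000)
    assert np.all(traj.freqs[:, 1] == 0.0)
    assert traj.freqs[-1, 0] == 1.0  # d1 itself fixed fine


def test_selection_phase_matches_logistic_oracle():
    """Median 5%->99.5% phase of a conditioned one-deme sweep is within 10%
    of the deterministic logistic travel time (~412 generations)."""
    spec = DemeSpec(sizes=(10_000,), s=(0.02,), Nm=1e-12)
    df = simulate_timing_batch(spec, 600, seed=2)
    # 1/s approximation ~ 412 generations; the exact discrete-map rate is
    # ln(1+s), giving ~ 416
    assert abs(logistic_phase_time(0.02) - 416.0) < 0.5
    median_phase = np.median(df["phase_d1"])
    assert abs(median_phase - 412.0) / 412.0 < 0.10


def test_neutral_drift_matches_binomial_oracle():
    """Without selection, E[dp] ~ 0 and Var(dp) ~ p(1-p)/N per generation."""
    rng = np.random.default_rng(3)
    N, p0, reps = 500, 0.3, 4000
    counts = rng.binomial(N, np.full(reps, p0))
    dp = counts / N - p0
    assert abs(dp.mean()) < 3 * np.sqrt(p0 * (1 - p0) / N / reps)
    var_expect = p0 * (1 - p0) / N
    assert abs(dp.var() - var_expect) / var_expect < 0.15


def test_high_migration_equals_panmictic_double_size():
    """At Nm = 200 the two demes behave as one deme of size 2N: median
    selection phases agree within 5%."""
    two = simulate_timing_batch(
        DemeSpec(sizes=(10_000, 10_000), s=(0.02, 0.02), Nm=200.0), 400, seed=4
    )
    one = simulate_timing_batch(
        DemeSpec(sizes=(20_000,), s=(0.02,), Nm=1e-12), 400, seed=5
    )
    m_two = np.median(two["phase_d2"])
    m_one = np.median(one["phase_d1"])
    assert abs(m_two - m_one) / m_one < 0.05


def test_median_completion_time_nonincreasing_in_migration(single_site_table):
    medians = (
        single_site_table.groupby("Nm")["t995_d2"].median().sort_index()
    )
    assert (np.diff(medians.to_numpy()) <= 0).all()


def test_completion_time_scales_with_log_ne():
    """The log(Ne)/s sojourn law predicts a completion-time ratio of
    log(1000)/log(10000) = 0.75 for Ne = 1000 vs 10000; the closed form is
    exact and the simulated one-deme medians land within 15% of it (the law
    describes the full fixation time, whose stochastic entry and exit phases
    carry the Ne dependence)."""
    assert log_ne_phase_ratio(1_000) == pytest.approx(0.75)
    assert log_ne_phase_ratio(5_000) == pytest.approx(np.log(5000) / np.log(10000))
    small = simulate_timing_batch(
        DemeSpec(sizes=(1_000,), s=(0.02,), Nm=1e-12), 500, seed=6
    )
    big = simulate_timing_batch(
        DemeSpec(sizes=(10_000,), s=(0.02,), Nm=1e-12), 500, seed=7
    )
    ratio = np.median(small["t995_d1"]) / np.median(big["t995_d1"])
    assert ratio < 1.0
    assert abs(ratio - 0.75) / 0.75 < 0.15


def test_stepping_stone_inflates_d2_variance():
    """At the lowest migration rate the d2 completion time is the sum of two
    waiting times under the stepping-stone layout, so its variance exceeds
    the fully connected layout's."""
    kw = dict(sizes=(2_000, 2_000, 2_000), s=(0.1, 0.1, 0.1), Nm=0.02)
    stepping = simulate_timing_batch(
        DemeSpec(layout="stepping", **kw), 250, seed=8
    )
    connected = simulate_timing_batch(
        DemeSpec(layout="connected", **kw), 250, seed=9
    )
    assert stepping["t995_d2"].var() > connected["t995_d2"].var()


def test_summarize_timing_arithmetic():
    freqs = np.zeros((601, 1))
    freqs[100:, 0] = 0.05
    freqs[512:, 0] = 0.995
    freqs[600, 0] = 1.0
    traj = Trajectory(
        freqs=freqs, spec=DemeSpec(sizes=(100,), s=(0.02,), Nm=1e-12), seed=0,
        restarts=0,
    )
    ts = summarize_timing(traj)
    assert ts.t5[0] == 100 and ts.t995[0] == 512
    assert ts.selection_phase[0] == 412
    assert ts.tfix[0] == 600


def test_waiting_period_definition():
    # three-deme trajectory: first copy in d1/d2 appears at generation 37
    freqs = np.zeros((50, 3))
    freqs[:, 0] = 0.5
    freqs[37:, 1] = 0.01
    traj = Trajectory(
        freqs=freqs,
        spec=DemeSpec(sizes=(100,) * 3, s=(0.02,) * 3, Nm=0.2, layout="connected"),
        seed=0,
        restarts=0,
    )
    assert summarize_timing(traj).waiting_period == 36


def test_truncated_run_reports_missing_thresholds():
    freqs = np.full((10, 1), 0.5)
    traj = Trajectory(
        freqs=freqs, spec=DemeSpec(sizes=(100,), s=(0.02,), Nm=1e-12), seed=0,
        restarts=0,
    )
    ts = summarize_timing(traj)
    assert np.isnan(ts.t995[0]) and not np.isnan(ts.t5[0])


def test_grid_enumeration_counts_and_exclusion():
    two = enumerate_grid(two_deme_rows())
    assert len(two) == 55
    excluded = [c for c in two if not c["execute"]]
    assert len(excluded) == 1
    assert excluded[0]["Nm"] == 0.02 and 0.0 in excluded[0]["s"]
    three = enumerate_grid(three_deme_rows())
    assert len(three) == 120
    assert sum(not c["execute"] for c in three) == 3  # one row x three layouts


def test_trajectory_stats_perfect_linearity_and_degeneracy():
    table = pd.DataFrame(
        {"Nm": [0.2, 2.0, 20.0] * 3, "y": np.tile(np.log10([0.2, 2.0, 20.0]), 3)}
    )
    assert trajectory_stats(table, "y")["r2"] == pytest.approx(1.0)
    table["z"] = 5.0
    res = trajectory_stats(table, "z")
    assert res["r2"] == 0.0 and res["degenerate"]


def test_batch_timing_is_seed_deterministic():
    spec = DemeSpec(sizes=(1_000, 1_000), s=(0.05, 0.05), Nm=2.0)
    a = simulate_timing_batch(spec, 20, seed=11)
    b = simulate_timing_batch(spec, 20, seed=11)
    pd.testing.assert_frame_equal(a, b)
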