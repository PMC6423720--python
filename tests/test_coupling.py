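"""Coupling statistics: Pearson calls, part-to-sum closed form, variance
decomposition, sibling differences, noise bootstrap, sample size."""

import math

import numpy as np
import pytest
from scipy import stats

from cyclephase import (
    BootstrapConfig,
    all_pairwise_coupling,
    noise_bootstrap_correlations,
    part_sum_correlation,
    pearson_coupling,
    sample_size_for_correlation,
    sibling_difference_coupling,
    simulate_phase_durations,
    variance_decomposition,
)
from cyclephase.records import table_from_durations


# ---------------------------------------------------------------------------
# pearson_coupling
# ---------------------------------------------------------------------------

def test_identity_is_coupled():
    x = np.arange(1.0, 20.0)
    res = pearson_coupling(x, x)
    assert res.r == pytest.approx(1.0)
    assert res.r2 == pytest.approx(1.0)
    assert res.call == "coupled"


def test_hand_computed_small_example():
    # cov = 3/...: r = 3/sqrt(2*4.6667) (sample covariance over sds)
    res = pearson_coupling([1, 2, 3], [1, 2, 4])
    assert res.r == pytest.approx(0.98198, abs=1e-5)
    assert res.r2 == pytest.approx(0.96429, abs=1e-5)


def test_independent_samples_are_uncoupled():
    rng = np.random.default_rng(0)
    res = pearson_coupling(rng.normal(size=10000), rng.normal(size=10000))
    assert res.call == "uncoupled"


def test_matches_textbook_formula():
    rng = np.random.default_rng(8)
    for _ in range(20):
        x = rng.normal(size=50)
        y = 0.3 * x + rng.normal(size=50)
        res = pearson_coupling(x, y)
        ref = np.mean((x - x.mean()) * (y - y.mean())) / (
            np.std(x) * np.std(y)
        )
        assert res.r == pytest.approx(ref, abs=1e-12)
        # p from the t transform with n-2 df
        t = ref * math.sqrt(48 / (1 - ref * ref))
        p_ref = 2 * stats.t.sf(abs(t), df=48)
        assert res.p == pytest.approx(p_ref, rel=1e-9)


def test_zero_variance_is_an_error():
    with pytest.raises(ValueError, match="zero variance"):
        pearson_coupling([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_weak_call_requires_significance_without_strength():
    rng = np.random.default_rng(3)
    x = rng.normal(size=5000)
    y = 0.15 * x + rng.normal(size=5000)  # r ~ 0.15: p tiny, r2 ~ 0.02
    res = pearson_coupling(x, y)
    assert res.p < 0.01 and res.r2 <= 0.1
    assert res.call == "weak"


def test_three_phases_give_three_pairs(rpe_table):
    results = all_pairwise_coupling(rpe_table)
    assert len(results) == 3
    assert {frozenset(r.pair) for r in results} == {
        frozenset(p) for p in (("G1", "S"), ("G1", "G2"), ("S", "G2"))
    }


# ---------------------------------------------------------------------------
# part-to-sum correlation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ratio,expected", [
    (0.0, 1.0),
    (1.0, 1 / math.sqrt(2)),
    (2.0, 1 / math.sqrt(5)),
])
def test_part_sum_closed_form(ratio, expected):
    assert part_sum_correlation(1.0, ratio) == pytest.approx(expected, abs=1e-12)


def test_part_sum_needs_positive_part_sd():
    with pytest.raises(ValueError):
        part_sum_correlation(0.0, 1.0)


def test_part_sum_matches_monte_carlo():
    rng = np.random.default_rng(19)
    n = 100000
    for ratio in (0.0, 0.5, 1.0, 2.0, 5.0):
        b = rng.normal(0, 1, n)
        c = rng.normal(0, ratio, n) if ratio else np.zeros(n)
        sim = stats.pearsonr(b, b + c).statistic
        assert abs(sim - part_sum_correlation(1.0, ratio)) < 0.02


# ---------------------------------------------------------------------------
# variance decomposition
# ---------------------------------------------------------------------------

def test_single_variable_phase_takes_all_variance():
    rng = np.random.default_rng(1)
    durs = [{"G1": g, "S": 5.0, "G2": 2.0, "M": 0.5}
            for g in rng.gamma(4, 1, 300)]
    frac = variance_decomposition(table_from_durations(durs))
    assert frac["G1"] == pytest.approx(1.0, abs=1e-9)
    assert frac["S"] == frac["G2"] == frac["M"] == 0.0


def test_fractions_follow_variance_shares():
    rng = np.random.default_rng(2)
    n = 100000
    durs = [
        {"G1": g, "S": s, "G2": 2.0 + 1e-6 * i, "M": 0.5}
        for i, (g, s) in enumerate(
            zip(rng.normal(10, 2, n), rng.normal(10, 1, n))
        )
    ]
    frac = variance_decomposition(table_from_durations(durs))
    assert frac["G1"] == pytest.approx(0.8, abs=0.01)
    assert frac["S"] == pytest.approx(0.2, abs=0.01)


def test_independent_phase_fractions_sum_to_one(rpe_table):
    frac = variance_decomposition(rpe_table)
    assert sum(frac.values()) == pytest.approx(1.0, abs=0.15)


# ---------------------------------------------------------------------------
# sibling differences (mechanics; the scientific property is exercised with
# the sister-pair generator in test_synth and the acceptance suite)
# ---------------------------------------------------------------------------

def test_sibling_difference_requires_pairs(rpe_table):
    with pytest.raises(ValueError, match="sister pairs"):
        sibling_difference_coupling(rpe_table)


# ---------------------------------------------------------------------------
# noise bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_yields_outer_times_inner_values(rpe_profile):
    table = simulate_phase_durations(rpe_profile, 120, seed=1)
    res = noise_bootstrap_correlations(
        table, ("G1", "S"), BootstrapConfig(n_outer=100, n_inner=100, seed=0)
    )
    assert res["n_replicates"] == 10000
    assert res["r_values"].shape == (10000,)


def test_bootstrap_delta_zero_is_point_mass(rpe_profile):
    table = simulate_phase_durations(rpe_profile, 50, seed=2)
    res = noise_bootstrap_correlations(
        table, ("G1", "S"), BootstrapConfig(n_outer=5, n_inner=5, delta=0.0, seed=3)
    )
    assert np.all(res["r_values"] == res["point_estimate"])


def test_bootstrap_null_mostly_uncoupled(rpe_profile):
    table = simulate_phase_durations(rpe_profile, 120, seed=4)
    res = noise_bootstrap_correlations(
        table, ("G1", "S"),
        BootstrapConfig(n_outer=20, n_inner=20, t_frame=1 / 6, seed=5),
    )
    assert res["fraction_uncoupled"] > 0.9


def test_bootstrap_clamps_nonpositive_durations():
    durs = [{"G1": 0.05, "S": 0.05, "G2": 1.0, "M": 0.5} for _ in range(30)]
    durs[0]["G1"] = 5.0  # avoid zero variance
    durs[0]["S"] = 5.0
    table = table_from_durations(durs)
    res = noise_bootstrap_correlations(
        table, ("G1", "S"),
        BootstrapConfig(n_outer=5, n_inner=5, delta=3.0, t_frame=1 / 6, seed=6),
    )
    assert res["n_clamped"] > 0
    assert np.all(np.isfinite(res["r_values"]))


# ---------------------------------------------------------------------------
# sample size
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("r2,alpha,power,expected", [
    (0.1, 0.01, 0.80, 112),  # the study's per-condition sample size
    (0.25, 0.05, 0.80, 29),  # textbook value for r = 0.5
    (0.9999, 0.01, 0.80, 4),  # perfect-correlation floor
])
def test_sample_size_reference_values(r2, alpha, power, expected):
    assert sample_size_for_correlation(r2, alpha, power) == expected


def test_sample_size_monotone_in_effect():
    ns = [sample_size_for_correlation(r2) for r2 in (0.05, 0.1, 0.3, 0.6)]
    assert ns == sorted(ns, reverse=True)


def test_null_pvalues_are_uniform(rpe_profile):
    """On independent Erlang phases the Pearson t-test p-value should be
    uniform; 2,000 null replicates at n = 125 must not reject uniformity."""
    rng = np.random.default_rng(99)
    pvals = np.empty(2000)
    for i in range(2000):
        x = rng.gamma(16, 7.9 / 16, 125)
        y = rng.gamma(64, 10.1 / 64, 125)
        pvals[i] = stats.pearsonr(x, y).pvalue
    assert stats.kstest(pvals, "uniform").pvalue > 0.01
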