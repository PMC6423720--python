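"""Erlang fitting: density values, MLE recovery, shared-rate model,
bootstrap spreads, KS validation and the Welch–Satterthwaite sum."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, special, stats

from cyclephase import (
    bootstrap_fit_sd,
    erlang_log_pdf,
    fit_erlang_phase,
    fit_shared_rate,
    validate_fit_ks,
    welch_satterthwaite,
)
from cyclephase.erlang import FitWarning, _profile_scan


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------

def test_log_pdf_hand_values():
    # k=2, lam=1, x=1: density = x e^{-x} = e^{-1}
    assert erlang_log_pdf(1.0, 2, 1.0, 1.0) == pytest.approx(-1.0, abs=1e-12)
    # exponential density near the origin tends to lam = 1
    assert erlang_log_pdf(1e-12, 1, 1.0, 1.0) == pytest.approx(0.0, abs=1e-9)


def test_log_pdf_large_shape_is_finite():
    v = erlang_log_pdf(10.0, 200, 20.0, 1.0)
    assert np.isfinite(v)


def test_log_pdf_matches_scipy_gamma():
    x = np.array([0.3, 1.7, 9.2])
    got = erlang_log_pdf(x, 5, 2.0, 1.0)
    ref = stats.gamma.logpdf(x, a=5, scale=0.5)
    assert got == pytest.approx(ref, abs=1e-12)


def test_log_pdf_rejects_nonpositive_duration():
    with pytest.raises(ValueError):
        erlang_log_pdf(0.0, 2, 1.0)
    with pytest.raises(ValueError):
        erlang_log_pdf(-1.0, 2, 1.0)


def test_log_pdf_rejects_noninteger_shape():
    with pytest.raises(ValueError):
        erlang_log_pdf(1.0, 2.5, 1.0)


# ---------------------------------------------------------------------------
# independent-rate fit
# ---------------------------------------------------------------------------

def test_exponential_data_recovers_k1():
    rng = np.random.default_rng(7)
    x = rng.exponential(1.0, size=2000)
    fit = fit_erlang_phase(x)
    assert fit.k == 1
    assert fit.lam == pytest.approx(1.0, rel=0.1)


def test_erlang8_recovery():
    rng = np.random.default_rng(11)
    x = rng.gamma(8, 1 / 1.2, size=1000)
    fit = fit_erlang_phase(x)
    assert fit.k in (7, 8, 9)
    assert fit.lam == pytest.approx(1.2, rel=0.1)


def test_constant_data_hits_kmax_with_warning():
    x = np.full(50, 3.0)
    with pytest.warns(FitWarning, match="boundary"):
        fit = fit_erlang_phase(x, k_max=200)
    assert fit.k == 200


@pytest.mark.parametrize("k", [1, 3, 8, 40, 200])
def test_profile_rate_matches_numeric_maximizer(k):
    """Closed-form λ̂ = k/mean is the root of the score dL/dλ = nk/λ − Σx."""
    rng = np.random.default_rng(100 + k)
    x = rng.gamma(8, 1 / 1.2, size=500)
    closed = k / np.mean(x)
    score = lambda lam: x.size * k / lam - np.sum(x)
    numeric = optimize.brentq(score, 1e-8, 1e6, xtol=1e-15, rtol=1e-15)
    assert abs(numeric - closed) / closed < 1e-10


def test_dt_never_changes_the_argmax():
    rng = np.random.default_rng(3)
    x = rng.gamma(12, 0.5, size=400)
    fits = [fit_erlang_phase(x, dt=dt) for dt in (1e-3, 1 / 6, 1.0, 24.0)]
    assert len({f.k for f in fits}) == 1
    assert len({round(f.lam, 12) for f in fits}) == 1
    # ΔT shifts the log-likelihood by exactly n·log ΔT
    assert fits[2].log_likelihood - fits[1].log_likelihood == pytest.approx(
        -400 * math.log(1 / 6), abs=1e-6
    )


def test_tie_break_prefers_smaller_k():
    # argmax of the scan is the first maximizer; verify against the raw scan
    rng = np.random.default_rng(5)
    x = rng.gamma(4, 1.0, size=50)
    fit = fit_erlang_phase(x, k_max=300)
    ks, ll = _profile_scan(x, 1.0, 300)
    best = ll.max()
    first_argmax = int(ks[np.flatnonzero(ll >= best - 1e-12)[0]])
    assert fit.k == first_argmax


# ---------------------------------------------------------------------------
# shared-rate fit
# ---------------------------------------------------------------------------

def _shared_data(lam=2.0, ks={"G1": 4, "S": 20, "G2": 8, "M": 1}, n=500, seed=0):
    rng = np.random.default_rng(seed)
    return {p: rng.gamma(k, 1 / lam, size=n) for p, k in ks.items()}


def test_shared_rate_recovery():
    data = _shared_data()
    fit = fit_shared_rate(data, seed=0)
    assert fit.lam == pytest.approx(2.0, rel=0.10)
    for p, k_true in {"G1": 4, "S": 20, "G2": 8, "M": 1}.items():
        assert abs(fit.k[p] - k_true) <= 1


def test_shared_rate_never_beats_independent_fits(rpe_table):
    data = {p: np.asarray(rpe_table.durations(p)) for p in ("G1", "S", "G2", "M")}
    shared = fit_shared_rate(data, seed=0)
    indep = sum(fit_erlang_phase(data[p]).log_likelihood for p in data)
    assert shared.log_likelihood <= indep + 1e-9


def test_shared_rate_matches_exhaustive_search_small_kmax():
    data = _shared_data(ks={"G1": 2, "S": 5, "G2": 3, "M": 1}, n=200, seed=2)
    fit = fit_shared_rate(data, k_max=8, seed=0)
    # brute force over all 8^4 shape vectors
    from itertools import product

    from cyclephase.erlang import _shared_loglik, _shared_loglik_terms

    terms = _shared_loglik_terms({p: np.asarray(x) for p, x in data.items()})
    best = max(
        (dict(zip(data, kv)) for kv in product(range(1, 9), repeat=4)),
        key=lambda kvec: _shared_loglik(kvec, terms, 1.0)[0],
    )
    assert fit.k == best


def test_heterogeneous_rates_strongly_favor_independent_model(rpe_table):
    """Phases with very different step rates: the single-rate model fits
    far worse, the reason it is rejected for real phase data."""
    data = {p: np.asarray(rpe_table.durations(p)) for p in ("G1", "S", "G2", "M")}
    shared = fit_shared_rate(data, seed=0)
    indep = sum(fit_erlang_phase(data[p]).log_likelihood for p in data)
    lr = 2 * (indep - shared.log_likelihood)
    assert lr > 50  # overwhelming likelihood-ratio evidence


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_sds_positive_and_finite():
    rng = np.random.default_rng(9)
    x = rng.gamma(8, 1 / 1.2, size=500)
    k_sd, lam_sd = bootstrap_fit_sd(x, n_boot=200, seed=1)
    assert 0 < k_sd < 10 and np.isfinite(k_sd)
    assert 0 < lam_sd < 1 and np.isfinite(lam_sd)


def test_bootstrap_sd_shrinks_with_duplicated_data():
    rng = np.random.default_rng(13)
    x = rng.gamma(6, 1.0, size=300)
    _, lam_sd = bootstrap_fit_sd(x, n_boot=400, seed=2)
    _, lam_sd2 = bootstrap_fit_sd(np.tile(x, 2), n_boot=400, seed=2)
    assert lam_sd2 / lam_sd == pytest.approx(1 / math.sqrt(2), rel=0.35)


def test_tiny_bootstrap_warns():
    rng = np.random.default_rng(1)
    x = rng.gamma(3, 1.0, size=60)
    with pytest.warns(FitWarning, match="unstable"):
        bootstrap_fit_sd(x, n_boot=2, seed=0)


# ---------------------------------------------------------------------------
# KS validation
# ---------------------------------------------------------------------------

def test_ks_calibrated_under_the_null():
    """When the observed sample really comes from the fitted distribution,
    the KS p-value is roughly uniform: the rejection rate at 0.05 stays
    near nominal (it would be conservative if the fit were re-estimated
    from the same observations)."""
    from cyclephase import ErlangFit

    rng = np.random.default_rng(21)
    fit = ErlangFit(phase="G1", k=8, lam=1.2, log_likelihood=0.0, n=300)
    n_reject = 0
    reps = 200
    for i in range(reps):
        x = fit.sample(300, rng)
        _, p = validate_fit_ks(x, fit, n_sim=1500, seed=1000 + i)
        n_reject += p < 0.05
    assert 0.01 <= n_reject / reps <= 0.10


def test_ks_rejects_gross_mismatch():
    rng = np.random.default_rng(2)
    x = rng.gamma(8, 1 / 1.2, size=500)
    fit = fit_erlang_phase(x)
    _, p = validate_fit_ks(x + 5.0, fit, n_sim=5000, seed=0)
    assert p < 1e-6


def test_ks_statistic_matches_reference_implementation():
    rng = np.random.default_rng(4)
    x = rng.gamma(8, 1 / 1.2, size=400)
    fit = fit_erlang_phase(x)
    d, _ = validate_fit_ks(x, fit, n_sim=400, seed=7)
    sim = fit.sample(400, np.random.default_rng(7))
    ref = stats.ks_2samp(x, sim).statistic
    assert d == pytest.approx(ref, abs=1e-12)


# ---------------------------------------------------------------------------
# Welch–Satterthwaite
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "components,expected",
    [
        ([(2, 1.0), (3, 1.0)], (5, 1.0)),  # equal scales: k just adds
        ([(4, 1.0), (1, 3.0)], (4, 1.75)),  # 49/13 ≈ 3.77 → 4, mean 7 kept
        ([(6, 0.5)], (6, 0.5)),  # single component unchanged
    ],
)
def test_ws_examples(components, expected):
    k, theta = welch_satterthwaite(components)
    assert k == expected[0]
    assert theta == pytest.approx(expected[1], abs=1e-12)


@given(
    st.lists(
        st.tuples(st.integers(1, 50), st.floats(0.01, 20.0)),
        min_size=1,
        max_size=6,
    )
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_ws_preserves_the_mean(components):
    k, theta = welch_satterthwaite(components)
    mean = sum(kk * th for kk, th in components)
    assert k * theta == pytest.approx(mean, rel=1e-12)
    # and the pre-rounding shape reproduces the printed formulas
    s1 = sum(th * kk for kk, th in components)
    s2 = sum(th * th * kk for kk, th in components)
    assert k == max(1, int(math.floor(s1 * s1 / s2 + 0.5)))


def test_ws_approximation_quality():
    """The two-parameter approximation of gamma(4,1)+gamma(1,3) is close in
    distribution (KS distance of large samples < 0.05)."""
    rng = np.random.default_rng(17)
    n = 100000
    conv = rng.gamma(4, 1.0, n) + rng.gamma(1, 3.0, n)
    k, theta = welch_satterthwaite([(4, 1.0), (1, 3.0)])
    approx = rng.gamma(k, theta, n)
    assert stats.ks_2samp(conv, approx).statistic < 0.05
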