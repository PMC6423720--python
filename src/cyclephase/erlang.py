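"""Erlang models of cell-cycle phase progression.

Each phase is modeled as a sequence of k exponential steps with common
rate λ, so the phase duration follows an Erlang(k, λ) distribution — a
gamma distribution with integer shape.  Two fits are provided:

* **independent-rate fit** — each phase gets its own (k, λ), found by an
  exhaustive scan over the integer shape with the rate profiled out in
  closed form;
* **shared-rate fit** — the simple Markovian model in which all four
  phases progress at one common step rate λ but have their own shapes,
  fit by coordinate ascent over the shape vector with the joint rate
  profiled in closed form.

The measurement interval ΔT enters the likelihood as an additive
constant per observation and therefore never changes the maximizer; it
is retained so reported log-likelihoods match the discretized density.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

logger = logging.getLogger("cyclephase")

DEFAULT_K_MAX = 500


class FitWarning(UserWarning):
    """Non-fatal fitting condition (boundary solution, tiny bootstrap...)."""


@dataclass
class ErlangFit:
    """Maximum-likelihood Erlang fit of one phase's durations."""

    phase: str
    k: int
    lam: float  # per-hour step rate
    log_likelihood: float
    n: int
    k_sd: float = 0.0
    lam_sd: float = 0.0
    dt: float = 1.0  # measurement interval used in the likelihood, hours

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"shape k must be >= 1, got {self.k}")
        if not self.lam > 0:
            raise ValueError(f"rate must be > 0, got {self.lam}")
        if self.n < 2:
            raise ValueError("need at least 2 observations")
        if self.k_sd < 0 or self.lam_sd < 0:
            raise ValueError("bootstrap sds must be >= 0")

    @property
    def mean(self) -> float:
        return self.k / self.lam

    def to_dict(self) -> dict:
        return {
            "phase": self.phase,
            "k": int(self.k),
            "lambda_per_h": self.lam,
            "k_sd": self.k_sd,
            "lambda_sd": self.lam_sd,
            "loglik": self.log_likelihood,
            "n": int(self.n),
            "dt_h": self.dt,
        }

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw durations from the fitted Erlang (gamma with integer shape)."""
        return rng.gamma(shape=self.k, scale=1.0 / self.lam, size=n)


@dataclass
class SharedRateFit:
    """Joint fit of all phases under a single common step rate."""

    lam: float
    k: dict[str, int] = field(default_factory=dict)  # phase -> shape
    log_likelihood: float = 0.0

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("rate must be > 0")
        if any(v < 1 for v in self.k.values()):
            raise ValueError("all shapes must be >= 1")

    def to_dict(self) -> dict:
        return {
            "lambda_per_h": self.lam,
            "k": {p: int(v) for p, v in self.k.items()},
            "loglik": self.log_likelihood,
        }


# ---------------------------------------------------------------------------
# Density and independent-rate fit
# ---------------------------------------------------------------------------

def erlang_log_pdf(x, k: int, lam: float, dt: float = 1.0):
    """Log of the Erlang density λ^k x^(k−1) e^(−λx) / (k−1)! times ΔT.

    The ΔT factor converts the density to a per-frame observation
    probability; it shifts the log-likelihood by a constant and never
    affects parameter estimates.  Uses log-gamma internally so large k
    cannot overflow.
    """
    if int(k) != k or k < 1:
        raise ValueError(f"shape k must be a positive integer, got {k}")
    if not lam > 0:
        raise ValueError(f"rate must be > 0, got {lam}")
    if not dt > 0:
        raise ValueError(f"measurement interval must be > 0, got {dt}")
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("durations must be strictly positive")
    k = int(k)
    out = (
        k * np.log(lam)
        + (k - 1) * np.log(x)
        - lam * x
        - special.gammaln(k)
        + np.log(dt)
    )
    return float(out) if out.ndim == 0 else out


def _profile_scan(x: np.ndarray, dt: float, k_max: int):
    """Log-likelihood over k = 1..k_max with the rate profiled out.

    For fixed k the rate MLE is λ̂(k) = k / mean(x) (from dL/dλ = 0),
    giving the profile log-likelihood
    n·k·log(k/x̄) + (k−1)·Σlog x − n·k − n·logΓ(k) + n·log ΔT.
    """
    n = x.size
    xbar = float(np.mean(x))
    slog = float(np.sum(np.log(x)))
    ks = np.arange(1, k_max + 1, dtype=float)
    ll = (
        n * ks * np.log(ks / xbar)
        + (ks - 1.0) * slog
        - n * ks
        - n * special.gammaln(ks)
        + n * np.log(dt)
    )
    return ks, ll


def fit_erlang_phase(
    durations,
    dt: float = 1.0,
    k_max: int = DEFAULT_K_MAX,
    phase: str = "",
) -> ErlangFit:
    """Fit an Erlang(k, λ) to one phase's durations by exact MLE.

    The integer shape is found by exhaustive scan over 1..k_max using the
    closed-form profile rate λ̂(k) = k/mean; ties in log-likelihood break
    toward the smaller k.  A shape landing on k_max triggers a boundary
    warning (near-deterministic data pushes k toward infinity).
    """
    x = np.asarray(durations, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 durations to fit")
    if np.any(x <= 0):
        raise ValueError("durations must be strictly positive")
    if not dt > 0:
        raise ValueError("measurement interval must be > 0")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    ks, ll = _profile_scan(x, dt, k_max)
    i = int(np.argmax(ll))  # argmax returns the first (smallest-k) maximizer
    k_hat = int(ks[i])
    if k_hat == k_max:
        warnings.warn(
            f"fitted shape hit k_max={k_max}; likely boundary solution "
            "(data too regular for the scanned range)",
            FitWarning,
            stacklevel=2,
        )
    lam_hat = k_hat / float(np.mean(x))
    return ErlangFit(
        phase=phase,
        k=k_hat,
        lam=lam_hat,
        log_likelihood=float(ll[i]),
        n=int(x.size),
        dt=dt,
    )


# ---------------------------------------------------------------------------
# Shared-rate (simple Markovian) fit
# ---------------------------------------------------------------------------

def _shared_loglik_terms(data: dict[str, np.ndarray]):
    stats_ = {}
    for p, x in data.items():
        stats_[p] = (x.size, float(np.sum(x)), float(np.sum(np.log(x))))
    return stats_


def _shared_loglik(kvec: dict[str, int], terms, dt: float):
    """Joint log-likelihood with λ profiled: λ̂ = Σ n_p k_p / Σ_p Σx."""
    num = sum(terms[p][0] * kvec[p] for p in kvec)
    den = sum(terms[p][1] for p in kvec)
    lam = num / den
    ll = 0.0
    for p, k in kvec.items():
        n_p, sx, slog = terms[p]
        ll += (
            n_p * k * np.log(lam)
            + (k - 1) * slog
            - lam * sx
            - n_p * special.gammaln(k)
            + n_p * np.log(dt)
        )
    return float(ll), float(lam)


def fit_shared_rate(
    data: dict[str, "np.ndarray | list"],
    dt: float = 1.0,
    k_max: int = DEFAULT_K_MAX,
    n_restarts: int = 10,
    max_sweeps: int = 50,
    seed: int | None = 0,
) -> SharedRateFit:
    """Fit the single-rate model: all phases share one step rate λ.

    ``data`` maps phase label to its duration sample.  The joint likelihood
    is the product of the per-phase Erlang densities with a common λ.
    Given a shape vector the common rate has the closed form
    λ̂ = (Σ_p n_p k_p) / (Σ_p Σ x); the shape vector is optimized by
    coordinate ascent (full scan of one phase's k at a time) from several
    seeded random restarts.
    """
    data = {p: np.asarray(x, dtype=float) for p, x in data.items()}
    for p, x in data.items():
        if x.size == 0:
            raise ValueError(f"phase {p} has no durations")
        if np.any(x <= 0):
            raise ValueError(f"phase {p} has non-positive durations")
    terms = _shared_loglik_terms(data)
    phases = list(data)
    rng = np.random.default_rng(seed)

    best_ll, best_k, best_lam = -np.inf, None, None
    starts = [{p: 1 for p in phases}]  # deterministic start plus random ones
    for _ in range(max(0, n_restarts - 1)):
        starts.append({p: int(rng.integers(1, min(k_max, 100) + 1)) for p in phases})

    candidates = np.arange(1, k_max + 1)
    for kvec in starts:
        kvec = dict(kvec)
        prev = None
        for _ in range(max_sweeps):
            for p in phases:
                # scan this phase's shape with the others held fixed;
                # vectorized over candidates with λ profiled per candidate
                n_p, sx_p, slog_p = terms[p]
                num_other = sum(terms[q][0] * kvec[q] for q in phases if q != p)
                den = sum(terms[q][1] for q in phases)
                lam_c = (num_other + n_p * candidates) / den
                ll_c = np.zeros(candidates.size)
                for q in phases:
                    n_q, sx_q, slog_q = terms[q]
                    k_q = candidates if q == p else kvec[q]
                    ll_c += (
                        n_q * k_q * np.log(lam_c)
                        + (k_q - 1) * slog_q
                        - lam_c * sx_q
                        - n_q * special.gammaln(k_q)
                        + n_q * np.log(dt)
                    )
                kvec[p] = int(candidates[int(np.argmax(ll_c))])
            cur = tuple(kvec[p] for p in phases)
            if cur == prev:
                break
            prev = cur
        else:
            logger.warning("shared-rate coordinate ascent hit max_sweeps=%d", max_sweeps)
        ll, lam = _shared_loglik(kvec, terms, dt)
        if ll > best_ll:
            best_ll, best_k, best_lam = ll, dict(kvec), lam
    assert best_k is not None
    return SharedRateFit(lam=best_lam, k=best_k, log_likelihood=best_ll)


# ---------------------------------------------------------------------------
# Bootstrap and validation
# ---------------------------------------------------------------------------

def bootstrap_fit_sd(
    durations,
    dt: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = 0,
    k_max: int = DEFAULT_K_MAX,
) -> tuple[float, float]:
    """Bootstrap standard deviations of the fitted (k, λ).

    Resamples the durations with replacement ``n_boot`` times and refits;
    returns (sd of k̂, sd of λ̂).
    """
    x = np.asarray(durations, dtype=float)
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if n_boot < 50:
        warnings.warn(
            f"n_boot={n_boot} is very small; bootstrap sds will be unstable",
            FitWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    k_hats = np.empty(n_boot)
    lam_hats = np.empty(n_boot)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FitWarning)
        for b in range(n_boot):
            xb = rng.choice(x, size=x.size, replace=True)
            fit = fit_erlang_phase(xb, dt=dt, k_max=k_max)
            k_hats[b] = fit.k
            lam_hats[b] = fit.lam
    return float(np.std(k_hats, ddof=1)), float(np.std(lam_hats, ddof=1))


def validate_fit_ks(
    observed,
    fit: ErlangFit,
    n_sim: int = 10000,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov–Smirnov test of fit adequacy.

    Simulates ``n_sim`` durations from the fitted Erlang and compares them
    with the observed sample; returns (D, p).
    """
    rng = np.random.default_rng(seed)
    sim = fit.sample(n_sim, rng)
    res = stats.ks_2samp(np.asarray(observed, dtype=float), sim, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Welch–Satterthwaite approximation of a sum of Erlangs
# ---------------------------------------------------------------------------

def welch_satterthwaite(components) -> tuple[int, float]:
    """Approximate a sum of Erlang variables by a single Erlang.

    ``components`` is a sequence of (k_i, θ_i) shape/scale pairs.  The
    moment-matching gamma has

        k_sum = (Σ θ_i k_i)² / (Σ θ_i² k_i),   θ_sum = (Σ θ_i k_i) / k_sum,

    which matches the mean exactly and the variance as closely as a
    two-parameter gamma allows.  The shape is then rounded half-up to the
    nearest integer and the scale rescaled so the mean k·θ is preserved.
    """
    comps = [(int(k), float(th)) for k, th in components]
    if not comps:
        raise ValueError("need at least one component")
    for k, th in comps:
        if k < 1:
            raise ValueError(f"component shape must be >= 1, got {k}")
        if not th > 0:
            raise ValueError(f"component scale must be > 0, got {th}")
    s1 = sum(th * k for k, th in comps)  # mean
    s2 = sum(th * th * k for k, th in comps)  # variance
    k_real = s1 * s1 / s2
    k_int = int(np.floor(k_real + 0.5))  # round half-up
    k_int = max(k_int, 1)
    theta = s1 / k_int  # mean-preserving rescale
    return k_int, theta
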