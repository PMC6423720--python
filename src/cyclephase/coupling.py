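"""Phase-coupling statistics.

Coupling between two phases is assessed by the Pearson correlation of
their durations across single cells with a two-sided t-test p-value.
A pair is called *coupled* only when the correlation is both significant
(p < 0.01) and strong (R² > 0.1); significant-but-weak correlations are
flagged separately, everything else is *uncoupled*.  The module also
provides the part-to-sum closed form ρ = 1/√(1 + (σ_C/σ_B)²), variance
decomposition of total cycle duration, sibling-difference analysis, a
noise-injection bootstrap reproducing frame-resolution measurement
error, and Fisher-z sample-size computation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .records import PhaseTable

logger = logging.getLogger("cyclephase")

DEFAULT_ALPHA = 0.01
DEFAULT_R2_STRONG = 0.1
COUPLING_PHASES = ("G1", "S", "G2")  # M is excluded: ~30 min, near the frame rate


@dataclass
class CouplingResult:
    """Pearson coupling of one phase pair (or phase vs total)."""

    pair: tuple[str, str]
    r: float
    r2: float
    p: float
    n: int
    call: str  # coupled | weak | uncoupled

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("r must be in [-1, 1]")
        if abs(self.r2 - self.r * self.r) > 1e-12:
            raise ValueError("r2 must equal r squared")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.call not in ("coupled", "weak", "uncoupled"):
            raise ValueError(f"unknown call {self.call!r}")


def _call(p: float, r2: float, alpha: float, r2_strong: float) -> str:
    if p < alpha and r2 > r2_strong:
        return "coupled"
    if p < alpha:
        return "weak"
    return "uncoupled"


def pearson_coupling(
    x,
    y,
    pair: tuple[str, str] = ("A", "B"),
    alpha: float = DEFAULT_ALPHA,
    r2_strong: float = DEFAULT_R2_STRONG,
) -> CouplingResult:
    """Pearson r, R², and t-test p-value for one pair of duration vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("correlation undefined: zero variance in an input")
    res = stats.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    r = max(-1.0, min(1.0, r))
    return CouplingResult(
        pair=pair, r=r, r2=r * r, p=p, n=int(x.size),
        call=_call(p, r * r, alpha, r2_strong),
    )


def all_pairwise_coupling(
    table: PhaseTable,
    phases=COUPLING_PHASES,
    alpha: float = DEFAULT_ALPHA,
    r2_strong: float = DEFAULT_R2_STRONG,
) -> list[CouplingResult]:
    """One coupling result per unordered phase pair (default G1/S/G2)."""
    durs = {p: np.asarray(table.durations(p)) for p in phases}
    out = []
    for a, b in combinations(phases, 2):
        out.append(
            pearson_coupling(durs[a], durs[b], pair=(a, b), alpha=alpha,
                             r2_strong=r2_strong)
        )
    return out


def part_sum_correlation(sigma_b: float, sigma_c: float) -> float:
    """Correlation of an independent part B with the sum A = B + C.

    ρ_{A,B} = 1 / sqrt(1 + (σ_C/σ_B)²): the part-to-sum correlation is
    always positive and scales with B's share of A's variance.
    """
    if not sigma_b > 0:
        raise ValueError("sigma_b must be > 0")
    if sigma_c < 0:
        raise ValueError("sigma_c must be >= 0")
    return 1.0 / math.sqrt(1.0 + (sigma_c / sigma_b) ** 2)


def variance_decomposition(table: PhaseTable, phases=("G1", "S", "G2", "M")) -> dict[str, float]:
    """Share of total-cycle-duration variance attributed to each phase.

    The share of phase P is R²(d_P, d_total) with d_total the per-cell
    sum of all phase durations.  For mutually independent phases the
    shares sum to ~1; correlated phases need not.
    """
    durs = {p: np.asarray(table.durations(p)) for p in phases}
    total = sum(durs.values())
    out = {}
    for p in phases:
        if np.std(durs[p]) == 0.0:
            out[p] = 0.0
            continue
        r = stats.pearsonr(durs[p], total).statistic
        out[p] = float(r * r)
    return out


def sibling_difference_coupling(
    table: PhaseTable,
    phases=COUPLING_PHASES,
    alpha: float = DEFAULT_ALPHA,
    r2_strong: float = DEFAULT_R2_STRONG,
    seed: int = 0,
) -> list[CouplingResult]:
    """Coupling between sister-difference durations, per phase pair.

    For each sister pair the per-phase differences ΔP = d_P(sister 1) −
    d_P(sister 2) are formed with a seeded random sister ordering (to
    avoid labeling bias), then each pair of distinct phases is tested
    for correlation of their Δs across pairs.  Heritability (high
    between-sister correlation) does not by itself couple the Δs: that
    requires interdependent factor assortment.
    """
    pairs = table.sister_pairs()
    if len(pairs) < 3:
        raise ValueError("need at least 3 complete sister pairs")
    rng = np.random.default_rng(seed)
    deltas = {p: [] for p in phases}
    for rec1, rec2 in pairs:
        if rng.random() < 0.5:
            rec1, rec2 = rec2, rec1
        for p in phases:
            d1, d2 = rec1.duration(p), rec2.duration(p)
            if d1 is None or d2 is None:
                raise ValueError(f"incomplete sister pair for phase {p}")
            deltas[p].append(d1 - d2)
    out = []
    for a, b in combinations(phases, 2):
        out.append(
            pearson_coupling(deltas[a], deltas[b], pair=(a, b), alpha=alpha,
                             r2_strong=r2_strong)
        )
    return out


def sister_correlations(table: PhaseTable, phases=COUPLING_PHASES) -> dict[str, float]:
    """Between-sister Pearson correlation of each phase's duration."""
    pairs = table.sister_pairs()
    out = {}
    for p in phases:
        x = np.array([a.duration(p) for a, b in pairs], dtype=float)
        y = np.array([b.duration(p) for a, b in pairs], dtype=float)
        out[p] = float(stats.pearsonr(x, y).statistic)
    return out


# ---------------------------------------------------------------------------
# Noise-injection bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapConfig:
    """Two-level noise-injection bootstrap configuration.

    delta is the frame-error multiplier converting the imaging interval
    T into the half-width of the uniform noise on each phase boundary;
    delta = 3 reflects a ±1-frame boundary identification accuracy on
    top of the within-frame timing uncertainty.
    """

    n_outer: int = 100
    n_inner: int = 100
    delta: float = 3.0
    t_frame: float = 10.0 / 60.0  # hours
    seed: int = 0
    with_replacement: bool = False  # optional standard-bootstrap mode

    def __post_init__(self) -> None:
        if self.n_outer < 1 or self.n_inner < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not self.t_frame > 0:
            raise ValueError("t_frame must be > 0")


def noise_bootstrap_correlations(
    table: PhaseTable,
    pair: tuple[str, str] = ("G1", "S"),
    cfg: BootstrapConfig | None = None,
    r2_strong: float = DEFAULT_R2_STRONG,
) -> dict:
    """Distribution of Pearson R under frame-resolution measurement noise.

    Every replicate uses all N cells (selection without replacement at
    the full sample size); variability comes only from the injected
    noise: each phase duration receives ε_begin + ε_end with each
    ε ~ Uniform(−0.5, 0.5)·T·δ, drawn independently per phase and per
    cell.  The outer×inner loop yields n_outer·n_inner R values; the
    summary reports the fraction with R² below the strong-coupling
    threshold.  Durations driven non-positive by noise are clamped to
    one frame and counted.
    """
    cfg = cfg or BootstrapConfig()
    x = np.asarray(table.durations(pair[0]), dtype=float)
    y = np.asarray(table.durations(pair[1]), dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 cells")
    rng = np.random.default_rng(cfg.seed)
    n_rep = cfg.n_outer * cfg.n_inner
    scale = cfg.t_frame * cfg.delta
    n_clamped = 0
    rs = np.empty(n_rep)
    for rep in range(n_rep):
        if cfg.with_replacement:
            idx = rng.integers(0, n, size=n)
            xb, yb = x[idx], y[idx]
        else:
            xb, yb = x, y  # full sample, no resampling variability
        if scale > 0:
            ex = (rng.uniform(-0.5, 0.5, n) + rng.uniform(-0.5, 0.5, n)) * scale
            ey = (rng.uniform(-0.5, 0.5, n) + rng.uniform(-0.5, 0.5, n)) * scale
            xn, yn = xb + ex, yb + ey
        else:
            xn, yn = xb.copy(), yb.copy()
        for arr in (xn, yn):
            bad = arr <= 0
            if bad.any():
                n_clamped += int(bad.sum())
                arr[bad] = cfg.t_frame
        rs[rep] = stats.pearsonr(xn, yn).statistic
    if n_clamped:
        logger.info("noise bootstrap clamped %d non-positive durations", n_clamped)
    point = float(stats.pearsonr(x, y).statistic)
    return {
        "r_values": rs,
        "point_estimate": point,
        "fraction_uncoupled": float(np.mean(rs**2 < r2_strong)),
        "n_cells": int(n),
        "n_replicates": int(n_rep),
        "n_clamped": int(n_clamped),
    }


# ---------------------------------------------------------------------------
# Sample size
# ---------------------------------------------------------------------------

def sample_size_for_correlation(
    r2_threshold: float, alpha: float = 0.01, power: float = 0.80
) -> int:
    """Cells needed to detect a correlation of R² = r2_threshold.

    Fisher-z method with the small-sample correction:
    n = ((z_{1−α/2} + z_{power}) / atanh(r))² + 3, rounded to the
    nearest integer as in the standard sample-size tables, with a floor
    of 4 (the smallest n giving the t-test a positive degree of
    freedom margin).  At R² = 0.1, two-sided α = 0.01 and power 0.80
    this yields 112 cells per condition.
    """
    if not (0.0 < r2_threshold < 1.0):
        raise ValueError("r2_threshold must be in (0, 1)")
    if not (0.0 < alpha < 1.0) or not (0.0 < power < 1.0):
        raise ValueError("alpha and power must be in (0, 1)")
    r = math.sqrt(r2_threshold)
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    n = ((z_a + z_b) / math.atanh(r)) ** 2 + 3.0
    return max(4, int(math.floor(n + 0.5)))
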