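"""Synthetic single-cell data with the statistical structure the analysis
assumes: Erlang phase durations, frame-quantized measurement, sister
pairs sharing heritable factors, and 1-D reporter traces.

Cell-type profiles hold per-phase Erlang (k, λ).  The bundled presets
use published mean phase durations for an untransformed epithelial line
(RPE), an osteosarcoma line (U2OS) and a human embryonic stem-cell line
(H9); shapes are representative of fitted phase distributions (many
steps for S, fewer for the gap phases).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .factors import FactorEnsemble, FactorModelParams, draw_factor_ensemble
from .records import (
    DEFAULT_FRAME_INTERVAL_H,
    PHASES,
    PhaseRecord,
    PhaseTable,
)
from .traces import PCNA_VARIANCE, PIP_MVENUS, TraceSeries

logger = logging.getLogger("cyclephase")


@dataclass(frozen=True)
class CellTypeProfile:
    """Per-phase Erlang shape and rate for one cell type."""

    label: str
    k: dict[str, int]
    lam: dict[str, float]  # per hour

    def __post_init__(self) -> None:
        for p in PHASES:
            if p not in self.k or p not in self.lam:
                raise ValueError(f"profile {self.label}: missing phase {p}")
        for p, kk in self.k.items():
            if isinstance(kk, bool) or int(kk) != kk or kk < 1:
                raise TypeError(f"profile {self.label}: k[{p}] must be a positive integer")
        for p, lm in self.lam.items():
            if not lm > 0:
                raise ValueError(f"profile {self.label}: lam[{p}] must be > 0")

    def mean(self, phase: str) -> float:
        return self.k[phase] / self.lam[phase]


def _profile(label, means, shapes) -> CellTypeProfile:
    return CellTypeProfile(
        label=label,
        k=dict(shapes),
        lam={p: shapes[p] / means[p] for p in PHASES},
    )


#: Mean durations (h): RPE G1 7.9, S 10.1, G2 3.4, M 0.5; H9 G1 2.1,
#: S 7.6, G2 4.0, M 0.5; U2OS intermediate.
PROFILES = {
    "rpe": _profile("rpe", {"G1": 7.9, "S": 10.1, "G2": 3.4, "M": 0.5},
                    {"G1": 16, "S": 64, "G2": 16, "M": 4}),
    "u2os": _profile("u2os", {"G1": 5.0, "S": 9.0, "G2": 3.7, "M": 0.5},
                     {"G1": 12, "S": 64, "G2": 16, "M": 4}),
    "h9": _profile("h9", {"G1": 2.1, "S": 7.6, "G2": 4.0, "M": 0.5},
                   {"G1": 8, "S": 48, "G2": 16, "M": 4}),
}


@dataclass
class LineageSimConfig:
    """Configuration for the sister-pair generator."""

    n_pairs: int = 500
    sister_sharing: float = 0.9  # correlation of factor abundances between sisters
    assortment: str = "independent"  # or "interdependent"
    rate_cv: float = 0.6  # CV of the heritable rate modulation
    gamma_noise: bool = True  # Erlang sampling noise on top of the rates
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sister_sharing <= 1.0):
            raise ValueError("sister_sharing must be in [0, 1]")
        if self.assortment not in ("independent", "interdependent"):
            raise ValueError("assortment must be 'independent' or 'interdependent'")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.rate_cv < 0:
            raise ValueError("rate_cv must be >= 0")


# ---------------------------------------------------------------------------
# Plain Erlang and normal-model samplers
# ---------------------------------------------------------------------------

def simulate_phase_durations(
    profile: CellTypeProfile,
    n: int,
    seed: int = 0,
    condition: str | None = None,
    frame_interval: float = DEFAULT_FRAME_INTERVAL_H,
) -> PhaseTable:
    """Draw n cells with independent Erlang phase durations.

    Event times are laid out cumulatively from birth at t = 0 so the
    table carries both events and durations.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cond = condition if condition is not None else profile.label
    durs = {
        p: rng.gamma(shape=profile.k[p], scale=1.0 / profile.lam[p], size=n)
        for p in PHASES
    }
    records = []
    for i in range(n):
        g1, s, g2, m = (durs[p][i] for p in PHASES)
        t0 = 0.0
        records.append(
            PhaseRecord(
                cell_id=f"{cond}{i:05d}",
                condition=cond,
                frame_interval=frame_interval,
                t_birth=t0,
                t_s_onset=t0 + g1,
                t_s_end=t0 + g1 + s,
                t_m_start=t0 + g1 + s + g2,
                t_telophase=t0 + g1 + s + g2 + m,
                d_g1=g1,
                d_s=s,
                d_g2=g2,
                d_m=m,
            )
        )
    return PhaseTable(records)


def simulate_phase_durations_normal(
    mean: float, variance: float, n: int, seed: int = 0
) -> np.ndarray:
    """Durations from a normal(μ, σ²) model, resampled until positive.

    Truncation at zero is a policy the normal model needs but the
    Erlang model does not; when the truncated mass exceeds 1% a warning
    flags that the sample moments are materially distorted.
    """
    if variance < 0:
        raise ValueError("variance must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sd = math.sqrt(variance)
    if sd == 0.0:
        return np.full(n, float(mean))
    p_neg = stats.norm.cdf(0.0, loc=mean, scale=sd)
    if p_neg > 0.01:
        warnings.warn(
            f"normal({mean}, {variance}) puts {p_neg:.1%} of its mass at "
            "non-positive durations; truncation materially distorts moments",
            UserWarning,
            stacklevel=2,
        )
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


# ---------------------------------------------------------------------------
# Frame quantization
# ---------------------------------------------------------------------------

def apply_frame_quantization(
    table: PhaseTable, frame_interval: float | None = None, seed: int = 0
) -> PhaseTable:
    """Snap event times onto an acquisition grid.

    Each cell gets a uniformly random grid offset; every event is
    recorded at the first acquisition frame at or after it happens, so
    each observed event time errs by at most one frame interval.
    Coincident snapped events are pushed apart by one frame so all
    durations stay positive (minimum one frame).
    """
    rng = np.random.default_rng(seed)
    records = []
    for rec in table:
        dt = frame_interval if frame_interval is not None else rec.frame_interval
        if not dt > 0:
            raise ValueError("frame_interval must be > 0")
        if not rec.has_events():
            raise ValueError(f"{rec.cell_id}: frame quantization needs event times")
        u = rng.uniform(0.0, dt)
        snapped = []
        for t in rec.event_times():
            q = u + dt * math.ceil((t - u) / dt)
            if snapped and q <= snapped[-1]:
                q = snapped[-1] + dt  # at least one frame per phase
            snapped.append(q)
        new = replace(
            rec,
            frame_interval=dt,
            t_birth=snapped[0],
            t_s_onset=snapped[1],
            t_s_end=snapped[2],
            t_m_start=snapped[3],
            t_telophase=snapped[4],
            d_g1=None, d_s=None, d_g2=None, d_m=None,
        )
        from .records import durations_from_events

        records.append(durations_from_events(new))
    return PhaseTable(records)


# ---------------------------------------------------------------------------
# Sister pairs sharing heritable factors
# ---------------------------------------------------------------------------

def _sister_copy_numbers(
    ensemble: FactorEnsemble, cfg: LineageSimConfig, rng: np.random.Generator
):
    """Copy numbers for the two sisters of one division.

    Each factor type's copies are the mean abundance plus a deviation
    split into a mother-shared part (weight sqrt(sister_sharing)) and a
    per-sister jitter (weight sqrt(1 − sister_sharing)); deviations are
    Gaussian with the Poisson variance.  With independent assortment the
    jitter is independent across factor types; the interdependent
    counterfactual makes each sister's jitter proportional across types
    along the ensemble's net-effect direction, so the deviations of all
    factor types rise and fall together.
    """
    mu = ensemble.mean_abundance
    sd = np.sqrt(mu)
    rho = cfg.sister_sharing
    shared = rng.normal(0.0, sd)
    if cfg.assortment == "independent":
        jit1 = rng.normal(0.0, sd)
        jit2 = rng.normal(0.0, sd)
    else:
        # direction whose projection onto every phase's effect vector is ~1
        direction = np.zeros_like(mu)
        for p, a in ensemble.coeffs.items():
            norm = ensemble.norm.get(p, 0.0)
            if norm > 0:
                direction += a / norm
        direction *= mu
        jit1 = rng.normal() * direction
        jit2 = rng.normal() * direction
    w_sh, w_j = math.sqrt(rho), math.sqrt(1.0 - rho)
    n1 = mu + w_sh * shared + w_j * jit1
    n2 = mu + w_sh * shared + w_j * jit2
    return n1, n2


def simulate_sister_pairs(
    profile: CellTypeProfile,
    factors: FactorModelParams,
    cfg: LineageSimConfig,
) -> PhaseTable:
    """Generate sister-cell pairs coupled through shared heritable factors.

    Per pair, factor copy numbers are drawn with between-sister
    correlation ``cfg.sister_sharing``; each sister's per-phase rate is
    the profile rate modulated multiplicatively by the standardized,
    effect-weighted copy-number deviations at strength ``cfg.rate_cv``
    (multiplicative so rates stay positive), and durations are Erlang
    draws at those rates (or deterministic k/λ when ``gamma_noise`` is
    off).
    """
    rng = np.random.default_rng(cfg.seed)
    ensemble = draw_factor_ensemble(factors, seed=int(rng.integers(2**31 - 1)))
    eta = cfg.rate_cv
    records = []
    for ip in range(cfg.n_pairs):
        n1, n2 = _sister_copy_numbers(ensemble, cfg, rng)
        ids = (f"pair{ip:05d}a", f"pair{ip:05d}b")
        for cid, sid, counts in ((ids[0], ids[1], n1), (ids[1], ids[0], n2)):
            dev = counts - ensemble.mean_abundance
            durs = {}
            for p in PHASES:
                norm = ensemble.norm.get(p, 0.0)
                z = float(dev @ ensemble.coeffs[p] / norm) if norm > 0 else 0.0
                lam = profile.lam[p] * math.exp(eta * z - 0.5 * eta * eta)
                if cfg.gamma_noise:
                    durs[p] = float(rng.gamma(profile.k[p], 1.0 / lam))
                else:
                    durs[p] = profile.k[p] / lam
            records.append(
                PhaseRecord(
                    cell_id=cid,
                    condition=profile.label,
                    sister_id=sid,
                    d_g1=durs["G1"],
                    d_s=durs["S"],
                    d_g2=durs["G2"],
                    d_m=durs["M"],
                )
            )
    return PhaseTable(records)


# ---------------------------------------------------------------------------
# Reporter traces
# ---------------------------------------------------------------------------

@dataclass
class SimulatedTrace:
    """A synthetic reporter trace with its ground-truth boundary frames."""

    trace: TraceSeries | None
    s_onset_frame: int | None
    s_end_frame: int | None
    resolvable: bool
    reason: str | None = None


def simulate_reporter_trace(
    rec: PhaseRecord,
    kind: str = PCNA_VARIANCE,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SimulatedTrace:
    """Synthesize a 1-D reporter trace from one cell's phase durations.

    ``pcna_variance``: low plateau (G1) → high plateau (S) → low plateau
    (G2/M).  ``pip_mvenus``: high G1 plateau, fast exponential fall at S
    onset, low S plateau, steep ramp from G2 onset.  Additive Gaussian
    noise is scaled by ``noise_sd`` times the trace's dynamic range.
    These shapes are idealizations built to exercise the boundary
    detectors, not a model of real reporter kinetics.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not rec.has_durations(("G1", "S", "G2")):
        raise ValueError(f"{rec.cell_id}: needs G1, S and G2 durations")
    dt = rec.frame_interval
    tail = rec.d_g2 + (rec.d_m or 0.0)
    n1 = int(round(rec.d_g1 / dt))
    n2 = int(round(rec.d_s / dt))
    n3 = int(round(tail / dt))
    if min(n1, n2, n3) < 1:
        return SimulatedTrace(
            None, None, None, resolvable=False,
            reason=f"{rec.cell_id}: a phase is shorter than one frame",
        )
    rng = np.random.default_rng(seed)
    if kind == PCNA_VARIANCE:
        low, high = 1.0, 3.0
        sig = np.concatenate(
            [np.full(n1, low), np.full(n2, high), np.full(n3, low)]
        )
        dyn = high - low
    elif kind == PIP_MVENUS:
        g1_level, s_level = 100.0, 5.0
        tau = 0.5  # frames; fast, efficient degradation at S onset
        fall = s_level + (g1_level - s_level) * np.exp(-(np.arange(n2) + 1.0) / tau)
        s_seg = np.maximum(fall, s_level)
        ramp = np.minimum(
            s_level + 12.0 * (np.arange(n3) + 1.0), 0.9 * g1_level
        )
        sig = np.concatenate([np.full(n1, g1_level), s_seg, ramp])
        dyn = g1_level - s_level
    else:
        raise ValueError(f"unknown reporter kind {kind!r}")
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd * dyn, size=sig.size)
    trace = TraceSeries(
        cell_id=rec.cell_id, frame_interval=dt, signal=sig, kind=kind
    )
    return SimulatedTrace(
        trace, s_onset_frame=n1, s_end_frame=n1 + n2, resolvable=True
    )


def simulate_trace_set(
    profile: CellTypeProfile,
    n: int,
    kind: str = PCNA_VARIANCE,
    noise_sd: float = 0.05,
    seed: int = 0,
    frame_interval: float = DEFAULT_FRAME_INTERVAL_H,
):
    """Convenience: n cells' traces plus a ground-truth table."""
    import pandas as pd

    table = simulate_phase_durations(
        profile, n, seed=seed, frame_interval=frame_interval
    )
    rng = np.random.default_rng(seed + 1)
    traces, rows = [], []
    for rec in table:
        sim = simulate_reporter_trace(
            rec, kind=kind, noise_sd=noise_sd, seed=int(rng.integers(2**31 - 1))
        )
        if not sim.resolvable:
            logger.warning("skipping unresolvable trace: %s", sim.reason)
            continue
        traces.append(sim.trace)
        rows.append(
            {
                "cell_id": rec.cell_id,
                "s_onset_frame": sim.s_onset_frame,
                "s_end_frame": sim.s_end_frame,
            }
        )
    return traces, pd.DataFrame(rows)
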