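"""The many-for-all model of heritable phase-length factors.

The model posits m types of heritable molecular factors whose copy
numbers modulate the progression rates of cell-cycle phases.  A
*phase-coupling* factor carries a (small, random) effect coefficient for
every phase; a *phase-specific* factor affects exactly one phase.  For a
cell with copy numbers n_i, the per-phase step rate is

    λ_P = λ0_P · (1 + γ_P · Z_P),
    Z_P = Σ_i a_{P,i} (n_i − μ_i) / sqrt(Σ_i a_{P,i}² μ_i),

i.e. the baseline rate plus a factor term proportional to the summed,
effect-weighted copy-number deviations.  Copy numbers are Poisson with
lognormal mean abundances, so Z_P is the Poisson-standardized factor
term and γ_P is directly the coefficient of variation of the rate
contributed by the whole factor ensemble.  The phase duration is then an
Erlang draw, T_P ~ gamma(k_P, λ_P).

Because every phase-coupling factor enters all phases through the same
copy-number deviations, phases are correlated when one factor dominates
(m small) and decorrelate as effects dilute across many factor types
(m large): the many-for-all explanation of uncoupled-yet-heritable
phase durations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .records import PhaseRecord, PhaseTable, PHASES

logger = logging.getLogger("cyclephase")

#: Default per-phase shapes/baseline rates: hTERT-RPE-1-like means
#: (G1 7.9 h, S 10.1 h, G2 3.4 h, M 0.5 h) with shapes in the range
#: typical of fitted phase distributions (tens of steps for S, fewer
#: for gap phases).
DEFAULT_K = {"G1": 16, "S": 64, "G2": 16, "M": 4}
DEFAULT_LAMBDA0 = {"G1": 16 / 7.9, "S": 64 / 10.1, "G2": 16 / 3.4, "M": 4 / 0.5}


@dataclass
class FactorModelParams:
    """Full parameterization of the many-for-all simulator.

    gamma is the per-phase coupling fraction: the coefficient of
    variation of the progression rate contributed by the factor
    ensemble (dimensionless).  sigma_effect is the sd of the raw effect
    coefficients; abundance means are lognormal with median
    ``abundance_log_median`` and log-sd ``abundance_log_sd``.
    """

    lambda0: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LAMBDA0))
    k: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_K))
    gamma: dict[str, float] | float = 0.25
    m_coupling: int = 100
    m_specific: dict[str, int] = field(default_factory=dict)  # phase -> count
    sigma_effect: float = 0.01
    abundance_log_median: float = 1000.0
    abundance_log_sd: float = 0.6
    abundance_prior: str = "lognormal"  # or "uniform" on [0, 2*median]
    perturbation_fold: float = 10.0
    rate_floor_fraction: float = 0.05
    n_cells: int = 200
    n_sims: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for p, lam in self.lambda0.items():
            if not lam > 0:
                raise ValueError(f"lambda0[{p}] must be > 0")
        for p, kk in self.k.items():
            if int(kk) != kk or kk < 1:
                raise ValueError(f"k[{p}] must be a positive integer")
        for g in self.gamma_by_phase().values():
            if g < 0:
                raise ValueError("gamma must be >= 0")
        if self.sigma_effect < 0:
            raise ValueError("sigma_effect must be >= 0")
        if not self.perturbation_fold > 0:
            raise ValueError("perturbation_fold must be > 0")
        if not (0 < self.rate_floor_fraction < 1):
            raise ValueError("rate_floor_fraction must be in (0, 1)")
        if self.m_coupling < 0 or any(v < 0 for v in self.m_specific.values()):
            raise ValueError("factor counts must be >= 0")
        if self.abundance_prior not in ("lognormal", "uniform"):
            raise ValueError("abundance_prior must be 'lognormal' or 'uniform'")

    def gamma_by_phase(self) -> dict[str, float]:
        if isinstance(self.gamma, dict):
            return {p: float(self.gamma.get(p, 0.0)) for p in self.lambda0}
        return {p: float(self.gamma) for p in self.lambda0}

    @property
    def phases(self) -> list[str]:
        return list(self.lambda0)


@dataclass
class FactorEnsemble:
    """One realization of factor types: effect coefficients and abundances.

    ``coeffs[P]`` holds one coefficient per factor type (zero for factor
    types that do not touch phase P); ``mean_abundance`` the per-type
    Poisson means.  ``norm`` caches the Poisson-standardization constant
    sqrt(Σ a² μ) per phase, fixed at creation so that perturbations show
    up as extra (un-normalized) rate variance.
    """

    coeffs: dict[str, np.ndarray]
    mean_abundance: np.ndarray
    m_coupling: int
    norm: dict[str, float] = field(default_factory=dict)
    perturbed_index: int | None = None
    perturb_fold: float = 1.0
    perturb_mode: str = "copies"  # or "mean"

    def __post_init__(self) -> None:
        m = self.mean_abundance.size
        for p, a in self.coeffs.items():
            if a.size != m:
                raise ValueError("coefficient vectors must match abundance length")
        if not self.norm:
            self.norm = {
                p: float(np.sqrt(np.sum(a**2 * self.mean_abundance)))
                for p, a in self.coeffs.items()
            }

    @property
    def m_total(self) -> int:
        return int(self.mean_abundance.size)


def draw_factor_ensemble(params: FactorModelParams, seed: int | None = None) -> FactorEnsemble:
    """Draw effect coefficients and mean abundances for all factor types.

    Phase-coupling factors get an independent N(0, sigma_effect)
    coefficient for every phase; each phase-specific factor gets a
    coefficient only for its own phase.  Mean abundances follow the
    configured prior (lognormal median/log-sd by default).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    phases = params.phases
    m_spec = {p: int(params.m_specific.get(p, 0)) for p in phases}
    m_total = params.m_coupling + sum(m_spec.values())
    coeffs = {p: np.zeros(m_total) for p in phases}
    # coupling factors occupy the first m_coupling slots
    for p in phases:
        coeffs[p][: params.m_coupling] = rng.normal(
            0.0, params.sigma_effect, size=params.m_coupling
        )
    off = params.m_coupling
    for p in phases:
        coeffs[p][off : off + m_spec[p]] = rng.normal(
            0.0, params.sigma_effect, size=m_spec[p]
        )
        off += m_spec[p]
    if params.abundance_prior == "lognormal":
        mu = rng.lognormal(
            mean=np.log(params.abundance_log_median),
            sigma=params.abundance_log_sd,
            size=m_total,
        )
    else:
        mu = rng.uniform(0.0, 2.0 * params.abundance_log_median, size=m_total)
    return FactorEnsemble(
        coeffs=coeffs, mean_abundance=mu, m_coupling=params.m_coupling
    )


def _rates_from_counts(
    params: FactorModelParams,
    ensemble: FactorEnsemble,
    counts: np.ndarray,
    mean_abundance: np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray], int]:
    """Per-cell, per-phase rates from realized copy numbers.

    Rates below rate_floor_fraction·λ0 are clamped; the clamp count is
    returned for logging.
    """
    gammas = params.gamma_by_phase()
    mu = ensemble.mean_abundance if mean_abundance is None else mean_abundance
    dev = counts - mu  # (n_cells, m)
    rates: dict[str, np.ndarray] = {}
    n_floored = 0
    n_cells = counts.shape[0]
    for p in params.phases:
        lam0 = params.lambda0[p]
        norm = ensemble.norm.get(p, 0.0)
        if norm > 0 and gammas[p] > 0:
            z = dev @ ensemble.coeffs[p] / norm
            lam = lam0 * (1.0 + gammas[p] * z)
        else:
            lam = np.full(n_cells, lam0)
        floor = params.rate_floor_fraction * lam0
        mask = lam < floor
        n_floored += int(mask.sum())
        rates[p] = np.where(mask, floor, lam)
    if n_floored:
        logger.debug("rate floor applied to %d cell-phase rates", n_floored)
    if n_floored >= n_cells * len(params.phases):
        raise ValueError(
            "all rates hit the floor; coupling fraction gamma is too large "
            "for the configured baseline rates"
        )
    return rates, n_floored


def _draw_counts(
    params: FactorModelParams,
    ensemble: FactorEnsemble,
    n_cells: int,
    rng: np.random.Generator,
    abundance_model: str = "poisson",
) -> np.ndarray:
    mu = ensemble.mean_abundance
    if abundance_model == "poisson":
        return rng.poisson(mu, size=(n_cells, mu.size)).astype(float)
    if abundance_model == "normal":
        # normal with variance equal to the mean, truncated at 0, rounded
        counts = rng.normal(mu, np.sqrt(np.maximum(mu, 0.0)), size=(n_cells, mu.size))
        return np.round(np.clip(counts, 0.0, None))
    raise ValueError(f"unknown abundance model {abundance_model!r}")


def simulate_factor_cells(
    params: FactorModelParams,
    ensemble: FactorEnsemble,
    n_cells: int | None = None,
    seed: int | None = None,
    abundance_model: str = "poisson",
    condition: str = "mfa",
) -> tuple[PhaseTable, dict[str, np.ndarray]]:
    """Simulate cells under a fixed factor ensemble.

    Each cell draws copy numbers for every factor type, the per-phase
    rates are formed from the effect-weighted deviations, and durations
    are Erlang draws at those rates.  Returns the phase table and the
    per-cell rates (phase -> array).
    """
    n_cells = params.n_cells if n_cells is None else int(n_cells)
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    counts = _draw_counts(params, ensemble, n_cells, rng, abundance_model)
    mu_eff = None
    if ensemble.perturbed_index is not None and ensemble.perturb_mode == "copies":
        i = ensemble.perturbed_index
        counts = counts.copy()
        counts[:, i] *= ensemble.perturb_fold
        mu_eff = ensemble.mean_abundance.copy()
        mu_eff[i] *= ensemble.perturb_fold
    rates, _ = _rates_from_counts(params, ensemble, counts, mean_abundance=mu_eff)
    durations = {
        p: rng.gamma(shape=params.k[p], scale=1.0 / rates[p]) for p in params.phases
    }
    records = []
    for i in range(n_cells):
        records.append(
            PhaseRecord(
                cell_id=f"{condition}{i:05d}",
                condition=condition,
                d_g1=float(durations["G1"][i]) if "G1" in durations else None,
                d_s=float(durations["S"][i]) if "S" in durations else None,
                d_g2=float(durations["G2"][i]) if "G2" in durations else None,
                d_m=float(durations["M"][i]) if "M" in durations else None,
            )
        )
    return PhaseTable(records), rates


def simulate_factor_cells_normal_abundance(
    params: FactorModelParams,
    ensemble: FactorEnsemble,
    n_cells: int | None = None,
    seed: int | None = None,
) -> tuple[PhaseTable, dict[str, np.ndarray]]:
    """Variant with copy numbers ~ normal(μ, μ), truncated at 0 and rounded.

    At the default abundance scale (~10³ copies) the normal and Poisson
    copy-number models are statistically indistinguishable.
    """
    return simulate_factor_cells(
        params, ensemble, n_cells=n_cells, seed=seed, abundance_model="normal"
    )


def perturb_single_factor(
    ensemble: FactorEnsemble,
    fold: float = 10.0,
    pair: tuple[str, str] = ("G1", "S"),
    mode: str = "copies",
) -> FactorEnsemble:
    """Amplify the dominant phase-coupling factor's abundance ``fold``-fold.

    The factor chosen is the coupling factor maximizing the product of
    its effect coefficients on the two phases of ``pair`` — the single
    factor whose amplification most strongly couples them.  ``mode``
    'copies' multiplies every cell's realized copy number of that factor
    (n' = fold·n, so its cell-to-cell spread scales by ``fold``); 'mean'
    instead multiplies the Poisson mean abundance before cells are drawn
    (spread scales by sqrt(fold)).  Standardization constants are kept
    from the unperturbed ensemble, so the amplified factor contributes
    extra, shared rate variance.
    """
    if ensemble.m_coupling < 1:
        raise ValueError("ensemble has no phase-coupling factors to perturb")
    if not fold > 0:
        raise ValueError("fold must be > 0")
    if mode not in ("copies", "mean"):
        raise ValueError("mode must be 'copies' or 'mean'")
    a1 = ensemble.coeffs[pair[0]][: ensemble.m_coupling]
    a2 = ensemble.coeffs[pair[1]][: ensemble.m_coupling]
    i_star = int(np.argmax(a1 * a2))
    mu = ensemble.mean_abundance.copy()
    if mode == "mean":
        mu[i_star] *= fold
    return replace(
        ensemble,
        mean_abundance=mu,
        norm=dict(ensemble.norm),  # keep unperturbed standardization
        perturbed_index=i_star,
        perturb_fold=float(fold),
        perturb_mode=mode,
    )


@dataclass
class SweepResult:
    """Mean/sd of pairwise R² across simulations for each factor count m."""

    m_values: list[int]
    mean_r2: list[float]
    sd_r2: list[float]
    perturbed: bool = False
    pair: tuple[str, str] = ("G1", "S")

    def __post_init__(self) -> None:
        if not (len(self.m_values) == len(self.mean_r2) == len(self.sd_r2)):
            raise ValueError("sweep vectors must have equal length")
        if any(not (0.0 <= v <= 1.0) for v in self.mean_r2):
            raise ValueError("mean R^2 must lie in [0, 1]")


def _pair_r2(table: PhaseTable, pair: tuple[str, str]) -> float:
    x = np.asarray(table.durations(pair[0]))
    y = np.asarray(table.durations(pair[1]))
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def coupling_sweep(
    params: FactorModelParams,
    m_values,
    with_specific: dict[str, int] | None = None,
    pair: tuple[str, str] = ("G1", "S"),
    perturb: bool = False,
    seed: int | None = None,
) -> SweepResult:
    """Sweep the number of phase-coupling factor types.

    For each m, ``params.n_sims`` independent replicates are run; each
    replicate draws a fresh ensemble, simulates ``params.n_cells`` cells
    and records the squared Pearson correlation of the two phases of
    ``pair``.  With ``perturb`` the dominant coupling factor is
    amplified ``params.perturbation_fold``-fold in every replicate.
    """
    m_values = [int(m) for m in m_values]
    if not m_values:
        raise ValueError("m_values must be nonempty")
    if params.n_sims == 1:
        logger.warning("n_sims=1: sd of R^2 is reported as 0")
    root = np.random.default_rng(params.seed if seed is None else seed)
    means, sds = [], []
    for m in m_values:
        p_m = replace(params, m_coupling=m, m_specific=dict(with_specific or {}))
        r2 = np.empty(params.n_sims)
        for s in range(params.n_sims):
            child = root.integers(0, 2**31 - 1, size=2)
            ens = draw_factor_ensemble(p_m, seed=int(child[0]))
            if perturb:
                ens = perturb_single_factor(ens, fold=params.perturbation_fold, pair=pair)
            table, _ = simulate_factor_cells(p_m, ens, seed=int(child[1]))
            r2[s] = _pair_r2(table, pair)
        means.append(float(np.mean(r2)))
        sds.append(float(np.std(r2, ddof=1)) if params.n_sims > 1 else 0.0)
    return SweepResult(
        m_values=m_values, mean_r2=means, sd_r2=sds, perturbed=perturb, pair=pair
    )
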