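# Methods

## Data model

A cell's record holds five event times in hours — birth, S onset, S end,
mitosis start (nuclear envelope breakdown), telophase — and/or the four
phase durations they delimit (G1, S, G2, M). Times are continuous reals;
frame-based measurements are converted at ingest using the acquisition
interval (default 10 min). Event times must be non-decreasing and
durations strictly positive; when both are present they must agree to
1e-9 h. Rows violating these invariants are dropped (and counted) at CSV
ingest rather than aborting a whole table. Cells with incomplete
observation (movie-boundary censoring) are simply rejected by operations
that need the missing fields; no censored-data likelihood is attempted.

## Erlang fitting

The Erlang density is evaluated through log-gamma, so shapes in the
hundreds cannot overflow. The measurement-interval factor ΔT multiplies
the density into a per-frame observation probability; it shifts the
log-likelihood by n·log ΔT and can never change the maximizer, which is
why it is retained for reporting but ignored by the optimizer.

*Independent-rate fit.* For fixed integer shape k the rate MLE is the
closed form λ̂(k) = k/x̄ (from dL/dλ = 0). The shape is found by
exhaustively scanning k = 1..k_max (default 500) over the profile
log-likelihood, vectorized over k. This is deterministic and exact under
the integer constraint, which a generic simplex optimizer cannot
guarantee. Ties break toward the smaller k (parsimony); an argmax at
k_max raises a boundary warning, since near-deterministic data push
k → ∞ (CV → 0).

*Shared-rate (simple Markovian) fit.* The joint likelihood is the
product of the four phases' Erlang densities with one common λ. Given a
shape vector, λ̂ = (Σ_p n_p k_p)/(Σ_p Σx) in closed form; the shape
vector is optimized by coordinate ascent (full vectorized scan of one
phase's shape at a time) from ten seeded restarts. Global optimality is
not guaranteed in general; the tests verify agreement with exhaustive
search over all shape vectors at small k_max.

*Uncertainty and adequacy.* Parameter spreads are nonparametric
bootstrap standard deviations (resample-with-replacement, refit;
default 1,000 draws). Fit adequacy uses a two-sample two-sided
Kolmogorov–Smirnov test against durations simulated from the fitted
Erlang. The calibration test draws the observed sample from the fitted
distribution itself; when the fit is instead re-estimated from the
tested sample the KS test is conservative (parameters estimated from
data), which is the expected behavior, not a defect.

*Shape-recovery limits.* The sampling sd of the shape MLE is
approximately k·sqrt(2/n) (the information bound with the rate
profiled). At n = 1,000 this is ≈0.3 at k = 8 but ≈2.9 at k = 64:
point identification of large shapes to ±1 step is impossible at
realistic sample sizes, and only the shape's scale is meaningful there.

*Welch–Satterthwaite.* A sum of Erlang components (kᵢ, θᵢ) is
approximated by a single gamma via k_sum = (Σθᵢkᵢ)²/(Σθᵢ²kᵢ),
θ_sum = Σθᵢkᵢ/k_sum — exact in the mean, matched in variance. The shape
is then rounded half-up to an integer and the scale rescaled so the mean
k·θ is preserved exactly.

## Coupling statistics

Pearson r with the two-sided t-test p-value (n−2 df); a pair is
*coupled* iff p < 0.01 and R² > 0.1, *weak* iff significant but
R² ≤ 0.1, else *uncoupled*. M phase is excluded from the default phase
set: at ~30 min it is comparable to the frame interval and contributes
negligible variance. The policy is applied per pair without multiplicity
correction, mirroring how such screens are usually read; a Bonferroni
adjustment is a caller-side division of α.

*Variance decomposition.* The share of total-cycle variance attributed
to phase P is R²(d_P, d_total). For independent phases this equals
σ²_P/Σσ², shares sum to ~1, and the part-to-sum formula
ρ = 1/√(1+(σ_C/σ_B)²) shows why every phase correlates positively with
the total even with zero phase–phase coupling.

*Sibling differences.* For sister pairs, per-phase differences
ΔP = d_P(s1) − d_P(s2) are correlated across pairs, with the sister
ordering randomized (seeded) to avoid labeling bias. High between-sister
correlation of durations does not couple the Δs; only interdependent
factor assortment does.

*Noise-injection bootstrap.* Every replicate uses the full sample
("selection without replacement" at N = sample size): variability comes
only from the injected noise, ε_begin + ε_end per phase and cell with
each ε ~ U(−0.5, 0.5)·T·δ, δ = 3, drawn independently per phase. The
default 100×100 two-level loop yields 10,000 R values and the fraction
with R² < 0.1. Durations driven non-positive are clamped to one frame
and counted. Design points left open by the procedure: noise at a shared
boundary (end of G1 = start of S) is drawn independently per phase
rather than shared (a shared draw would anti-correlate adjacent phases);
a conventional with-replacement mode is available behind a flag.

*Sample size.* Fisher-z: n = ((z_{1−α/2} + z_power)/atanh r)² + 3,
rounded to the nearest integer (as in the standard tables), floored at
4. At R² = 0.1, two-sided α = 0.01 and power 0.80 this gives 112. Note
these are the α/power conventions under which 112 arises; the function
exposes both explicitly rather than guessing a caller's labeling of
type-I/type-II rates.

## Many-for-all factor model

Each of m phase-coupling factor types carries an independent
N(0, σ_effect) coefficient per phase (σ_effect = 0.01); phase-specific
types carry one nonzero coefficient. Mean abundances are lognormal
(median 1,000 copies, log-sd 0.6 — interpreted as median; an arithmetic
reading and a uniform prior are config switches) and per-cell copy
numbers Poisson (or normal(μ, μ), truncated and rounded, which is
indistinguishable at ~10³ copies).

The per-cell rate is λ_P = λ0_P·(1 + γ_P·Z_P) with Z_P the
effect-weighted copy-number deviation standardized by its Poisson sd,
sqrt(Σ a²μ). Two choices here are deliberate:

- **Centering.** λ0 is defined as the *average* progression rate, so the
  factor term is centered on the mean copy numbers; an uncentered sum
  would shift every simulation's mean rate by an ensemble constant
  without affecting within-population coupling.
- **Standardization.** γ is the coefficient of variation of the rate
  contributed by the whole ensemble (default 0.25, chosen so duration
  CVs stay in the experimentally plausible range), held constant across
  m. Without this, the factor-term variance grows ∝m and the sweep
  confounds coupling dilution with rate-variance explosion (rates are
  driven negative for m ≳ 10 at any γ that yields visible coupling at
  m = 1). The dilution mechanism — all phases share the same copy-number
  deviations, and their correlated part shrinks as 1/√m — is untouched.

Rates are floored at 5% of λ0 (fires on <1% of cells at defaults; all
cells flooring raises an error as a mis-calibration signal). Durations
are direct gamma draws T_P ~ gamma(k_P, λ_P), which is distributionally
identical to stepping the k-stage chain with a Gillespie algorithm.
Default shapes/baselines are the RPE-like profile (means 7.9/10.1/3.4/
0.5 h, shapes 16/64/16/4).

*Sweep.* For each m, n_sims fresh (ensemble, cells) replicates; each
yields one G1–S R² from n_cells = 200 cells; mean and sd are reported.
The default replicate count is 50 (standard errors on mean R² of
~0.01–0.03, sufficient to resolve the order-of-magnitude dilution
trend).

*Perturbation.* The coupling factor maximizing the product of its
effect coefficients on the target pair is amplified fold = 10; the
default multiplies realized copy numbers (n' = 10n, spread ×10, the
literal reading of a 10-fold abundance increase), with a mean-abundance
mode (spread ×√10) behind a flag. Standardization constants stay those
of the unperturbed ensemble so the amplified factor contributes extra,
shared rate variance. Because the baseline G1–S correlation of a random
ensemble carries a random sign, a perturbation whose added coupling is
comparable to the baseline can occasionally shrink |R²|; with the
copies-mode amplification the increase dominates in ≈95% of ensembles.

## Synthetic data

*Frame quantization* emulates discrete acquisition: each cell gets a
uniform grid offset and every event is recorded at the first frame at or
after it occurs, so each event time errs by at most one frame and
durations by at most one frame in magnitude; coincident snapped events
are pushed apart one frame (minimum one-frame phase). Note that because
both boundaries of a phase share one acquisition grid, a duration that
is an exact frame multiple is always reproduced exactly — per-event
independent errors require the boundary-identification noise modeled by
the bootstrap's δ term, not the grid itself.

*Sister pairs.* Factor copy numbers per pair are mean + deviation, the
deviation split into a mother-shared part (weight √ρ, ρ =
sister_sharing) and per-sister jitter (weight √(1−ρ)); deviations are
Gaussian with the Poisson variance. Independent assortment draws the
jitter independently per factor type; the interdependent counterfactual
makes each sister's jitter proportional across types along the
ensemble's net-effect direction — the specific alignment that maximally
couples sibling differences, built as a positive control. Rates are
modulated multiplicatively, λ_P = λ0_P·exp(ηZ_P − η²/2) with η = 0.6
(rates stay positive; the strength reflects strongly heritable
progression rates so that sister correlations land in the
experimentally observed r > 0.5 regime), and durations are Erlang draws
(suppressible via `gamma_noise=False` for exact-inheritance checks).

*Reporter traces* are piecewise idealizations, not kinetic models: the
PCNA-variance trace is a low–high–low step (plateaus 1.0/3.0); the
PIP-degron trace is a 100-level G1 plateau, exponential fall (τ = 0.5
frames) to an S plateau of 5, and a steep linear G2 ramp. Additive
Gaussian noise is scaled by the dynamic range. Phases shorter than one
frame are flagged unresolvable. Passing trace tests therefore shows the
callers implement the stated rules and tolerate additive noise — not
that they would survive real-microscopy artifacts (drift, bleaching,
segmentation errors), which are out of scope.

## Trace calling

PCNA: moving-average smoothing (window 3), plateau levels from the
25th/75th percentiles of the smoothed trace, midpoint threshold,
crossings must be sustained two frames (suppresses single-frame
spikes). Calls are 0-based frame indices, half-open convention (the
onset frame is the first frame inside the new phase); calls are
invariant to affine signal rescaling and equivariant to time shifts.

PIP: two-pass level estimation — a provisional G1 level from the leading
frames locates a provisional 50% crossing, the G1 level is re-estimated
as the median of the pre-onset plateau and the crossing re-called; the
S level is likewise the median of the plateau delimited by the G2
crossing itself. The G2 rise threshold is S level + 2% of the trace
maximum, and the upward search starts only once the signal has reached
the S plateau (otherwise the fall through the threshold would trigger
it). Because the rule's entire margin is 2% of the maximum, it is only
meaningful when noise is well below that margin; the synthetic PIP
benchmark uses 0.5% noise, while the PCNA midpoint rule (margin = half
the dynamic range) is benchmarked at 5%.

## Reproducibility and problem sizes

Every stochastic operation takes an explicit seed; the CLI derives
per-module child seeds from one global seed and writes a manifest
(parameters, seed, input hashes) beside each output. The acceptance
script sizes its computations to resolve each effect cleanly — e.g.
100-seed recovery runs at n = 1,000, 50-replicate factor sweeps at 200
cells, 10⁵-draw Monte-Carlo checks of closed forms — the same sizes used
in the test suite.
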