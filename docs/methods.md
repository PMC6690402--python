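# Methods

This note records the model, the simulators, and the numerical and
design choices behind them, in enough detail to reproduce or challenge
any number the package computes.

## Observer model

Two linear detection mechanisms with energy combination. The LUM
mechanism weights L- and M-cone contrast by (cos θ, sin θ) with
θ ∈ (0, π/2), so both cone classes enter with positive sign; the RG
mechanism's weights are fixed at the L−M diagonal (direction 3π/4),
i.e. equal and opposite. Each mechanism's temporal transfer function is
a difference of low-pass cascades H(ω) = ξ(H₁(ω) − ζH₂(ω)) with
H_k(ω) = (i2πτ_kω + 1)^(−n_k). ω is in Hz and τ in seconds, so 2πτω is
dimensionless. The subtraction is carried out on the complex responses
and the magnitude taken afterwards; because the two cascades rotate
phase at different rates, |H| can exceed the DC value ξ(1−ζ) (it does,
for example, for M1's LUM filter at 1 Hz). Sensitivity is the energy
sum of the gain-scaled projections; it is π-periodic in color direction
(counterphase symmetry), and threshold is its reciprocal. Fixed-
frequency detection contours are therefore ellipses, recovered
analytically by eigendecomposition of the 2×2 quadratic form
Q = |H_RG|²w_RGw_RGᵀ + |H_LUM|²w_LUMw_LUMᵀ.

A deliberate reading choice: the combination rule is written in the
source literature with H(ω) inside squared terms although H is complex.
We take the complex magnitude of each mechanism's transfer function
before projection and squaring — sensitivity is a nonnegative real and
mechanism outputs combine by energy, not coherently. Whether magnitudes
are taken before or after the bandpass subtraction *within* a mechanism
is a separate question; we subtract first, faithful to the difference-
of-filters construction.

## Spatial gain field

Only the two mechanism gains vary over the visual field:
log₁₀ξ = b₀ + b₁r + b₂r cos 2φ + b₃r sin 2φ (r in degrees, φ in radians
from the right horizontal meridian, positive upward). The b₃ term
vanishes on the vertical meridian, which the left/right 2AFC design
cannot test anyway. Four variants constrain b₃: symmetric (b₃ = 0,
17 free parameters), yoked (shared, 18), luminance-only (18),
unconstrained (19). Left/right mirror locations are collapsed to one
canonical location with h ≥ 0.

Parameter boxes for fitting: ζ ∈ [0, 1], τ ∈ (10⁻³, 1] s, n ∈ [1, 12],
θ ∈ (0, π/2), b₀ ∈ [−1, 4], b₁ ∈ [−0.5, 0.2], b₂, b₃ ∈ [−0.2, 0.2].
The τ and ζ boxes follow the shipped presets, several of which sit
exactly on 1.00 or 0.00 — a strong hint the original fits were
box-bounded there. Gains are always fit in log₁₀ (b-space), which
subsumes positivity. A soft prior keeps b₁±b₂ ≤ 0 for both mechanisms
(sensitivity must not grow with eccentricity), implemented as a hinge
penalty with weight 10³ and an override flag; every shipped preset
satisfies it strictly.

## Fitting

The objective is Σ|log₁₀(measured) − log₁₀(predicted)| over uncensored
points. L1 on log thresholds makes the fit a conditional-median
regression: robust to the occasional wild staircase estimate, and
median-unbiased under symmetric log-domain noise. Censored points
(thresholds recorded at the display gamut edge) are excluded by
default; an optional hinge mode penalizes only predictions more
sensitive than the gamut bound. How censored points entered the
original fits is unknown; exclusion mirrors their exclusion from the
residual analyses.

The objective is non-smooth, so optimization is a box-bounded
Nelder–Mead simplex, restarted at the incumbent until it stops
improving (tolerance 10⁻⁶, at most 4 cycles of 400·dim evaluations),
multi-started (default 20 starts: the four subject presets plus
jittered copies, and any caller-supplied vectors such as packed
per-location solutions). Per-location 13-parameter fits can be
iteratively re-seeded with every other location's solution until none
improves (tolerance 10⁻⁴, at most 5 rounds); objectives are
nonincreasing across rounds by construction.

Leave-one-out cross-validation refits with each uncensored point
withheld, warm-starting from the all-data fit (validated against cold
restarts: median |difference| in held-out errors < 10⁻³ on a 100-point
set). A `max_folds` option subsamples held-out points deterministically
to bound runtime. Variant comparison reports, per held-out point, the
log₁₀ ratio of |errors| against the yoked model, with the median and a
1,000-resample bootstrap SE; the winner is the variant with the lowest
median |held-out error|. Parameter-constancy tests refit a semi-global
model (free per-location gains, optionally freeing one named shape
parameter per location) and compare paired per-point |held-out errors|
with a one-sided Wilcoxon signed-rank test; identical error vectors
return p = 0.5, and tie-degenerate data falls back to an exact sign
test.

## Synthetic data

The study's raw thresholds are not distributed, so the generator is the
package's data source. It reproduces: the published per-subject
condition counts over opponent/nonopponent × (≤5 Hz / >5 Hz) cells;
a 15-location grid spanning r ∈ [2°, 14°] at φ ∈ {−π/4, 0, π/4}
(on and beside the horizontal meridian, never the untestable vertical
meridian); directions drawn uniformly within each cell's half-quadrant
and frequencies log-uniformly within its band (the real conditions were
distributed "nearly continuously"); multiplicative lognormal threshold
noise, σ = 0.10 log₁₀ units; and censoring at an elliptical display-
gamut model with semi-axes 1.0 (L+M) and 0.16 (L−M) in cone contrast.

σ = 0.10 is back-computed from the published 10th/90th percentile
residual band 0.77–1.40 (0.26 decades across 2.56 standard normal
quantiles). Note the published band is slightly asymmetric (geometric
centre 1.039); a symmetric lognormal cannot reproduce both tails — it
gives 0.744/1.343 — so tests check the generator against the exact
lognormal quantiles, not against both published tail values.

What the generator does **not** emulate: session/block structure and
learning effects, spatial-uncertainty inflation of thresholds at high
eccentricity, any departure from ellipse-shaped detection contours, and
response-modality differences. Passing tests therefore demonstrate
estimator correctness and calibration under the model's own
assumptions, not that real observers obey them.

Two generator-level findings worth knowing:

* **Censoring is informative.** Excluding gamut-censored points keeps
  only realizations whose noise pushed them below the bound, which
  biases fitted RG gains upward (≈ +0.06 in b₀_RG at the default
  censoring rate, ~15–20% of points). The parameter-recovery
  experiment therefore runs censoring-free; analyses of real,
  gamut-limited data inherit this bias.
* **Where censoring lives.** With the shipped presets and default
  gamut, censoring is dominated by high-frequency opponent conditions
  (~45% censored) — the RG mechanism is weak there and the opponent
  gamut axis is short. Low-frequency opponent censoring is rare (0–2%).

## Adaptive experiment simulator

2AFC trials come from a Weibull psychometric function
P(correct) = γ + (1−γ−λ)(1−exp(−(x/α)^β)) with γ = 0.5, default β = 3
and λ = 0.01; α is the model threshold, sitting at the 63.2% point of
the underlying cdf. The staircase holds a 200-point posterior over
log₁₀ threshold spanning ±2 decades around its prior centre (lognormal
prior, σ = 0.5 decades; centred on the GP prediction, or on a generic
1% contrast for the four session-opening corner conditions), updates it
in log space with the assumed-Weibull likelihood, and reads out the
posterior mode after 40 trials.

Trial placement is the one place we depart from the textbook staircase:
trials are placed at the posterior **mean** of log threshold shifted to
the assumed psychometric function's sweet point (the amplitude
maximizing per-trial Fisher information, ≈1.19× threshold for β = 3) —
the ZEST refinement plus optimal-placement rule. Mode placement is
measurably less efficient (estimate sd ≈ 0.071 vs ≈ 0.055 decades over
40 trials), and with β = 3 the information bound for 40 2AFC trials
(CRLB ≈ 0.045 decades at the sweet point) leaves no slack to waste: the
calibration requirement that 40-trial estimates land within ±15% of
truth at least 80% of the time is only reachable near the bound. The
40-trial **mode readout** is kept as is.

The condition-placement loop fits a Gaussian process to (log₁₀
frequency, direction) → log₁₀ threshold with covariance
σ²·Matérn-5/2(Δlog f/ℓ_f)·exp(−2sin²(Δd)/ℓ_d²) — the direction factor is
π-periodic because a direction and its antipode are the same stimulus —
plus a noise term. Hyperparameters are refit by maximum marginal
likelihood (L-BFGS on log parameters, 3 restarts) after every
measurement. The GP is implemented directly (Cholesky solves; jitter
10⁻¹⁰) because the required per-dimension product kernel is not
available off the shelf; tests verify it against an explicit
Gram-matrix solve. The next condition is the in-gamut candidate (16
directions × 12 log-spaced frequencies by default) with the largest
predictive standard deviation — predictive variance would pick the same
point — with deterministic ties toward low frequency, then low
direction. Candidates whose predicted threshold exceeds the gamut are
never tested, mirroring the real protocol. Simulated measurements are
censored when the observer's *true* threshold exceeds the gamut, and
presented amplitudes are clamped to the gamut limit.

## Diagnostics and comparisons

Residuals are log₁₀(measured) − log₁₀(predicted) over uncensored points
only; summaries report the median and the 10th/90th percentiles of the
exponentiated ratios using the linear-interpolation quantile rule. The
residual autocorrelation map bins median residuals on a direction ×
log-frequency grid (frequency bins span nominal ×/÷ 1.5, direction bins
nominal ±10°), subtracts the map mean, and averages lagged products
pairwise-complete over non-empty bins, normalized by the map variance —
so the zero-lag value is exactly 1 and the map is symmetric under lag
negation. The direction axis wraps with period π; the frequency axis
does not.

The species comparison normalizes log sensitivities within each
(subject, location) by subtracting that set's own mean (a max option is
exposed; mean is the default), pools across locations, restricts to a
frequency band, and — treating subject as a random effect — aggregates
to one mean per subject and compares species on subject means with a
two-sample t-test. With two subjects per species this subject-level
test is exactly what a balanced mixed-model F-test reduces to; a
full variance-component fit is numerically degenerate at this design
and was rejected for that reason.

## Problem sizes used by the shipped analyses

Simulated datasets match the published per-subject totals (344, 724,
220, 272). The refit-calibration check uses the full 724-point M2
design; parameter recovery uses 700 points from M1. The
variant-selection study uses 240 points and 80 leave-one-out folds with
warm starts, and a ground-truth shared b₃ of 0.02 — the published
shared asymmetries (|b₃| ≤ 7×10⁻³) are an order of magnitude below what
these sample sizes can resolve, so they are a null condition, not a
selection testbed. Constancy tests in the suite run at 4 locations ×
60 points. These sizes were chosen as the smallest at which each
effect is decisively measurable.

## Known limitations

* The elliptical gamut is a stand-in; real projector gamuts in cone
  contrast space are polygonal and background-dependent.
* σ_log10 conflates measurement and model error; recovered-parameter
  tolerances are stated relative to this default.
* The L1 objective has flat regions; different parameter vectors can
  fit thresholds equally well (ridge degeneracy). Tests compare
  threshold surfaces, not raw parameters, wherever that matters.
* QUEST criterion level (the percent-correct the 40-trial mode targets)
  is a configuration default (β = 3, λ = 0.01, γ = 0.5); calibration
  numbers quoted above are specific to it.
* The human–monkey low-frequency luminance difference lives in the
  subjects' fitted parameters; the synthetic comparison measures
  whatever the presets imply plus sampling noise, not new biology.
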