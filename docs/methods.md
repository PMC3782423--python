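# Methods

## The task environment

Each session is a sequence of `n_trials = 220` trials.  On trial *i* a
landing point *x_i* is drawn from a Gaussian N(μ_gen(i), σ_gen(i)²) and a
parabolic trajectory is constructed that ends at *x_i*.  All positions are
fractions of the horizontal screen width (the screen spans [0, 1]); time is
in seconds.

**Change-point schedule.**  μ_gen and σ_gen are piecewise constant.  Each
holds its value for an integer gap drawn uniformly from
[`jump_gap_min`, `jump_gap_max`] = [20, 40] trials and then jumps to a fresh
independent draw; the two schedules are independent.  Post-jump values are
drawn uniformly for the mean (range [0.2, 0.8]) and log-uniformly for the SD
(range [0.02, 0.12]).  Uniform/log-uniform redraws are deliberately
noncommittal — they exercise the observer at all scales without privileging
any regime; the ranges keep endpoint distributions comfortably on screen
while spanning a factor of six in spread.

**Trajectories.**  Motion follows x(t) = x0 + v0·t + ½·a·t² in the
horizontal dimension, with 40 samples equally spaced over 6 s (t = 0 at the
first sample, t_end = 6 s at the landing point).  Vertical motion is a
constant downward sweep and carries no information.  The acceleration is
uniform on [−a_max, +a_max] with a_max chosen so that the acceleration
component of the motion spans 50% of the screen width over the full
duration (½·a_max·t_end² = 0.5, i.e. a_max = 1/36 screen·s⁻²).  Given the
endpoint, the start point x0 is drawn uniformly on the screen and v0 solved
from (x0, a, x_end, t_end); (x0, a) pairs are rejection-sampled jointly
until the whole path stays on screen.  Endpoints themselves are resampled
(not clipped) when off screen, preserving the Gaussian shape up to
truncation.  Because the endpoint constrains only the *joint* choice of
start point and curvature, neither x0 nor a alone predicts x_end (their
trialwise correlation with the endpoint is ≈ 0); extrapolation genuinely
requires estimating the full equation of motion.

**Observation noise.**  The first 30 of 40 samples (observed fraction 0.75 —
the occluded fraction is a free design choice, made configurable) are shown
with i.i.d. Gaussian position noise of per-trial SD σ_noise, drawn
log-uniformly from [0.01, 0.10] and then rescaled by a common session
factor so that the mean σ_noise over analysis trials is exactly
`noise_calibration_ratio = 0.67` times the mean σ_gen over analysis trials.
This calibration keeps the dynamic and statistical predictions of comparable
precision, which is what makes the combination models distinguishable.  The
first 20 trials are noise free (task familiarization) and excluded from all
analyses, leaving 200 analysis trials.

## The ideal observer (statistical model)

The observer knows the generative *structure* — Gaussian endpoints whose
mean and SD may independently jump — but not the parameters.  It maintains a
joint posterior over the 4-D lattice {μ, σ, α_μ, α_σ}, where α_μ and α_σ are
the per-trial jump probabilities of the mean and SD.  Defaults: 60 uniform
μ points over the screen, 20 log-spaced σ points over [0.005, 0.3], 8
log-spaced α points over [0.001, 0.3] per hazard axis (a single-point axis
fixes that hazard instead of inferring it).  These resolutions balance
fidelity against desk-scale cost; the posterior carries 76 800 cells and a
full session filters in well under a second.

Each trial applies, in order:

1. **Prediction** — the emitted belief (μ_s(i), σ_s(i)) is the
   moment-matched Gaussian of the posterior-predictive mixture *before*
   observing x_i: μ_s = E[μ], σ_s² = E[σ² + μ²] − μ_s².  Moment matching is
   used because everything downstream (combination, KL regressors) treats
   the statistical prediction as a single Gaussian, and it preserves the
   predictive mean and variance exactly.
2. **Bayes update** — multiply by N(x_i; μ, σ²) cell-wise and renormalize.
   Likelihoods are accumulated in log space with max-subtraction before
   exponentiation, so long sessions cannot underflow.
3. **Leaky propagation** — within each (α_μ, α_σ) slice, mix the slice with
   uniform redistributions of μ and/or σ in proportion to the hazards:
   (1−α_μ)(1−α_σ)·p(μ,σ) + α_μ(1−α_σ)·U(μ)p(σ) + (1−α_μ)α_σ·p(μ)U(σ) +
   α_μα_σ·U(μ)U(σ).  Hazard marginals are untouched; mass drift is asserted
   below 1e−10 and renormalized.

The prior is uniform over all cells.  Warmup trials are observed like any
other (feedback is always given).  With hazards fixed at zero the filter
reduces exactly to static Bayesian updating on the (μ, σ) lattice, which the
tests verify against an independent loop-based implementation; on stationary
streams the belief converges to the sample mean, and after a generative jump
σ_s transiently rises before contracting — the behaviour that makes the
statistical precision regressor non-trivial.

## The dynamic model

The trajectory estimate is an OLS fit of a second-order polynomial to the
observed samples.  μ_d is the fitted value at t_end and σ_d the standard
error of that fitted value, σ_d² = s²·hᵀ(XᵀX)⁻¹h with h = (1, t_end,
t_end²) — a standard error, not a prediction interval, because the true
landing point lies on the smooth curve.  By default s² is the estimated
residual variance (the observer does not know the noise level); a
known-variance mode substitutes the generative σ_noise² and is used where
exact algebra is required.  Noise-free warmup trials get σ_d = 0.

A sequential variant carries the statistical belief as a prior *during*
trajectory estimation: weighted least squares on the first k samples plus a
pseudo-observation (t_end, μ_s) of SD σ_s.  At full data this is
algebraically identical to precision-weighting the prior-free endpoint
estimate with the prior — the package verifies the identity numerically to
better than 1e−8 per session — so endpoint behaviour cannot distinguish
"prior constrains the fit" from "estimates are fused afterwards".

## Response models, fitting, comparison

With P_s = M/σ_s² and P_d = (2−M)/σ_d²:

* weighted combination: μ_sd = b + (P_s μ_s + P_d μ_d)/(P_s+P_d),
  σ_sd = (P_s+P_d)^−½, M ∈ [0, 2] (M = 1 is Bayes-optimal);
* unweighted combination: μ_sd = b + M μ_s + (1−M) μ_d, M ∈ [0, 1];
* weighted no-combination ("select"): μ_sd = b + the more precise source's
  mean, ties resolved to the statistical source (deterministic and
  documented).

This parameterization satisfies the defining constraints of the three
models — the M ranges, M = 1 reducing to optimal precision weighting, and an
additive spatial bias b.  σ_d = 0 is treated as (near-)infinite precision
via an internal floor of 1e−9 screen widths.

Responses are r ~ N(μ_sd, k²).  `fit_mle` maximizes the summed log
likelihood over the declared free parameters within bounds (M per model;
k ∈ (0, 0.5]; b ∈ [−0.25, 0.25]) by a 21-point-per-axis grid followed by
bounded Nelder–Mead refinement from the best cell; fits at a bound are
flagged.  Fixed parameters in nested versions default to M = 1 (0.5 for
unweighted), b = 0, and k at the residual SD.  BIC = p·ln(n) − 2·logL.
Models with equal free-parameter counts are compared by logLR; nested
versions by ΔBIC.

The attraction-slope analysis provides a fit-free summary: within σ_d
terciles, the slope of (x − r) on (x − μ_s) is 0 for a purely dynamic
responder, 1 for a purely statistical one, and rises across noise bins for
any precision-weighting responder.  Reference slopes come from noiseless
optimal-observer responses.

## Regressors

Per analysis trial: ln(1/σ_s²), ln(1/σ_d²), KL(statistical ‖ combined),
KL(statistical_i ‖ statistical_{i+1}), |μ_s(i+1) − μ_s(i)|, and accuracy
100·|r − x| (% screen width; unsigned, since it is a distance).  The
combined prediction uses the optimal weighting (M = 1, b = 0) by default —
regressors describe the task, not a fitted subject — with a fitted parameter
set available as an option.  Natural logs throughout.  KL between Gaussians
uses the closed form ln(σ₂/σ₁) + (σ₁² + (μ₁−μ₂)²)/(2σ₂²) − ½.  The final
trial has no successor, so its between-trial columns are missing (NaN), not
zero.  Accuracy is orthogonalized (OLS residual, with intercept) against the
always-defined model regressors.  Event onsets place a 0.1 s event at the
decision phase of each trial, with a timeline of 6 s trajectory + 1 s
response + 0.5 s feedback + an exponential ITI of mean 6 s resampled into
[2, 12] s (resampling shifts the realized mean slightly below 6 s; only
relative onsets matter here).

## Synthetic cohorts and recovery experiments

A cohort (default 22 participants × 220 trials) draws per-participant
parameters around the optimal values: M ~ U[0.7, 1.3], k ~ U[0.015, 0.03]
screen widths, b ~ U[−0.02, 0.02].  These spreads are declared package
defaults: mild over/under-weighting, response scatter of a few percent of
the screen (commensurate with endpoint accuracy in this kind of task), and
near-zero bias.  All randomness descends from one master seed via
`SeedSequence` spawning, so results are reproducible and independent of
participant ordering.

Model recovery fits all three models to every synthetic participant and
tabulates pairwise logLRs; parameter recovery reports bias and RMSE of
(M, k, b) across seeded replicates and trial counts.  Because the generator
and the fitted models share their functional form, recovery here validates
the *pipeline* (identifiability at these noise levels and session lengths),
not human behaviour: real data add model mismatch, lapses, motor noise and
learning effects that the synthetic cohort deliberately omits.

## Numerical choices and limitations

* Grid filter: log-space likelihoods; mass conservation asserted to 1e−10
  after every step; predictive variance guaranteed positive for any
  non-degenerate grid.
* OLS via `numpy.linalg.lstsq`; the information matrix is kept for standard
  errors; designs with fewer than 4 points or fewer than 3 distinct times
  are rejected.
* Optimization is deterministic (fixed grid + Nelder–Mead with fixed
  starting point); no stochastic restarts.
* Problem sizes used by the shipped experiments — 10 sessions for
  calibration/correlation checks, 22×220 trials for model recovery, 60–620
  trials for equivalence and parameter recovery — are package defaults
  chosen to characterize the estimators well at interactive runtimes.
* The observer does not learn its own grid ranges or model the training
  phase preceding a session; hazard inference is restricted to the α lattice.
* The select model's likelihood surface is piecewise-constant in M wherever
  no trial flips its choice; the grid stage makes the fit robust to this,
  but fitted M values for that model are identified only up to the flip
  boundaries.
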