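# Methods

This note documents the models, the numerical choices behind them, and the
design decisions taken where the analysis recipe left room, in the order
the pipeline runs.

## Synthetic scenario generator

The generator emulates the dual-cohort glasshouse design the analysis
assumes. Each **sentinel** plant contributes three area series (bud, stem,
thermal-reference strip) on a 5-min grid:

    area(t) = baseline_px * G(t) * (1 + osc(t) + drift(t) + eps(t))

- **Growth trend `G(t)`**: a saturating logistic rise per tissue/treatment
  (per-plant gains jittered lognormally, sd 0.10). Droughted stems use a
  peak-and-decline variant: rise capped at day 32, linear decline to 18%
  below the peak just before rehydration on day 50, then recovery over one
  day. The 18% figure is the maximum stem contraction the design targets;
  day 32 and day 50 are the observed stem-area peak and the rehydration
  day of the emulated study.
- **Diurnal oscillation `osc(t)`**: tissue contracts while lights are on.
  The day/night profile is the product of two logistic ramps centred on
  lights-on (08:30) and lights-off (20:30), with logistic scale
  `30 min / ln(81)` so the 10–90% transition spans the ~30 min the tissues
  take. The bud's ramp centres are shifted by the configured
  `true_lag_dawn` / `true_lag_dusk` (minutes) — this is the ground truth
  the lag model must recover. Baseline amplitude is 2% of tissue area (the
  printed record gives no amplitude; 2% is a typical optical-dendrometry
  oscillation for herbaceous tissue and keeps the signal-to-noise of the
  rendered figures). Droughted stem amplitude grows 3%/day of drought,
  reproducing the amplitude increase that accompanies water deficit; bud
  amplitude does not grow, since buds buffer their turgor.
- **Thermal drift**: one shared 24-h harmonic per camera (amplitude 0.5%),
  identical across the three ROIs of a plant — exactly the disturbance the
  reference-strip correction exists to remove.
- **Noise**: iid Gaussian, sd 0.15% of area, chosen to match the visible
  scatter of dendrometry transition windows (roughly 5–12% of the rescaled
  window amplitude).

**Peripheral** plants supply the predawn water-status tables. Day-level
population means come from piecewise-linear anchor maps: droughted Ψ_x
declines from −0.5 MPa at drought onset to −2.09 MPa on day 48 and
recovers to −1.3 MPa after rehydration; well-watered Ψ_x wanders between
−0.47 and −0.87 MPa. Bud osmotic potential is Ψ_x minus a pressure
differential that widens from 1.77 MPa (pre-drought, Π_B = −2.27 MPa) to
3.54 MPa at the drought extreme (Π_B = −5.63 MPa); leaf osmotic potential
tracks Ψ_x at a constant 0.45 MPa offset. Individual draws add Gaussian
noise (Ψ_x 0.15, Π_L 0.25 MPa); bud pools are means of five per-bud draws
(sd 0.30 MPa) taken *before* measurement noise, mirroring physical pooling
of five buds per psychrometer sample, three pools per day × treatment.

What the generator does **not** emulate: correlated (AR) sensor noise,
frame jitter and refocusing artefacts, plant motion, missing frames,
stomatal-closure irregularity of late drought, or between-plant variation
in the water-status trajectories beyond iid noise. Passing tests therefore
demonstrate that the pipeline recovers truth under the design's idealised
statistical structure, not robustness to every field artefact.

Rendering: frames are drawn as dark shapes on a light background — stem as
a vertical trapezoid (widths scaled linearly to hit the target area), bud
as an adjacent ellipse (semi-axes scaled by √area), reference as a
pixel-exact strip. Rasterisation error is bounded by the silhouette
perimeter; the round-trip extraction error at default geometry measures
≤1%.

## Dendrometry extraction

Binarisation thresholds are per-sequence constants: either supplied
(reproducing a manual per-sequence choice) or selected once per sequence
by between-class variance maximisation (Otsu) on the first frame. For
integer gray levels the Otsu level itself belongs to the dark class, so
the automatic threshold is placed half a gray level above it and the
strict darker-than rule is used everywhere. A constant frame carries no
histogram structure; automatic mode falls back to mid-gray (128).

Bud area is the combined-ROI count minus the stem-ROI count; a negative
difference raises (ROI misconfiguration) rather than clamping. Thermal
correction is additive removal of the reference's relative drift,

    rel(t) = tissue(t)/tissue(0) − (ref(t)/ref(0) − 1),

anchoring rel(0) = 1 exactly; a multiplicative variant
(`tissue·ref(0)/ref`, then normalise) is selectable. Both are the identity
under a flat reference. The additive form removes a *shared additive*
relative drift exactly; if the drift enters multiplied by a growth factor
far from 1 a residual of second order in the drift remains — negligible at
the sub-percent drift amplitudes thermal expansion produces. Correction
order (correct, then normalise, in one formula) is fixed here; the
original processing order is not recoverable and the difference is second
order. Corrupt or missing frames are dropped with a logged gap, never
interpolated — the spline stage tolerates gaps.

## Detrending

Each relative-area series gets a rank-3 thin-plate regression spline of
continuous time (days since series start): basis = affine null space
{1, t} plus the leading eigenvector of the |t−k|³ radial kernel on 50
quantile knots, fit by ordinary least squares. With the basis dimension
itself acting as the smoother there is nothing to penalise; three degrees
of freedom can follow a week of growth but not a 24-h oscillation (a
cross-check against an independent penalised-spline implementation agreed
to r = 0.998 on the fitted trend). Residuals within ±60 min of each light
transition form the analysis windows, one per (plant, tissue, transition,
day), rescaled to percent of the maximum residual over the plant–tissue's
whole analysed window set — a single shared scale so dawn and dusk are
comparable. The default analysis days are 17–23 (the emulated study's lag
week; its figure caption says 17–24, so the range is a parameter).

## Hierarchical sigmoid lag model

Within a window the signal is a logistic transition

    y_i ~ Normal( A_g,d / (1 + exp(B (t_i − C_tis))) + D_g,d , σ )

with amplitude and offset per plant×tissue group g (`A_g`, `D_g`) plus
day-level random deviations nested in the group
(`a_gd ~ N(0, τ_A)`, `d_gd ~ N(0, τ_D)`), one global rate B per fit,
tissue-specific midpoints C, and separate fits per transition type. The
temporal lag is ΔC = C_bud − C_stem (positive = bud lags stem).

Priors (percent units for A/D/σ, per-minute for B, minutes for C):
A, D ~ N(0, 50); B ~ N(0, 1) constrained positive; C ~ N(0, 30);
σ, τ_A, τ_D ~ half-Normal(0, 10). The sigmoid family has an exact
reflection (A, B) ↔ (−A, −B, D+A); constraining B > 0 and letting A carry
the sign of the transition removes the duplicate mode with no loss of
expressiveness — dawn windows fit A > 0 (area drops), dusk windows A < 0.

**Sampling.** Conditional on (B, C_bud, C_stem, σ, τ_A, τ_D) the model is
linear in every A/D coefficient, so those are integrated out analytically
under their Gaussian priors (per-group Woodbury identity; with complete
windows all groups of a tissue share one capacitance matrix, making a
likelihood evaluation ~0.3 ms at the default design). An affine-invariant
ensemble sampler (differential-evolution moves, 16 walkers) explores the
remaining six-dimensional posterior; the default configuration runs four
independent ensembles of 8000 iterations (2000 warmup), and test-scale
fits shrink to two ensembles of 500–1000 iterations, which the
six-dimensional marginal posterior comfortably mixes through. Convergence
is the rank-normalised split R̂ across ensembles (threshold 1.01);
non-convergence flags the fit rather than raising. Linear coefficients,
when needed (summaries, posterior predictive checks), are drawn exactly
from their conditional Gaussian given each retained draw — this is a
collapsed-Gibbs augmentation, not an approximation.

Posterior predictive checks replicate data per retained draw and report
pointwise 95% predictive-interval coverage plus a tail area for the
omnibus scale discrepancy sd(y_rep) vs sd(y_obs); constant data are
flagged degenerate.

Calibration, measured by simulation at the study design (5 plants × 7
days, generator noise): ΔC posterior mean bias ≈ 0.05 min at true lag 0;
95% credible-interval coverage 49/50 across replicates; an injected
10-min lag is recovered with the interval covering the truth.

Degenerate inputs: a single-tissue window set raises (lag undefined);
single-day data pin the day variances near zero but remain proper thanks
to the half-Normal priors; zero-amplitude data leave C at its prior,
visible as an interval an order of magnitude wider than an identified fit.

## Water relations

**Turgor balance.** `turgor(psi_x, pi) = psi_x − pi` (MPa), requiring both
arguments finite and non-positive; negative output is a valid turgor-loss
state.

**Decline calibration.** Ψ_x of peripheral plants is regressed on the
sentinel stems' mean daily area decline (a positive percentage below the
pre-rehydration maximum of the across-plant daily mean) with a random
intercept per measurement day, REML. Marginal R² is the fixed-effect
variance share, conditional R² adds the day-intercept variance (the
standard variance-partition definitions). The decline sign convention
makes the slope a "MPa drop per 1% decline".

Because the covariate is day-level, the slope's information comes from the
m measurement days, not the N observations. At the study's m = 4,
likelihood-based intervals undercover badly: the day-variance REML
estimate sits on the zero boundary in a large fraction of replicates, and
the resulting intervals treat day noise as residual noise (measured
coverage 83–89% over 200 simulations for profile and Satterthwaite-Wald
variants). The default interval therefore uses the exact reduction: day
means regressed on day declines give an exact t(m−2) interval under the
model (measured coverage 94.9% over 1000 simulations, bias 0.3%).
Profile-deviance (with a Satterthwaite-df cutoff) and Wald intervals
remain available by flag for comparison with conventional output. Day 20
is excluded from the default calibration days (27, 34, 41, 50): stems are
still actively growing, so "decline" is not yet meaningful.

**Rate contrasts.** Daily rates of change of Ψ_x, Π_L and Π_B are compared
across tissue × treatment groups. Peripheral plants are new at each
timepoint, so each group is an ordinary regression of value on day by
default (a per-plant random intercept is available by flag for designs
with repeated measures); intercepts are reparameterised at day 27 (the
first fully post-onset sampling day). All pairwise slope and day-27
intercept differences use a Tukey-style adjustment: p = P(q ≥ √2·|t|) from
the studentized-range distribution with k = number of groups and
Welch–Satterthwaite df. Under equal-slope null simulations the adjusted
contrasts stay above 0.05 in well over 90% of replicates; at the emulated
effect size (bud–xylem differential widening ~0.06 MPa/day over the
drought-progression days 20–48) the Π_B vs Ψ_x slope contrast is reliably
flagged. Contrasts spanning the post-rehydration reversal (day 50) lose
power to curvature, which is why the power analysis restricts to the
widening phase.

## Pipeline and reproducibility

`run_pipeline` chains simulate → (optional render/extract check) →
correct/normalise → detrend → lag → water on the droughted cohort,
writing every intermediate tidy CSV, a manifest (config hash, seeds,
package and library versions, hashed again into a manifest hash) and a
plain-text report. All randomness flows from `ScenarioConfig.rng_seed` and
`McmcConfig.seed`; identical configurations produce byte-identical tables
and identical manifest hashes. Tables use one shared tidy-CSV schema per
domain type; readers validate columns, dtypes and categorical levels and
report offending row numbers.

## Problem sizes used in the shipped tests

Lag fits in the test suite use 2 ensembles × 500–1000 iterations on the
5-plant × 7-day design (the interval-calibration study runs 50
replicates); the decline-calibration recovery study uses 200 replicates of
the 60-observation table; the rate-contrast null calibration uses 100
replicates. These sizes give Monte-Carlo error comfortably inside the
asserted bands.

## Known limitations

- The additive thermal correction leaves a second-order residual when
  drift multiplies a growth factor far from 1.
- The lag model assumes a common within-window time grid across days for
  its fast path; heterogeneous grids (missing frames) fall back to a
  slower per-group path.
- The between-day calibration interval is exact only while the decline
  covariate is constant within days (true for this design, where decline
  comes from sentinel daily means).
- Day-level random effects apply to A and D only; a day effect on the
  midpoint C itself (transition timing varying by day) would be absorbed
  into σ and slightly widen the lag posterior rather than bias it.
- The simulator's truth for ΔC is exact because generator ramps and the
  fitted sigmoid are the same logistic family; real transitions that are
  asymmetric in time would make C a family-dependent summary.
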