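# budhydro

Optical dendrometry and water-relations analysis of axillary-bud drought
physiology in herbaceous annuals.

## The scientific problem

Basal axillary buds (node-2 buds in garden pea are the classic model) are
the plant's insurance policy: if drought or herbivory destroys the shoot
apex, these buds regrow the plant. Two questions decide their fate under
water deficit:

1. **Are dormant buds hydraulically connected to the stem?** If the
   bud–stem junction carries significant hydraulic resistance, the bud's
   diurnal turgor oscillation should *lag* the stem's. Optical dendrometry
   — time-lapse imaging of tissue silhouettes, with profile area as a
   turgor proxy — can resolve lags of minutes at 5-min sampling.
2. **How do buds keep turgor while the xylem dries out?** Cell turgor
   follows the pressure balance **P_t = Ψ_x − Π_B** (xylem water potential
   minus bud osmotic potential, MPa). Buds can defend P_t by osmotic
   adjustment: actively deepening Π_B as Ψ_x falls, maintaining a positive
   pressure differential.

`budhydro` implements the full analysis chain for this experimental design,
plus a synthetic-data generator that emulates the glasshouse study
(two treatments × 5 continuously imaged sentinel plants, 15 destructively
sampled peripheral plants per predawn timepoint, 12-h photoperiod
08:30–20:30, drought from day 20 with rehydration on day 50), so every
stage can be validated against known ground truth.

## The pipeline

| stage | what it does | core class / function |
|---|---|---|
| `simulate` | synthetic area series, frame stacks and water-status tables with encoded truths | `ScenarioConfig`, `simulate_area_series`, `simulate_water_status`, `render_frames` |
| `extract` | threshold frames (manual or Otsu), count black pixels per ROI, bud = combined − stem, thermal-reference correction, normalise to first sample | `binarize`, `measure_areas`, `correct_and_normalize`, `extract_series` |
| `detrend` | rank-3 thin-plate regression spline of time (OLS) isolates growth; residuals cut into ±1 h dawn/dusk windows, rescaled to % of window-set maximum | `SplineTrend`, `extract_windows` |
| `lag` | hierarchical Bayesian sigmoid `f(t) = A/(1+exp(B(t−C))) + D` per transition; A, D by plant×tissue with day-level random deviations, global B, tissue-specific C; the lag is ΔC = C_bud − C_stem | `SigmoidLagModel` |
| `water` | turgor balance; LMM of Ψ_x on stem area decline (day random intercept, marginal/conditional R²); per-group daily rates of Ψ_x, Π_L, Π_B with Tukey-adjusted slope and day-27 intercept contrasts | `turgor`, `DeclineCalibration`, `RateTrendModel` |

The statistical models are scikit-learn-style estimators (`fit`,
`predict`, `get_params`, fitted attributes with trailing underscores);
module-level functions (`fit_trend`, `fit_lag_model`, `fit_decline_lmm`,
`fit_rate_models`) are thin wrappers.

## Worked example

Run the whole pipeline on the default droughted scenario (reduced MCMC for
a desk-scale run):

```python
import budhydro as bh

cfg = bh.ScenarioConfig(rng_seed=42, noise_sd=0.0015)
mcmc = bh.McmcConfig(chains=2, iterations=1000, warmup=400, seed=0)
res = bh.run_pipeline(cfg, "out/", mcmc=mcmc, check_extraction=True)
print(open("out/report.txt").read())
```

prints

```
budhydro pipeline report
========================

Bud-stem transition lag (minutes, bud minus stem):
  dawn: mean +0.39  95% CI [-0.43, +1.24]  (true +0.0)
  dusk: mean +0.14  95% CI [-0.72, +0.98]  (true +0.0)

Stem decline calibration: slope -0.070 MPa per 1% decline (95% CI -0.604 to +0.464; drop magnitude 0.070); marginal R2 0.342, conditional R2 0.861; Pearson r -0.682 (p 2e-09)
Minimum droughted day-mean pressure differential Psi_x - Pi_B: 1.74 MPa
Extraction round-trip max relative error: 0.0095
```

Reading the numbers: both posterior lag means are below 1 min with 95%
credible intervals covering zero — the generator injected no lag, and a
bud that oscillates synchronously with its stem is hydraulically connected
to it. The calibration slope says each 1% of stem area contraction
corresponds to about 0.07 MPa of xylem tension in this synthetic run (the
between-day interval is honest about having only four calibration days).
The droughted cohort's day-mean pressure differential never drops below
1.74 MPa, i.e. buds keep positive turgor throughout the simulated drought.
Extraction recovered the generator's areas to within 1%.

The same stages are available from a shell:

```bash
budhydro simulate --out out/
budhydro extract --frames out/frames/D1 --rois rois.yaml --threshold auto --out areas.csv
budhydro detrend --in relative.csv --days 17:23 --out windows.csv
budhydro lag --windows windows.csv --chains 4 --iter 8000 --warmup 2000 --seed 1 --out out/
budhydro water --status out/water_status.csv --decline out/decline.csv --out out/
budhydro run --config scenario.yaml --out out/
```

## Turgor at the drought extreme

```python
>>> import budhydro as bh
>>> bh.turgor(-2.09, -5.63)   # day-48 droughted means: Psi_x, Pi_B (MPa)
3.5400000000000005
```

A bud holding a 3.54 MPa pressure differential against a xylem at
−2.09 MPa is the signature of strong osmotic adjustment.

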