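# Methods

`frostbloom` projects apple (*Malus domestica*) bloom dates and blossom
frost risk from ensembles of daily temperature series, and quantifies when
the projected change becomes distinguishable from projection noise.  This
note documents the models, the choices behind their implementation, and
what the synthetic test bed does and does not show.

## The projection chain

1. **Climate input.** An ensemble of daily mean/minimum temperature series,
   one per climate realization and grid point.
2. **Preparation.** Optional temporal interpolation to hourly resolution,
   3×3 spatial floating mean, ordinary kriging to a common grid, and
   monthly quantile-mapping bias correction.
3. **Phenology.** Seven chilling–forcing models map each phenological year
   (August 1 – July 31) to a chilling-completion day `t1` and a bloom day
   `t2` (BBCH 60/65).
4. **Risk.** Blossom frost risk θ = (years in a 30-year window with
   min Tmin ≤ β between bloom and July 31) / 30, for β = 0 °C and 2 °C.
5. **Uncertainty.** Variance partitioning of the area-mean signal into
   internal variability, climate-run and impact-model components; the
   fractional uncertainty F = λ√T/|G| and its first sustained crossing of
   1 (time of emergence).
6. **Trends.** Mann–Kendall for continuous series, Cox–Lewis for event
   series.

## Phenological models

All models accumulate daily rates.  Forcing is growing-degree-day-like,
`Rf = max(T − Tbf, 0)`, multiplied by a day-length factor `(D / 12 h)^c`
for the extended models (5–7); day length comes from the astronomical
declination/hour-angle formula.  Chilling is counted in *chill days*
(`Rc = 1` while `0 °C ≤ T ≤ Tbc`) for models 2, 3, 6, 7 — the 0–10 °C band
being the effective temperature range for apple development — and in Utah
units for model 4 (stepwise weights 0 / 0.5 / 1 / 0.5 / 0 / −0.5 / −1 over
the bands below 1.5, 1.5–2.5, 2.5–9.2, 9.2–12.5, 12.5–16, 16–18 and above
18 °C, with the cumulative state floored at zero).  Model 4's band edges
are fixed; its `tbc` slot is accepted but unused, and the calibration does
not search it.

Model structures:

* **1 (thermal time)** — forcing from January 1 until `Sf ≥ Fcrit`.
  Implicitly assumes dormancy is already released.
* **5 (thermal time + day length)** — as model 1 but with the day-length
  exponent `c` and a calibrated forcing-start day `t1` (searched over the
  whole phenological year, encoded as extended DOY 213–424).
* **2, 6 (sequential)** — chill days from August 1; when `Sc ≥ Ccrit` the
  chilling is complete (day `t1`) and forcing starts with requirement
  `F* = a·exp(b·Sc(t1))`.
* **3, 7 (parallel)** — chilling and forcing accumulate concurrently from
  August 1; forcing is gated by the chilling fraction
  `min(Sc/Ccrit, 1)` and bloom occurs when the gated sum reaches the
  time-varying requirement `a·exp(b·Sc(t))`.
* **4 (modified Utah)** — Utah chilling to `Ccrit`, then a fixed forcing
  threshold `Fcrit`.

The exponential chilling–forcing link (typically `b < 0`) means poorly
chilled seasons need more heat, which both delays bloom after mild winters
and guards against runaway late bloom dates.  A season with no bloom by
July 31 — or no chilling completion at all — is flagged *unfulfilled*; the
day-length factor applies to forcing only, not chilling.

Daily resolution is canonical throughout; the Utah accumulation is
classically hourly, and hourly series produced by `daily_to_hourly` can be
fed to the rates directly, but all calibration and projection here runs
daily.

## Temporal interpolation

The daily→hourly spline anchors Tmin at the sunrise hour (from the
astronomical day length, rounded to the whole hour so the anchor coincides
with an output sample) and Tmax at 14:00, with one cubic spline through all
anchors so the curve is continuous across midnight.  No per-day mean
re-adjustment is applied: a correction that restores each day's mean
exactly cannot simultaneously stay continuous at day boundaries and exact
at the anchors, and for the smooth, roughly symmetric diurnal cycles the
pipeline feeds it the daily mean is already reproduced to about 0.1 K away
from the series edges (the natural boundary condition distorts the first
and last day).

## Bias correction

Monthly non-parametric quantile mapping: per calendar month the empirical
CDFs of simulated and reference values are smoothed with a Gaussian kernel
of bandwidth `h = 0.1` — interpreted as a fraction of the sample standard
deviation, so the smoothing is scale-free — and matched at 257 quantiles.
Outside the calibrated range the map extrapolates the boundary slopes
linearly, so projected values warmer than anything in the calibration
period are still shifted rather than clamped.  Daily mean and daily
minimum are mapped separately because frost counting depends on the Tmin
distribution, not the mean.  Constant (degenerate) samples fall back to an
identity-plus-shift map.  Quantile maps are monotone by construction, so
ordering within a month is never changed.

## Spatial operators

The 3×3 floating mean replaces each grid point by the mean of itself and
its available neighbours (edges shrink the neighbourhood), leaving the grid
resolution unchanged.  Ordinary kriging solves the standard constrained
system (weights summing to one) with an exponential variogram
`γ(d) = sill·(1 − exp(−d/range))` fitted by least squares to the binned
empirical semivariogram; coordinates are treated as planar, which is
adequate for a few degrees of extent.  The estimator is exact at sample
locations and reproduces constant fields.

## Calibration

Parameters are fitted by bound-constrained simulated annealing
(`scipy.optimize.dual_annealing`, local search disabled because the
objective — an RMSE over integer bloom days — is piecewise constant),
minimizing the RMSE between observed and simulated bloom DOY.  Base
temperatures are bounded to [0, 10] °C; the other default bounds
(`Fcrit` 20–800, `Ccrit` 10–160, `a` 20–2000, `b` −0.05–0, `c` 0–4) span
the plausible range for apple at daily resolution.  Seasons where a
candidate parameter set yields no bloom contribute a fixed 100-day error,
keeping the objective finite while making degenerate parameters
unattractive.  The default budget (`maxiter = 2000`) recovers the
generating parameters of all seven models on 30 noisy synthetic seasons in
a few seconds to half a minute per model; ties are broken by first-found
under the seeded schedule.  Validation: leave-one-out PRMSE (refit per
fold) and external PRMSE (pooled over held-out locations).

## Frost risk

A year counts toward θ when the daily minimum within the closed interval
[bloom day, July 31] reaches β; bloom-day frost counts.  Years without
bloom cannot incur blossom frost and are excluded from the count while the
denominator stays at the window length — θ is then a multiple of 1/30 and
θ(β=2) ≥ θ(β=0) pointwise.  Windows shorter than 30 years are rejected
unless a proportional denominator is explicitly requested.  The Δθ
distribution over grid points and runs is summarized by a Gaussian KDE
with a bandwidth floor for degenerate samples.

## Uncertainty partitioning and emergence

Area-mean annual series per (run, model) are smoothed with a 10-year
centered moving average and fitted with a 4th-order polynomial.  Pooled
fit residuals give a time-constant internal variability V; the population
(1/n) variance of the fits across runs, averaged over models, gives M(t);
the error-weighted population variance across models of the run-mean fits
gives I(t).  Weights are `w ∝ 1/max(error, 0.1 d)` — the floor prevents an
infinite weight for a nominally perfect model.  The signal G(t) is the
weighted model mean expressed as change from the reference-window mean,
and `F(t) = λ√(V+M+I)/|G|` with λ = 0.674 / 1 / 1.645 for the 50 / 68.3 /
90% confidence levels.  Emergence is the first year with F ≤ 1 sustained
for at least five consecutive years (a persistence rule suppresses
single-year dips; a below-threshold run truncated by the series end still
counts), scanned from the end of the reference window; the minimum-F year
is reported alongside.

## Trend tests

Mann–Kendall uses the exact S statistic, tie-corrected variance and ±1
continuity correction with a two-sided normal p-value; no
serial-correlation correction is applied.  The Cox–Lewis statistic
standardizes the mean event time within the observation period,
`U = (t̄ − L/2)/(L/√(12n))`, with event times at year midpoints relative to
the period start; both choices keep the null distribution standard normal,
verified by simulation (type-I error within [0.03, 0.07] at α = 0.05).

## Synthetic test bed

The generator emulates a North-German (Lower-Saxony-like) setting: daily
mean = 9 °C annual mean − 8.5 K·cos-seasonality (coldest mid-January)
+ linear warming (default 3 K/century with a 0.4 K/century per-run spread,
an A1B-like ensemble) + per-run bias (sd 0.5 K) + AR(1) anomalies
(φ = 0.75, innovation sd 2.3 K, stationary sd ≈ 3.5 K).  Daily minimum is
mean − 4 K plus independent noise, clipped so Tmin ≤ Tmean — sufficient
for frost counting, though not a full diurnal model.  Bloom observations
come from a chosen *true* model plus rounded Gaussian noise, with
unfulfilled seasons emitted as NaN.  The per-model reference parameter
sets place baseline bloom near DOY 95–105 with essentially no unfulfilled
seasons in 1971–2000, and were chosen once against the generator's
climatology (chill-day totals of roughly 120 per winter in the 0–8 °C
band, falling to roughly 80 by 2070–2099).

What the synthetic bed reproduces: warming-driven delay of chilling
completion, advance of bloom and (faster) advance of the last spring
freeze, a negative ensemble-mean Δθ with single members of either sign,
single-series trend significance long before the joint multi-model signal
emerges, and temperature emerging before bloom.  What it does not contain:
real orography and station sampling, seasonally asymmetric warming,
radiation and humidity effects, frost severity or damage economics, and
variety genetics — so passing tests validate the method chain, not
site-specific risk numbers.

Default problem sizes (5 runs × 2–4 grid points × 150 years, 30-season
calibrations) were chosen so the whole chain, including annealing fits,
runs in minutes on one CPU while keeping Monte-Carlo tolerances tight.

## Known limitations

* The parallel-model coupling and the day-length factor follow canonical
  literature forms; other gating or factor shapes exist.
* Kriging assumes planar coordinates and an exponential variogram.
* The hourly interpolation degrades near series ends (natural spline
  boundary) and for strongly asymmetric diurnal cycles.
* Mann–Kendall p-values ignore serial correlation; for strongly
  autocorrelated annual series they are anti-conservative.
* V is assumed time-constant; a drifting internal variability would be
  mis-attributed to M or I.
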