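# Methods

## Phenological Index

The PI of a sheet is the proportion-weighted mean of the class index
values (buds 1, flowers 2, immature fruits 3, mature fruits 4). It is
defined only for fertile sheets (total count > 0); the pipeline default is
to skip infertile sheets with a logged warning rather than score them as 0
or NaN, because a missing composition has no phenological stage. Values
are kept at full floating precision internally and rounded only in
reports. `doy` admits 366 so that Dec-31 collections in leap years
validate, even though day-of-year conventions are often quoted as 1–365.

## Detector evaluation

Counting error is signed as `e = predicted − manual`, so positive means
the detector over-counts. MAE is the mean of |e| per class across sheets.
Concordance regresses predicted on manual counts (scipy OLS); the slope is
"predicted organs per manual organ" and its reciprocal the detection
ratio. Abundance bins are fixed-width ([0,10), [10,20), … with an open top
bin) because counting difficulty grows with organ crowding; empty bins are
reported with n = 0, never dropped silently.

Age effects regress a transformed error magnitude on collection year:
log10(|e|+1) for class errors (the +1 handles the many zero-error sheets)
and √|ΔPI| for PI error (ΔPI is bounded in [0,3] and needs no offset). A
constant response returns slope exactly 0 with p = 1 rather than relying
on the numerical fit. The helper `age_error_difference(slope, years)`
reproduces the usual back-of-envelope reading |slope|·years without
attempting to undo the log transform — the conventional presentation for
coefficients this small.

## Regression models

Both model families are fitted by OLS with untransformed, uncentred
predictors so coefficients read directly as days/year, days/PI unit,
days/m, days/°C and days/mm. CIs use t quantiles with residual df. Partial
R² for a term is `(SSE_reduced − SSE_full)/SSE_reduced`, computed by
actually refitting the model without that term — the standard
squared-partial-correlation definition. Model comparison uses closed
95%-CI intervals; touching intervals count as overlapping (conservative
for "no detectable difference" verdicts). No model selection is performed:
the two formulas are fixed by design.

Derived quantities are linear transforms of CI bounds: |year bound|·100
gives days/century; the PI-coefficient interval across models gives
days/PI unit, and ×3 the bud-to-ripe-fruit cycle (the PI spans 4−1 = 3
units). Non-significant terms (e.g. longitude) are always retained.

## Synthetic collections

The generator is an assumptions-explicit stand-in for a real scored
collection, not a calibrated emulator. Per sheet:

1. **Site and year.** Latitude 35.5–41.5°, longitude −123 to −118°,
   elevation 200–3200 m, year 1900–2013, all uniform — a
   montane-California-like century of collecting.
2. **Climate.** Spring Tmax = 20 °C − 0.005·elevation + N(0, 2 °C) (a
   standard ~5 °C/km lapse rate); winter PPT ~ LogNormal(6.2, 0.55) mm.
   These choices reproduce realistic ranges (Tmax roughly 0–24 °C, sd
   ≈ 4.8 °C; PPT sd ≈ 360 mm).
3. **Stage and composition.** A latent stage u ~ U(0, 3) sets
   PI_true = 1 + u. Class affinities follow a Gaussian kernel
   exp(−(k − PI_true)²/(2τ²)) over the class indices (τ = 0.6), scaled by
   per-class abundance parameters (defaults 27.4, 28.5, 11.0, 12.5 organs
   per sheet) and normalised by each kernel column's stage-average so that
   every class's expected count across the collection equals its
   configured mean regardless of τ. The sheet total is negative-binomial
   (dispersion 5) around the stage-dependent sum, floored at 1 organ
   (collections contain only fertile sheets), and manual counts are a
   multinomial split.
4. **Collection date.** DOY is linear in (year − 1950), Tmax, PPT and the
   *expected composition PI* at stage u, plus N(0, 15 days), rounded and
   clamped to [1, 366]. Using the expected composition PI (rather than u
   itself) as the generative phenology term matters: the kernel compresses
   composition near the endpoints (scored PIs span ≈ 1.1–3.9), and making
   DOY linear in the very quantity the scored PI estimates is what lets a
   regression of DOY on PI recover the configured 17 days/PI unit without
   systematic bias. Defaults: −0.10 days/year, −5.3 days/°C,
   +0.0072 days/mm, baseline 215.
5. **Detector.** Predicted counts binomially thin the manual counts with
   class-specific detection probabilities (0.16, 0.22, 0.30, 0.28; the
   flower value is interpolated between the neighbouring classes, which
   bracket the plausible range). An optional `age_error_rate` scales the
   probabilities linearly with (year − 2000) to emulate age-degraded
   detection; default 0.

One `numpy` Generator seeded once drives every draw in a fixed order, so a
(config, seed) pair reproduces the collection byte-for-byte.

What the generator does *not* emulate: detector false positives,
occlusion geometry (errors do not grow super-linearly with crowding),
spatial climate autocorrelation, or collector behaviour (stage and year
are independent). Passing tests therefore demonstrate that the statistical
machinery behaves correctly under a faithful undercounting mechanism, not
that any particular real detector is this well-behaved.

### Emergent properties (measured, not asserted constants)

With defaults, per-class concordance slopes estimate the detection
probabilities, the predicted/manual count ratio converges to them, PI
concordance r exceeds every per-class count r (≈ 0.99 vs ≤ 0.96 at
n = 1500), and 95% CIs from both model families cover the generating
coefficients in ≥ 90% of 20 replicate seeds at n = 700. Class-count
standard deviations are emergent from the stage mixture and mildly exceed
the configured means' nominal spread for buds.

## Numerical choices

- Exhaustive PI validation enumerates all count vectors with total ≤ 12
  against a brute-force weighted mean at 1e-12.
- OLS agreement with explicit normal-equation/SSE oracles is asserted at
  1e-10; noiseless recovery tests construct exactly-integer DOY designs
  (counts totalling 17, years on decades, climate on coarse grids) so
  integer day-of-year storage does not blur exactness.
- CSV output uses `%.17g` floats and reading uses round-trip parsing, so
  write→read is bit-exact.
- Simulation sizes in the test-suite (700–2000 sheets, 20 replicate
  seeds, 10⁴ Monte-Carlo draws) were chosen to put Monte-Carlo error well
  below every asserted margin while keeping the full suite in a few
  seconds.

## Known limitations

- The evaluation module assumes the manual counts are ground truth;
  human error is not modelled.
- Age effects are linear in year on the transformed scale only; no
  change-point or nonlinear ageing is considered.
- The phenoclimatic models ignore spatial autocorrelation and use two
  fixed climate covariates; no mixed models or model selection.
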