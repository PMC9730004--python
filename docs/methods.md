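# Methods

## Generative model

The simulator implements a Bayes-least-squares observer for interval
reproduction in which all noise lives in log₁₀-duration space. Additive
Gaussian noise on log duration is equivalent to multiplicative noise on
duration, which gives the scalar property of interval timing (SD
proportional to duration) and matches the log transform used throughout
the analysis.

Per trial with sample interval S (ms) and retention period d (s):

    m   ~ Normal(log10 S, sigma_eff(d)^2),  sigma_eff(d)^2 = sigma_m^2 + eta2 * d
    e   = w * m + (1 - w) * prior_mu,       w = prior_sigma^2 / (prior_sigma^2 + sigma_eff(d)^2)
    R   = 10 ** (e + Normal(0, sigma_prod^2))

The diffusion form — variance growing *linearly* with the retention
period — is this package's modelling choice for memory decay. It is the
simplest decay law consistent with error measures that grow linearly
rather than logarithmically with delay, and it makes the posterior weight
w (hence the expected log-log reproduction slope) strictly decreasing in
d whenever eta2 > 0, while leaving the indifference point at 10^prior_mu
in every condition. The decay law is isolated in `effective_sd` and easy
to swap.

A discrete empirical prior over the presented interval set is provided as
an alternative (`prior_kind="empirical_discrete"`, with posterior means
taken in log or linear space); the conjugate Gaussian log prior is the
default because its closed forms (w, 10^prior_mu) serve as exact oracles
for recovery testing.

### Parameters and defaults

| parameter   | meaning                                   | units            | default |
|-------------|-------------------------------------------|------------------|---------|
| sigma_m     | measurement noise SD at zero delay        | log10 units      | 0.115   |
| eta2        | memory diffusion rate                     | log10²/s         | 0.0013  |
| sigma_prod  | production (motor) noise SD               | log10 units      | 0.05    |
| prior_mu    | prior mean                                | log10 ms         | log10 640 |
| prior_sigma | prior SD                                  | log10 units      | 0.2     |

The defaults were calibrated once, analytically, to the slope profile of
the blocked 0.4/2/8 s study (w ≈ 0.76/0.70/0.63): with prior_sigma fixed
at 0.2, a least-squares fit of sigma_eff² = sigma_m² + eta2·d to the three
implied likelihood variances gives sigma_m ≈ 0.115 and eta2 ≈ 0.0013.
sigma_prod = 0.05 puts production noise at roughly a quarter of the total
reproduction variance, a typical motor share.

Between-participant heterogeneity (`PopulationSpec`) is log-normal on
sigma_m, eta2 and sigma_prod (relative SD 0.2 each) and normal on
prior_mu (SD 0.05 log10 units ≈ ±12% in duration), mirroring the
participant random intercept of the analysis models. Foreperiods are
generated (uniform 0.5–1.2 s) purely so simulated tables carry the real
schema; the analysis never reads them.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes: geometric
interval spacing, balanced trial counts, blocked or interleaved retention
conditions, central bias growing with retention, stable indifference
points, participant heterogeneity. It does **not** model lapses,
attention or temporal-unpredictability effects, sequential (trial-order)
dependencies, feedback learning of the prior, or asymmetries between
blocked and mixed presentation — simulated exp2 and exp3 differ only in
trial order. Passing tests therefore validate the pipeline's arithmetic
and inferential behaviour under the model's assumptions, not the
psychological claims themselves.

A known quantitative gap: calibrating the observer to the empirical slope
profile pins the growth of reproduction variability, and the implied CV
increments across retention conditions (≈ +2–5% relative) are smaller
than real data show. With 10 repetitions per interval the per-participant
CV estimate has relative SD ≈ 1/√(2·10) ≈ 22%, so at 35 participants the
condition-mean CV ordering is reproduced reliably only in expectation
(verified at ~120 simulated participants), not in every 35-participant
replicate. Slope ordering, by contrast, is recovered essentially always.

## Analysis chain

* **Exclusion.** A trial is flagged when reproduced/sample or
  sample/reproduced exceeds 5; a participant is removed when flagged
  trials strictly exceed 30. Whole participants only; no trial trimming.
* **Block fits.** OLS of log10 R on log10 S per participant × retention
  condition. Log-log axes are used for consistency with the blanket log
  transform of the analysis. I = 10^(b/(1−a)); |a − 1| < 1e-9 marks the
  indifference point undefined (NaN). Undefined rows are dropped from the
  indifference-point model with a logged count.
* **Error decomposition.** R′ = R − R̄ + S̄ within participant ×
  condition; VE_i = |mean(R′_i) − S_i|/S̄ (accuracy), CV_i = population
  SD(R′_i)/S̄ (precision; denominator S̄, not S_i). Default scale is
  linear ms — CV = SD/mean is conventional there — with `log10` available
  as a recorded option, since either reading is defensible.
* **Mixed models.** statsmodels MixedLM, participant random intercept,
  maximum likelihood (so AICs are comparable); a random slope on
  log10 S is available behind a flag, off by default. Tests are
  large-sample Wald chi-squared; pairwise contrasts are z-based with Holm
  adjustment within each family. Software using Satterthwaite t tests
  will give slightly different p values at small sample sizes.
* **Retention curves.** outcome ~ d and outcome ~ ln d by OLS on
  participant × condition × interval rows; AIC = n·ln(2π·RSS/n) + n +
  2(k+1) with k = 2; Δ = AIC_log − AIC_linear, positive favouring linear
  growth. Natural log is used for the logarithmic model (the base only
  rescales the coefficient). With exactly two retention periods both
  two-parameter fits are saturated and Δ = 0.

## Numerical choices

* Interval-set values are kept unrounded internally; rounding
  (half-away-from-zero to the nearest ms) is display-only.
* Mixed-interleaved schedules split each (retention, interval) pair's
  repetitions across blocks as evenly as possible, steering remainders to
  the least-loaded blocks, so block totals are exactly balanced whenever
  the total trial count divides by the block count (70 per block in the
  standard designs).
* MixedLM is optimized with Powell's method: the default gradient
  optimizers frequently collapse the random-intercept variance to the
  boundary on this data shape; Powell recovers the interior optimum.
* The retention-curve RSS is floored at 1e-300 inside the AIC so
  perfectly interpolating fits tie at Δ = 0 instead of producing NaN.
* All simulation randomness flows through `numpy.random.default_rng`
  seeded from the design and population specs; identical configs give
  byte-identical output files.

## Problem sizes used in the test suite

Unit and property tests run on 2–12 simulated participants. The
acceptance-style checks use the sizes their scenarios state: 20
participants for closed-form slope recovery (tolerance ±0.02 of w = 0.8)
and indifference invariance (50 replicates; the ±3% check applies to
per-condition means pooled over replicates, whose sampling error is small
enough for a convergence check, while per-replicate 20-participant means
carry ≈2.5–3% sampling SD), 35 participants × 20 replicates for the
qualitative retention pattern, 12 participants × 200 replicates for null
calibration of the slope contrasts, and 420-row synthetic curves × 50
replicates for the AIC sign test.

## Known limitations

* No fitting of observer parameters to data — forward simulation and
  recovery through the analysis pipeline only.
* The CV-growth effect size is tied to the slope calibration (see above);
  the single-mechanism observer cannot make both match real data at once.
* Wald/z inference is mildly anti-conservative with few participants
  (measured pairwise-contrast type-I rate ≈ 0.08 at 12 participants,
  within the expected band but above nominal).
* The indifference-point estimator 10^(b/(1−a)) is a ratio estimator:
  heavy-tailed for slopes near 1, with a small condition-dependent bias
  (< 1% at the default noise levels).
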