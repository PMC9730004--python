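# delayrep

Simulation and analysis of **delayed interval reproduction** experiments —
the paradigm used to study how short-term memory decay strengthens the
central tendency (Vierordt) bias in human timing.

In a delayed reproduction task a participant watches a visual stimulus for a
sample interval *S* (here: 7 intervals geometrically spaced around 640 ms,
0.15 log₁₀ units apart), waits through a retention period *d* (0.4–8 s), and
reproduces the interval with a key press, yielding *R*. Regressing
log₁₀ *R* on log₁₀ *S* per participant and condition gives a slope *a* < 1
(reproductions regress toward the center of the stimulus distribution), an
intercept *b*, and an **indifference point** *I* = 10^(b/(1−a)) — the
duration reproduced veridically. The question the analysis answers: does the
bias (1 − *a*) grow with the retention period while *I* stays put, and how
do accuracy (**VE**) and precision (**CV**) change with delay?

The package is aimed at researchers who want a tested reference
implementation of this analysis chain, and a generative model to validate
it against.

## Model

The simulator is a three-stage Bayesian observer operating on
x = log₁₀ duration:

1. **Measurement + memory decay.** m ∼ 𝒩(x, σ_eff²(d)) with
   σ_eff²(d) = σ_m² + η²·d — the memory trace diffuses, so measurement
   variance grows linearly with the retention period.
2. **Inference.** With a Gaussian prior 𝒩(μ_p, σ_p²) over log durations
   (the reference memory built up over trials), the posterior-mean estimate
   is ŵ·m + (1 − ŵ)·μ_p with **posterior weight**
   w = σ_p² / (σ_p² + σ_eff²). The expected log-log reproduction slope
   equals w, and the indifference point equals 10^μ_p, for any d.
3. **Production.** log₁₀ R = log₁₀ estimate + 𝒩(0, σ_prod²).

Hence η² > 0 ⇒ slopes decrease with retention while indifference points do
not move — exactly the signature the analysis is built to detect. A
discrete empirical prior over the presented interval set (BLS-style
observer) is available as an alternative.

The analysis side implements the standard chain: outlier-participant
exclusion (reproduction more than 5× off the sample on more than 30
trials), per-block OLS in log-log space, I = 10^(b/(1−a)), the error
decomposition R′ᵢₙ = Rᵢₙ − R̄ + S̄ with VEᵢ = |mean(R′ᵢ) − Sᵢ|/S̄ and
CVᵢ = SD(R′ᵢ)/S̄, linear mixed models (interval × condition interaction,
participant random intercept, ML) with Holm-adjusted pairwise contrasts,
and an AIC comparison of linear vs logarithmic growth of CV/VE with
retention.

## Worked example

```python
import delayrep as dr

spec = dr.design_presets()["exp2"]          # blocked retention periods 0.4/2/8 s
spec.seed = 1
data, truth = dr.simulate_dataset(spec, dr.PopulationSpec(seed=2))

fit = dr.fit_reproduction_model(data)
print(dr.condition_slopes(fit).round(3))
print(dr.pairwise_slope_contrasts(fit).round(4).to_string(index=False))
print(dr.block_fits(data).groupby("retention_s")["indifference_ms"].mean().round(1))
```

prints

```
0.4    0.727
2.0    0.697
8.0    0.613
 condition_1  condition_2  estimate     se  statistic  p_raw  p_holm
         0.4          2.0    0.0298 0.0104     2.8712 0.0041  0.0041
         0.4          8.0    0.1137 0.0104    10.9553 0.0000  0.0000
         2.0          8.0    0.0839 0.0104     8.0841 0.0000  0.0000
retention_s
0.4    629.3
2.0    659.1
8.0    627.5
```

Slopes fall from 0.73 to 0.61 as the retention period grows from 0.4 s to
8 s (every pairwise difference significant after Holm adjustment): the
central bias strengthens with memory decay. The indifference points hover
around 640 ms — the center of the stimulus distribution — in every
condition, i.e. the bias strengthens without shifting the gravitation point
of reproduction.

The same workflow is available from a shell:

```
delayrep all --preset exp2 --seed 1 --out out/
```

which writes the trial table, block-fit and VE/CV tables, the exclusion
report, model summaries, three diagnostic plots and a machine-readable
`summary.json`.

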