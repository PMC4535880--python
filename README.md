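# crabsettle

Tools for analysing daily settlement of blue-crab (*Callinectes spp.*)
megalopae at coastal monitoring sites, built for two questions that
arise in post-larval monitoring programmes:

1. **What drives day-to-day settlement variation?**  Daily counts of
   megalopae per passive collector are decomposed, on the log scale,
   into an annual seasonal trend, a 30-day lunar trend, short-range
   autoregressive structure and hydrodynamic/wind effects, and each
   site's variance is partitioned among these drivers.
2. **Did a perturbation (an oil spill) change settlement?**
   Before-after control-impact ANOVA, oiled/not-oiled comparisons and
   exact power analysis quantify what such monitoring designs can and
   cannot detect.

Because settlement monitoring data of this kind are rarely deposited,
the package ships a first-class synthetic-data generator that emulates
the field data's structure — log-scale harmonics, AR(1) noise, weekend
sampling gaps, rare settlement pulses, lunar-modulated tides and weakly
covarying winds — with known ground truth, so every stage of the
pipeline is testable end to end.

## The model

For site *s*, year *y* and day *t*, observed settlement rate
`N(t)` (megalopae collector⁻¹ day⁻¹) is analysed as
`z(t) = ln(N(t) + 1)` in four sequential stages:

1. **Seasonal**: `z ~ sin(2πDay/365)*Site*Year + cos(2πDay/365)*Site*Year`,
   with AIC selection over the factorial structures (full, Site-only,
   Year-only, plain, null).  `*` denotes full crossing; columns made
   inestimable by absent site-year cells are dropped, and the parameter
   count `k` is the number of estimable columns plus one variance
   parameter.  Models within 2 AIC units are treated as equivalent and
   the more parsimonious one is preferred.
2. **Lunar**: seasonal residuals are fit to
   `sin(2πLunarDay/30) * cos(2πLunarDay/30) * Site * Year` (the
   crossing includes the sin·cos second-harmonic product), where
   LunarDay is days since the last new moon (1-based, capped at 30).
3. **ARIMA**: per site, residuals on a continuous daily index (weekend
   gaps as missing observations, state-space likelihood) are whitened
   by the AIC-selected ARIMA(p, d, q), p and q in 0..4, d in 0..2.
4. **Environmental**: per site, whitened residuals are regressed on
   daily sea-level flux, maximum sea level, mean night sea level
   (20:00–06:00), the north-south wind component `u = ws·cos(θ)`, Year
   and all second-order interactions, pruned by backward elimination
   under AIC with marginality.

Per site, each stage's explained share is (variance entering − variance
leaving) / variance of `z`; shares plus the final unexplained fraction
sum to one.

The impact module computes balanced 2×2 factorial ANOVA (Site × Period)
on site-year mean rates, one-way oiled/not-oiled ANOVA on log rates or
weights, and exact two-sample t-test power
`P(|T′(df, λ)| > t_crit)` with `λ = d·√(n₁n₂/(n₁+n₂))`, d being
Cohen's d.

## Worked example

```sh
python analysis/01_simulate.py 0      # synthetic 5-site campaign
python analysis/02_summarize.py
python analysis/03_decompose.py
python analysis/04_alternate_order.py
python analysis/05_dwh_tests.py
```

The decomposition step prints, for the default seed-0 data set:

```
Variance partition (fractions of log-variance):
        site seasonal lunar arima environmental unexplained
Apalachicola    0.355 0.075 0.047         0.000       0.523
     Dauphin    0.484 0.152 0.076         0.006       0.282
   Galveston    0.181 0.116 0.182         0.011       0.509
   GrandIsle    0.467 0.032 0.069         0.009       0.424
   Pensacola    0.431 0.149 0.104         0.019       0.297
        MEAN    0.384 0.105 0.096         0.009       0.407
```

i.e. the seasonal trend explains the most variance at every site, the
lunar trend a moderate share, environmental covariates very little, and
roughly 40% remains unexplained.  The ordering-sensitivity step shows
why the environmental share must be read with care: because the tidal
covariates are themselves lunar-periodic, their apparent explanatory
power falls from 11.6% (fit to raw data) to 7.5% (after seasonal
removal) to 1.9% (after lunar removal) on the same data set.  The
impact step prints the power of both spill tests — 0.052–0.16 for the
4-vs-4 baseline design and 0.051–0.123 for the 2-vs-5 oiled/not-oiled
design over standardised effects 0.1–0.8 — showing that even an 80%
settlement change would most likely go undetected.

A `crabsettle` console command exposes the same steps
(`simulate`, `summarize`, `decompose`, `alt-order`, `anova`, `power`):

```sh
crabsettle power --d 0.8 --n1 4 --n2 4   # -> 0.16
```

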