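# apcmort

Age-period-cohort (APC) decomposition of mortality surfaces, built for the
question it is hard to answer with crude or age-standardized rates alone:
when a cause-specific death rate declines over calendar time, is the
underlying period risk really falling, or is the decline an artifact of
healthier birth cohorts moving through the population?

`apcmort` is aimed at epidemiologists working with single-year Lexis
tabulations (death counts and person-years by single year of age × calendar
year, e.g. CDC WONDER exports). It fits the additive Poisson model

```
log r_ij = u + α_i + β_j + γ_k ,    k = j − i  (birth year)
```

where `r_ij` is the mortality proportion at age `i` in year `j`, with
sum-to-zero coded age (α), period (β), and cohort (γ) blocks. Because
cohort = period − age exactly, the design has a one-dimensional null space
and the effects are identified only up to a linear trend. The fit uses the
**Intrinsic Estimator**: the unique solution orthogonal to that null vector,
computed by eigendecomposing X'X, dropping the single null eigenvector, and
running iteratively reweighted least squares in the reduced basis. A
constrained fit (two cohort effects set equal) is provided as a validation
oracle — every estimable function (fitted rates, deviance, second differences
of each effect block) must agree between the two.

From a fitted decomposition the package derives the **age-cohort adjusted
rate series**, the period-effect trajectory converted to a rate with age and
cohort held at their median effects:

```
s_j = u + β_j + median(α) + median(γ)
rate_j = scale · e^{s_j} / (1 + e^{s_j})   (logit variant, default)
rate_j = scale · e^{s_j}                   (log variant)
```

At proportions below 5×10⁻³ the two variants differ by under 0.5% relative;
both are provided. A trend-correlation stage interpolates sparse risk-factor
prevalence series (biennial obesity surveys, five historical smoking surveys)
to annual resolution and computes Pearson correlations of rate series with
obesity prevalence and of cohort effects with smoking prevalence by birth
year. A synthetic-data module generates Poisson Lexis surfaces with known
curvilinear age, piecewise-linear period, and linearly declining cohort
effects, so the whole pipeline is testable without any data download.

## Worked example

```python
from apcmort import *

bundle = generate_study_bundle(SyntheticConfig())          # defaults, seed 20220817
surface = bundle["surface"]
est = fit_intrinsic_estimator(surface)
print(f"converged: {est.converged} after {est.n_iterations} IRLS iterations, "
      f"deviance {est.deviance:.1f} on {surface.deaths.size - 156} df")

crude = crude_rate_series(surface)
adjusted = age_cohort_adjusted_series(est)                 # logit variant, per 100,000
print(f"crude rate:     {crude.rates[0]:7.2f} (1999) -> {crude.rates[-1]:7.2f} (2018)")
print(f"adjusted rate:  {adjusted.rates[0]:7.2f} (1999) -> {adjusted.rates[-1]:7.2f} (2018)")

obesity = interpolate_annual(bundle["obesity"], surface.periods, hold_right=True)
for series in (adjusted, crude):
    res = correlate_rates_with_obesity(series, obesity)
    print(f"r({series.kind}, obesity) = {res.r:+.3f}  (n={res.n}, p={res.p_value:.2g})")
res = correlate_cohort_effects_with_smoking(est, bundle["smoking"], (1965, 1990))
print(f"r(cohort effects, smoking 1965-1990) = {res.r:+.3f}  (n={res.n}, p={res.p_value:.2g})")
```

prints:

```
converged: True after 3 IRLS iterations, deviance 992.4 on 1044 df
crude rate:      337.63 (1999) ->  299.71 (2018)
adjusted rate:   186.68 (1999) ->  264.83 (2018)
r(age_cohort_adjusted, obesity) = +0.994  (n=20, p=1.4e-18)
r(crude, obesity) = -0.752  (n=20, p=0.00013)
r(cohort effects, smoking 1965-1990) = +0.995  (n=26, p=1.4e-25)
```

The synthetic stratum was generated with a declining cohort effect and a
period effect that accelerates after 2007. The crude rate *falls* by 11%
while the age-cohort adjusted rate *rises* by 42%: the apparent decline is
cohort confounding, and the sign pattern of the three correlations (adjusted
rates track rising obesity, crude rates anti-track it, cohort effects track
declining smoking) is exactly the structure the adjusted-rate method is
designed to expose.

The same pipeline is available from the shell:

```
apcmort simulate --out-surface S.csv --out-obesity O.csv --out-smoking K.csv
apcmort fit --surface S.csv --out effects.csv
apcmort adjust --effects effects.csv --variant logit --out adjusted.csv
apcmort correlate --rates adjusted.csv --prevalence O.csv
apcmort correlate-cohort --effects effects.csv --prevalence K.csv --window 1965:1990
```

`apcmort fit` also accepts CDC-WONDER-style tab-separated exports directly
(`.txt`/`.tsv`); suppressed cells are a hard error because the estimator
needs a complete Lexis rectangle.

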