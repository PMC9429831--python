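# Methods

## Model

Deaths `D_ij` at single year of age `i` and calendar year `j` are modeled as
Poisson with log person-years offset:

    D_ij ~ Poisson( N_ij · r_ij ),    log r_ij = u + α_i + β_j + γ_k,   k = j − i.

`r_ij` is a mortality *proportion* (deaths per person-year); any reporting
scale (default 100,000) is applied only when series are emitted. Age, period,
and cohort blocks are deviation (sum-to-zero) coded with the last category of
each block omitted; full-length effect vectors are recovered by the
negative-sum rule, so each block is centered by construction. On an A×P grid
there are C = A + P − 1 cohorts and 1 + (A−1) + (P−1) + (C−1) design columns.

### Identification and the Intrinsic Estimator

Because k = j − i exactly, the design matrix X has a one-dimensional null
space: a linear trend can be moved freely between the three blocks without
changing any fitted rate. The null vector is computed as the right-singular
vector of the single zero singular value (relative tolerance 1e-8 on the
spectrum; zero or multiple null directions are an error), with its sign fixed
so the first entry exceeding 1e-10 in magnitude is positive.

The Intrinsic Estimator is the maximum-likelihood solution orthogonal to this
null vector. Implementation: eigendecompose X'X, drop the single eigenvector
whose eigenvalue falls below 1e-8 × the largest, fit the Poisson GLM in the
remaining basis by IRLS, and map the coefficients back. Orthogonality of the
returned coefficient vector to the null vector is then automatic.

IRLS details: start values from a least-squares fit to log((D + 0.5)/N)
(finite for zero-death cells, which are valid inputs); stopping when the
relative deviance change falls below `tol` (default 1e-8) within `max_iter`
(default 100); non-convergence returns the fit flagged `converged=False` with
a warning rather than raising; zero or non-finite IRLS weights raise. The
fit is deterministic — there is no randomness anywhere in estimation.

### Validation by estimable functions

`fit_constrained` fits the same likelihood under the just-identifying
constraint that two named cohort effects are equal (parametrized on the
hyperplane orthogonal to the constraint vector). Any such fit spans the same
model space as the IE, so fitted log rates, deviance, and second differences
of every effect block must agree; the test suite asserts these at 1e-6
(rates, second differences) and 1e-8 (deviance), running both fits at IRLS
tolerance 1e-10 so the comparison measures the estimator, not stopping noise.
The IE's fitted values are additionally cross-checked against an independent
GLM implementation (statsmodels, Poisson family, same reduced basis) in the
test suite.

## Adjusted rate series

- **Crude**: Σ_i D_ij / Σ_i N_ij per calendar year.
- **Age-standardized**: Σ_i w_i (D_ij / N_ij) with fixed weights w normalized
  to 1. No official standard population is bundled; `synthetic_standard_population`
  provides a smooth synthetic profile (geometric 2%/year decline with age)
  for tests and demos, and real analyses should pass their standard's weights.
- **Age-cohort adjusted**: s_j = u + β_j + median(α) + median(γ); the logit
  variant scale·e^s/(1+e^s) is the default reported form, the log variant
  scale·e^s is the one consistent with the log link. Medians use the standard
  even-length convention (mean of the two central order statistics). Only the
  sum enters, so the series is invariant to shifting a constant between u and
  the β block. Both variants are computed for **all** fitted periods.

## Trend correlations

Sparse prevalence series are joined by piecewise-linear interpolation; knot
years reproduce knot values exactly, and target years outside the knot range
raise rather than extrapolate. One deliberate exception: `hold_right=True`
carries the final knot value forward, for the case where the last reporting
year falls just past the final biennial survey cycle (cycles are anchored at
their first year, so knots 1999, 2001, …, 2017 cover a 1999–2018 study period
with 2018 held from 2017).

Correlations are sample Pearson r with the two-sided t test on n − 2 df
(constant inputs and n < 3 are errors; |r| = 1 reports p = 0). Rate–obesity
correlations align the two series by calendar year, not position. The
cohort–smoking correlation pairs the effect of the cohort *born* in year Y
with smoking prevalence observed in calendar year Y; a `lag` parameter can
shift the pairing, but no lag is chosen by default and no lag search is
performed. No multiplicity adjustment is applied across the correlation
family. The birth-year window 1965–1990 on the default grid yields 26 pairs.

## Synthetic data

`SyntheticConfig` defaults define one study-like stratum:

| parameter | default | meaning |
|---|---|---|
| ages, periods | 25–84, 1999–2018 | single-year Lexis grid (60×20, 79 cohorts) |
| baseline_log_rate | log(1.5e-3) | grand-mean log proportion |
| age_curvature, age_vertex | 1.2e-3, 80 | α = −curv·(age−vertex)²: risk rises steeply, flattens near 80 |
| period_breakpoint, slopes | 2007; 0.005 / 0.02 /yr | slow rise, then 4× acceleration |
| cohort_slope | −0.02 /yr | log-linear decline across birth years |
| population_per_cell | 1e6 | person-years per cell (constant; optional age-declining profile) |
| seed | 20220817 | single RNG stream per simulate call |

True effects are centered and, by default, projected off the design null
vector (`orthogonalize=True`). The projection moves mass only along the null
direction, so every cell rate — and hence every simulated surface — is
unchanged by it; what it fixes is the *bookkeeping*: the stored truth becomes
the particular representative the Intrinsic Estimator converges to, making
parameter recovery a well-posed benchmark. With `orthogonalize=False` the raw
shapes are kept, which demonstrates the identification problem instead (the
IE then recovers the rates but a different effect split; no test asserts
recovery in that mode).

Prevalence series are affine-in-effect with Gaussian noise, clamped to
[0, 100]%: obesity knots at every second study year track the period effect
(intercept 35%, slope 40 per log unit, sd 0.4), smoking knots at the five
historical survey years 1965/1970/1974/1980/1990 track the cohort effect
(intercept 33%, slope 25, sd 0.4), so declining cohort risk co-moves with
declining smoking. These magnitudes were chosen to land in the observed US
ranges (obesity ~30→42%, smoking ~42→26%).

The paradox scenario intentionally produces a crude series that *falls*
(each year advances every cell's cohort by one, subtracting 0.02 from its
log rate, outweighing the period rise) while the adjusted series *rises* —
the qualitative confounding structure the method exists to detect.

**Recovery benchmark.** Parameter-recovery checks use `recovery_config()`:
1e7 person-years per cell with gentler gradients (age curvature 4e-4, cohort
slope −0.01) so every cell's rate stays near the 1.5e-3 baseline. The reason
is the corner cohorts: the oldest and youngest cohorts are observed in a
single Lexis cell, so their effect estimates carry that one cell's full
Poisson noise (log-rate SE ≈ 1/√deaths). Under the paradox defaults the
youngest-cohort corner cell has rate ~7e-5 and its estimate is noisy at the
0.02–0.04 level even at 1e7 person-years — an inherent property of
single-year APC grids, not an estimator defect. Under the recovery config
every cell holds ~10⁴ expected deaths and all blocks are recovered with
correlation > 0.999 and max absolute error < 0.01 at the default seed.

## What the synthetic tests do and do not show

Passing tests establish that the estimator, adjustment, and correlation
stages are internally correct and mutually consistent under the generator's
assumptions: exact additivity on the log scale, independent Poisson counts
(no overdispersion), complete surfaces, constant or smoothly varying
population, and prevalence series that are truly affine in one effect. Real
mortality surfaces violate several of these (overdispersion, age heaping,
coding changes across ICD revisions, migration-driven cohort-size dynamics),
so agreement on synthetic data does not certify substantive conclusions about
any real cause of death; it certifies the machinery.

## Known limitations

- Single-year age and period bins only; no grouped (5-year) bins, where the
  APC null-space structure differs.
- No standard errors or confidence bands for IE effects, and no inferential
  comparison of the two adjusted-rate link variants.
- Suppressed/withheld cells in input exports are a hard error, never imputed.
- No negative-binomial/overdispersion option in the simulator, and no
  joinpoint or EAPC trend statistics for the rate series.
- Which link variant an external analysis used for published adjusted rates
  is generally unstated; at proportions below 5e-3 the choice moves values by
  under 0.5%, which can still matter for matching figures printed to two
  decimals.
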