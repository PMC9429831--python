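"""Synthetic Lexis surfaces and prevalence series with known ground truth.

The generator emulates the structure the analysis assumes: Poisson death
counts whose log rate is additive in a curvilinear (quadratic) age effect, a
piecewise-linear period effect with a breakpoint year, and a linearly
declining cohort effect; plus sparse prevalence series constructed to track a
chosen effect.  Because a linear trend can be shifted freely between the age,
period, and cohort blocks (the APC identification problem), the true effects
are by default projected off the design null vector — the cell rates are
unchanged by that projection, and it makes the Intrinsic Estimator a
consistent estimator of the stored truth.  Setting ``orthogonalize=False``
keeps the raw shapes, which demonstrates the identification problem rather
than parameter recovery.

Default scales: baseline mortality proportion 1.5e-3 per person-year, period
effect rising slowly before a 2007 breakpoint and five times faster after it,
cohort effect declining 2% per birth year, 1e6 person-years per cell.  Under
these conditions the crude rate series declines over 1999-2018 while the
age-cohort adjusted series rises — the confounding pattern the adjusted-rate
method is designed to expose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .apc_core import APCDesign, EffectEstimates, build_design
from .data_io import MortalitySurface, PrevalenceSeries

__all__ = [
    "SyntheticConfig",
    "recovery_config",
    "generate_true_effects",
    "simulate_surface",
    "simulate_prevalence",
    "generate_study_bundle",
]

DEFAULT_SEED = 20220817


@dataclass
class SyntheticConfig:
    """Ground-truth shape parameters for one synthetic stratum.

    The age effect is quadratic on the log scale, ``-curvature * (age - vertex)^2``
    before centering, so risk rises steeply through adulthood and flattens near
    the vertex.  The period effect is piecewise linear in calendar year with a
    single breakpoint; the cohort effect is linear in birth year with slope
    ``cohort_slope`` (negative = later cohorts at lower risk).
    """

    ages: tuple[int, int] = (25, 84)
    periods: tuple[int, int] = (1999, 2018)
    baseline_log_rate: float = math.log(1.5e-3)
    age_curvature: float = 0.0012
    age_vertex: float = 80.0
    period_breakpoint: int = 2007
    period_slope_pre: float = 0.005
    period_slope_post: float = 0.02
    cohort_slope: float = -0.02
    population_per_cell: float = 1e6
    population_age_decline: float = 0.0  # log person-years lost per year of age
    seed: int = DEFAULT_SEED
    orthogonalize: bool = True

    @property
    def age_values(self) -> np.ndarray:
        return np.arange(self.ages[0], self.ages[1] + 1)

    @property
    def period_values(self) -> np.ndarray:
        return np.arange(self.periods[0], self.periods[1] + 1)


def recovery_config(**overrides) -> SyntheticConfig:
    """Benchmark config for parameter-recovery studies.

    Uses 1e7 person-years per cell and gentler age/cohort gradients than the
    paradox defaults so every cell's mortality proportion stays near the 1.5e-3
    baseline.  This matters for the corner cohorts, which are observed in a
    single Lexis cell: their effect estimates carry that one cell's Poisson
    noise, so recovery benchmarks need every cell to hold enough expected
    deaths (~1e4 here) for the noise floor to sit well below the effect sizes.
    """
    defaults = dict(age_curvature=4e-4, cohort_slope=-0.01, population_per_cell=1e7)
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def _center(v: np.ndarray) -> np.ndarray:
    return v - v.mean()


def generate_true_effects(config: SyntheticConfig,
                          design: APCDesign | None = None) -> EffectEstimates:
    """Deterministic ground-truth effects for the configured grid.

    Effect vectors are centered; with ``orthogonalize`` the stacked
    deviation-coded coefficient vector is additionally projected off the
    design null vector (cell rates are unaffected).  Raises if any implied
    cell mortality proportion falls outside (0, 0.1).
    """
    ages = config.age_values
    periods = config.period_values
    if design is None:
        design = build_design(ages, periods)
    cohorts = design.cohorts

    alpha = _center(-config.age_curvature * (ages - config.age_vertex) ** 2)
    bp = config.period_breakpoint
    beta_raw = np.where(
        periods <= bp,
        config.period_slope_pre * (periods - periods[0]),
        config.period_slope_pre * (bp - periods[0])
        + config.period_slope_post * (periods - bp),
    )
    beta = _center(beta_raw)
    gamma = _center(config.cohort_slope * (cohorts - cohorts[0]).astype(float))

    truth = EffectEstimates(
        intercept=config.baseline_log_rate,
        age_effects=alpha, period_effects=beta, cohort_effects=gamma,
        ages=ages, periods=periods, cohorts=cohorts,
        deviance=0.0, converged=True, n_iterations=0,
    )
    if config.orthogonalize:
        theta = truth.stacked_coefficients()
        v = design.null_vector
        theta = theta - (theta @ v) * v
        A, P, C = ages.size, periods.size, cohorts.size
        truth = EffectEstimates(
            intercept=float(theta[0]),
            age_effects=np.concatenate([theta[1:A], [-theta[1:A].sum()]]),
            period_effects=np.concatenate([theta[A:A + P - 1], [-theta[A:A + P - 1].sum()]]),
            cohort_effects=np.concatenate([theta[A + P - 1:], [-theta[A + P - 1:].sum()]]),
            ages=ages, periods=periods, cohorts=cohorts,
            deviance=0.0, converged=True, n_iterations=0,
        )

    rates = np.exp(_cell_log_rates(truth))
    if rates.min() <= 0 or rates.max() >= 0.1:
        raise ValueError(
            f"rates implausible: cell mortality proportions span "
            f"[{rates.min():.3g}, {rates.max():.3g}], must lie in (0, 0.1)"
        )
    return truth


def _cell_log_rates(truth: EffectEstimates) -> np.ndarray:
    A = truth.age_effects.size
    P = truth.period_effects.size
    i, j = np.meshgrid(np.arange(A), np.arange(P), indexing="ij")
    k = j - i + (A - 1)
    return (truth.intercept + truth.age_effects[i]
            + truth.period_effects[j] + truth.cohort_effects[k])


def simulate_surface(truth: EffectEstimates, config: SyntheticConfig) -> MortalitySurface:
    """Draw Poisson death counts deaths_ij ~ Poisson(pop_ij * exp(log rate_ij))."""
    ages = config.age_values
    periods = config.period_values
    if truth.age_effects.size != ages.size or truth.period_effects.size != periods.size:
        raise ValueError("truth dimensions do not match the configured grid")
    pop = np.full((ages.size, periods.size), float(config.population_per_cell))
    if config.population_age_decline:
        pop = pop * np.exp(-config.population_age_decline
                           * (ages - ages[0]))[:, None]
    lam = pop * np.exp(_cell_log_rates(truth))
    if np.any(lam > pop):
        raise ValueError("expected deaths exceed population in at least one cell")
    rng = np.random.default_rng(config.seed)
    deaths = rng.poisson(lam).astype(float)
    return MortalitySurface(ages, periods, deaths, pop,
                            stratum_label=f"synthetic(seed={config.seed})")


def simulate_prevalence(years, linked_effect, intercept: float, slope: float,
                        noise_sd: float = 0.5, seed: int = DEFAULT_SEED,
                        label: str = "") -> PrevalenceSeries:
    """Prevalence series tracking an effect vector: clamp(a + b*effect + noise, 0, 100)."""
    years = np.asarray(years, dtype=int)
    linked_effect = np.asarray(linked_effect, dtype=float)
    if years.size == 0:
        raise ValueError("years must be non-empty")
    if years.size != linked_effect.size:
        raise ValueError("years and linked_effect must have equal length")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    raw = intercept + slope * linked_effect + rng.normal(0.0, noise_sd, size=years.size)
    values = np.clip(raw, 0.0, 100.0)
    if np.all((values == 0.0) | (values == 100.0)):
        raise ValueError("degenerate series: every value clamped to a bound")
    return PrevalenceSeries(years, values, label=label)


def generate_study_bundle(config: SyntheticConfig | None = None) -> dict:
    """One full synthetic study: truth, surface, obesity and smoking knot series.

    Obesity knots sit at every second year from the first study year (survey
    cycles anchored at their first year) and track the true period effect with
    a rising slope; smoking knots sit at the five historical survey years
    1965/1970/1974/1980/1990 (when inside the cohort range) and track the true
    cohort effect with a positive slope, so declining cohort risk goes with
    declining smoking.  Returns a dict with keys ``config, design, truth,
    surface, obesity, smoking``.
    """
    config = config or SyntheticConfig()
    design = build_design(config.age_values, config.period_values)
    truth = generate_true_effects(config, design)
    surface = simulate_surface(truth, config)

    periods = config.period_values
    knot_idx = np.arange(0, periods.size, 2)
    obesity = simulate_prevalence(
        periods[knot_idx], truth.period_effects[knot_idx],
        intercept=35.0, slope=40.0, noise_sd=0.4,
        seed=config.seed + 1, label="synthetic obesity",
    )
    smoke_years = np.array([y for y in (1965, 1970, 1974, 1980, 1990)
                            if truth.cohorts[0] <= y <= truth.cohorts[-1]])
    if smoke_years.size < 2:
        # grid too small to reach the historical survey years: space five
        # knots across the cohort range instead
        smoke_years = np.unique(np.linspace(truth.cohorts[0], truth.cohorts[-1], 5).astype(int))
    gamma_at = np.interp(smoke_years, truth.cohorts, truth.cohort_effects)
    smoking = simulate_prevalence(
        smoke_years, gamma_at,
        intercept=33.0, slope=25.0, noise_sd=0.4,
        seed=config.seed + 2, label="synthetic smoking",
    )
    return {"config": config, "design": design, "truth": truth,
            "surface": surface, "obesity": obesity, "smoking": smoking}
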