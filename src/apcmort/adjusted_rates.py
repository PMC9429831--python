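"""Crude, age-standardized, and age-cohort adjusted mortality rate series.

The age-cohort adjusted rate turns the fitted period-effect trajectory into a
rate series by holding age and cohort fixed at their median effects:

    s_j   = u + beta_j + median(alpha) + median(gamma)
    logit variant:  rate_j = scale * e^{s_j} / (1 + e^{s_j})
    log variant:    rate_j = scale * e^{s_j}

The logit variant is the default reporting form; the log variant is the one
consistent with the log-linear model.  At mortality proportions below
5e-3 (500 per 100,000) the two differ by under 0.5% relative, since
e^s / (1 + e^s) = e^s (1 - e^s + O(e^{2s})).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .apc_core import EffectEstimates
from .data_io import MortalitySurface

__all__ = [
    "RateSeries",
    "StandardPopulation",
    "crude_rate_series",
    "age_standardized_series",
    "age_cohort_adjusted_series",
    "median_effect",
    "synthetic_standard_population",
]


@dataclass
class RateSeries:
    """Per-calendar-year mortality rates on a reporting scale (default per 100,000)."""

    years: np.ndarray
    rates: np.ndarray
    rate_scale: float = 100_000.0
    kind: str = "crude"  # crude | age_adjusted | age_cohort_adjusted
    link_variant: str | None = None  # logit | log, meaningful for age_cohort_adjusted

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.years.size != self.rates.size:
            raise ValueError("years and rates must have equal length")
        if self.years.size > 1 and np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")


@dataclass
class StandardPopulation:
    """Fixed age weights for direct standardization; normalized to sum to 1."""

    ages: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.ages.size != self.weights.size:
            raise ValueError("ages and weights must have equal length")
        if np.any(self.weights <= 0):
            raise ValueError("standard-population weights must be positive")
        self.weights = self.weights / self.weights.sum()


def synthetic_standard_population(ages) -> StandardPopulation:
    """A smooth synthetic standard-population age profile (NOT an official standard).

    Weights decline geometrically with age at 2% per year, loosely shaped like
    the US adult age pyramid.  Intended for tests and demonstrations; direct
    standardization against an official standard requires supplying that
    standard's weights explicitly.
    """
    ages = np.asarray(ages, dtype=int)
    return StandardPopulation(ages, np.exp(-0.02 * (ages - ages[0])))


def crude_rate_series(surface: MortalitySurface) -> RateSeries:
    """Total deaths over total person-years for each calendar year."""
    rates = surface.deaths.sum(axis=0) / surface.population.sum(axis=0)
    return RateSeries(surface.periods, rates * surface.rate_scale,
                      surface.rate_scale, kind="crude")


def age_standardized_series(surface: MortalitySurface, std: StandardPopulation) -> RateSeries:
    """Directly age-standardized rates: fixed-weight average of age-specific rates."""
    if not np.array_equal(std.ages, surface.ages):
        raise ValueError("standard population ages must match the surface ages")
    specific = surface.deaths / surface.population
    rates = std.weights @ specific
    return RateSeries(surface.periods, rates * surface.rate_scale,
                      surface.rate_scale, kind="age_adjusted")


def median_effect(effects) -> float:
    """Sample median; even length averages the two central order statistics."""
    effects = np.asarray(effects, dtype=float)
    if effects.size == 0:
        raise ValueError("cannot take the median of an empty effect vector")
    return float(np.median(effects))


def age_cohort_adjusted_series(
    estimates: EffectEstimates,
    link_variant: str = "logit",
    rate_scale: float = 100_000.0,
) -> RateSeries:
    """Age-cohort adjusted rate series from a fitted APC decomposition.

    Only the sum u + beta_j + median(alpha) + median(gamma) enters, so the
    series is invariant to shifting a constant between the intercept and the
    period effects.
    """
    if estimates.period_effects.size == 0:
        raise ValueError("estimates have no period effects")
    s = (
        estimates.intercept
        + estimates.period_effects
        + median_effect(estimates.age_effects)
        + median_effect(estimates.cohort_effects)
    )
    if link_variant == "logit":
        rates = expit(s)
    elif link_variant == "log":
        rates = np.exp(s)
    else:
        raise ValueError(f"link_variant must be 'logit' or 'log', got {link_variant!r}")
    years = estimates.periods if estimates.periods is not None else np.arange(s.size)
    return RateSeries(years, rates * rate_scale, rate_scale,
                      kind="age_cohort_adjusted", link_variant=link_variant)
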