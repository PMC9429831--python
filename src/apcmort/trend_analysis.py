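"""Annual interpolation of sparse prevalence series and Pearson trend correlations.

Two correlation families are computed: mortality rate series (crude,
age-adjusted, or age-cohort adjusted) against annual obesity prevalence over
the study period, and fitted birth-cohort effects against historical smoking
prevalence over the birth-year window the smoking data cover.  The
cohort-smoking pairing matches the smoking prevalence observed in calendar
year Y with the cohort born in year Y (an optional lag shifts the calendar
year); prevalence knots are joined by piecewise-linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .adjusted_rates import RateSeries
from .apc_core import EffectEstimates
from .data_io import PrevalenceSeries

__all__ = [
    "CorrelationResult",
    "interpolate_annual",
    "pearson",
    "correlate_rates_with_obesity",
    "correlate_cohort_effects_with_smoking",
]


@dataclass
class CorrelationResult:
    """Pearson r with its two-sided t test (df = n - 2)."""

    r: float
    n: int
    t_statistic: float
    df: int
    p_value: float
    pair_label: str = ""


def interpolate_annual(series: PrevalenceSeries, target_years,
                       hold_right: bool = False) -> PrevalenceSeries:
    """Piecewise-linear interpolation of a prevalence series onto annual years.

    Knot years reproduce knot values exactly.  Target years outside the knot
    range raise (no extrapolation), except that ``hold_right=True`` carries
    the final knot value forward — used when a reporting year falls just past
    the last survey cycle.
    """
    target_years = np.asarray(target_years, dtype=int)
    if series.years.size < 2:
        raise ValueError("need at least 2 knots to interpolate")
    below = target_years < series.years[0]
    above = target_years > series.years[-1]
    if np.any(below) or (np.any(above) and not hold_right):
        bad = np.concatenate([target_years[below],
                              target_years[above] if not hold_right else []]).astype(int)
        raise ValueError(f"target years outside knot range "
                         f"[{series.years[0]}, {series.years[-1]}]: {sorted(set(bad.tolist()))}")
    values = np.interp(target_years, series.years, series.values)
    return PrevalenceSeries(target_years, values, label=series.label)


def pearson(x, y, pair_label: str = "") -> CorrelationResult:
    """Sample Pearson correlation with the two-sided t test on n - 2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input vector")
    r = float(stats.pearsonr(x, y).statistic)
    df = n - 2
    if abs(r) >= 1.0:
        t = float(np.inf) if r > 0 else float(-np.inf)
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(r=r, n=n, t_statistic=float(t), df=df,
                             p_value=p, pair_label=pair_label)


def correlate_rates_with_obesity(rate_series: RateSeries,
                                 obesity: PrevalenceSeries) -> CorrelationResult:
    """Correlate a mortality rate series with obesity prevalence over common years."""
    common, ri, oi = np.intersect1d(rate_series.years, obesity.years,
                                    return_indices=True)
    if common.size < 3:
        raise ValueError(f"only {common.size} overlapping years; need at least 3")
    label = f"{rate_series.kind} vs {obesity.label or 'obesity'} ({common[0]}-{common[-1]})"
    return pearson(rate_series.rates[ri], obesity.values[oi], pair_label=label)


def correlate_cohort_effects_with_smoking(
    estimates: EffectEstimates,
    smoking: PrevalenceSeries,
    cohort_window: tuple[int, int] = (1965, 1990),
    lag: int = 0,
) -> CorrelationResult:
    """Correlate fitted cohort effects with smoking prevalence over a birth-year window.

    The cohort born in year k is paired with the (interpolated) smoking
    prevalence at calendar year k + lag; the default lag of 0 pairs each
    birth cohort with same-year adult smoking prevalence.
    """
    lo, hi = cohort_window
    if estimates.cohorts is None:
        raise ValueError("estimates carry no cohort labels")
    mask = (estimates.cohorts >= lo) & (estimates.cohorts <= hi)
    years = estimates.cohorts[mask]
    if years.size == 0:
        raise ValueError(f"no estimated cohorts in window {lo}-{hi}")
    annual = interpolate_annual(smoking, years + lag)
    label = f"cohort effects vs {smoking.label or 'smoking'} ({lo}-{hi}, lag {lag})"
    return pearson(estimates.cohort_effects[mask], annual.values, pair_label=label)
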