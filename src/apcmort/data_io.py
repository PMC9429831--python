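"""Reading and writing mortality surfaces, prevalence series, and result tables.

Mortality surfaces live on a Lexis rectangle: death counts and person-years
tabulated by single year of age and single calendar year.  The supported input
dialects are the CDC-WONDER-style tab-separated export (header row, data rows,
optional trailing "Notes" metadata block) and a tidy CSV with columns
``age, year, deaths, population``.  All outputs are tidy CSV.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MortalitySurface",
    "PrevalenceSeries",
    "read_wonder_export",
    "read_surface_csv",
    "write_surface_csv",
    "read_prevalence_csv",
    "write_prevalence_csv",
    "write_rate_series_csv",
    "read_rate_series_csv",
    "write_effects_csv",
    "read_effects_csv",
    "write_correlation_csv",
]

#: Cell values CDC WONDER emits instead of a count when data are withheld.
SENTINELS = frozenset({"suppressed", "unreliable", "missing", "not applicable"})


def _check_consecutive(values: np.ndarray, name: str) -> None:
    if values.size == 0:
        raise ValueError(f"{name} is empty")
    if values.size > 1 and not np.all(np.diff(values) == 1):
        raise ValueError(f"{name} must be strictly increasing with step 1, got {values.tolist()}")


@dataclass
class MortalitySurface:
    """Death counts and person-years on an age x calendar-year grid (one stratum).

    ``deaths[i, j]`` and ``population[i, j]`` refer to age ``ages[i]`` in year
    ``periods[j]``; the birth cohort of that cell is ``periods[j] - ages[i]``.
    """

    ages: np.ndarray
    periods: np.ndarray
    deaths: np.ndarray
    population: np.ndarray
    stratum_label: str = ""
    rate_scale: float = 100_000.0

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.periods = np.asarray(self.periods, dtype=int)
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.population = np.asarray(self.population, dtype=float)
        _check_consecutive(self.ages, "ages")
        _check_consecutive(self.periods, "periods")
        shape = (self.ages.size, self.periods.size)
        if self.deaths.shape != shape or self.population.shape != shape:
            raise ValueError(
                f"deaths/population must have shape {shape}, got "
                f"{self.deaths.shape} and {self.population.shape}"
            )
        if not np.all(self.population > 0):
            raise ValueError("all population entries must be > 0")
        if np.any(self.deaths < 0) or np.any(self.deaths > self.population):
            raise ValueError("deaths must satisfy 0 <= deaths <= population in every cell")
        if self.rate_scale <= 0:
            raise ValueError("rate_scale must be positive")

    @property
    def cohorts(self) -> np.ndarray:
        """Birth years present on the grid, oldest cohort first."""
        return np.arange(self.periods[0] - self.ages[-1], self.periods[-1] - self.ages[0] + 1)


@dataclass
class PrevalenceSeries:
    """A prevalence time series in percent (e.g. obesity or current smoking)."""

    years: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.size != self.values.size:
            raise ValueError("years and values must have equal length")
        if self.years.size and np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if self.years.size and (np.any(self.values < 0) or np.any(self.values > 100)):
            raise ValueError("prevalence values must lie in [0, 100] percent")


# ---------------------------------------------------------------------------
# CDC-WONDER-style export
# ---------------------------------------------------------------------------

def _match_column(headers: list[str], want: str) -> int:
    """Locate the header column for *want* in {age, year, deaths, population}."""
    lowered = [h.strip().strip('"').lower() for h in headers]
    if want == "age":
        hits = [i for i, h in enumerate(lowered) if "age" in h]
        coded = [i for i in hits if "code" in lowered[i]]
        hits = coded or hits
    elif want == "year":
        hits = [i for i, h in enumerate(lowered) if "year" in h and "age" not in h]
        coded = [i for i in hits if "code" in lowered[i]]
        hits = coded or hits
    elif want == "deaths":
        hits = [i for i, h in enumerate(lowered) if "death" in h]
    else:
        hits = [i for i, h in enumerate(lowered) if "population" in h]
    if not hits:
        raise ValueError(f"no column matching '{want}' in header {headers!r}")
    return hits[0]


def _leading_int(text: str) -> int:
    """Parse '60' or '60 years' to 60."""
    tok = text.strip().strip('"').split()
    return int(tok[0])


def read_wonder_export(
    path,
    stratum_label: str = "",
    age_range: tuple[int, int] | None = None,
    period_range: tuple[int, int] | None = None,
    rate_scale: float = 100_000.0,
) -> MortalitySurface:
    """Parse a CDC-WONDER-style tab-separated export into a mortality surface.

    The dialect is tab-separated with optionally double-quoted fields.  Data
    rows end at the first line whose first field is empty or equals "Notes";
    everything after is metadata and is ignored.  Rows outside the configured
    ``age_range``/``period_range`` window (inclusive) are dropped.

    Suppressed or unreliable cells are a hard error: the age-period-cohort
    estimator needs a complete Lexis rectangle, and silently imputing withheld
    counts would bias it.
    """
    with open(path, "r", newline="") as fh:
        text = fh.read()
    lines = text.splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")

    header = next(csv.reader([lines[0]], delimiter="\t"))
    cols = {w: _match_column(header, w) for w in ("age", "year", "deaths", "population")}

    records: dict[tuple[int, int], tuple[float, float]] = {}
    bad_numeric: list[str] = []
    suppressed: list[tuple[int, int]] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        fields = next(csv.reader([raw], delimiter="\t"), [])
        if not fields or fields[0].strip().strip('"') in ("", "Notes"):
            break  # trailing notes/metadata block
        try:
            age = _leading_int(fields[cols["age"]])
            year = _leading_int(fields[cols["year"]])
        except (ValueError, IndexError):
            bad_numeric.append(f"line {lineno}: cannot parse age/year from {raw!r}")
            continue
        cell_issue = False
        vals = []
        for w in ("deaths", "population"):
            s = fields[cols[w]].strip().strip('"')
            if s.lower() in SENTINELS:
                suppressed.append((age, year))
                cell_issue = True
                break
            try:
                vals.append(float(s.replace(",", "")))
            except ValueError:
                bad_numeric.append(f"line {lineno}: non-numeric {w} value {s!r}")
                cell_issue = True
                break
        if cell_issue:
            continue
        records[(age, year)] = (vals[0], vals[1])

    if suppressed:
        cells = ", ".join(f"(age {a}, year {y})" for a, y in sorted(set(suppressed)))
        raise ValueError(f"suppressed/unreliable cells cannot be used: {cells}")
    if bad_numeric:
        raise ValueError("; ".join(bad_numeric))
    if not records:
        raise ValueError(f"{path}: no data rows found")

    ages_seen = sorted({a for a, _ in records})
    years_seen = sorted({y for _, y in records})
    lo_a, hi_a = age_range if age_range else (ages_seen[0], ages_seen[-1])
    lo_p, hi_p = period_range if period_range else (years_seen[0], years_seen[-1])
    ages = np.arange(lo_a, hi_a + 1)
    periods = np.arange(lo_p, hi_p + 1)

    deaths = np.empty((ages.size, periods.size))
    population = np.empty_like(deaths)
    missing = []
    for i, a in enumerate(ages):
        for j, y in enumerate(periods):
            try:
                deaths[i, j], population[i, j] = records[(a, int(y))]
            except KeyError:
                missing.append((int(a), int(y)))
    if missing:
        cells = ", ".join(f"({a}, {y})" for a, y in missing[:20])
        more = "" if len(missing) <= 20 else f" (+{len(missing) - 20} more)"
        raise ValueError(f"missing (age, period) cells after filtering: {cells}{more}")

    return MortalitySurface(ages, periods, deaths, population, stratum_label, rate_scale)


# ---------------------------------------------------------------------------
# Tidy CSV surfaces
# ---------------------------------------------------------------------------

def read_surface_csv(path, stratum_label: str = "", rate_scale: float = 100_000.0) -> MortalitySurface:
    """Read a tidy CSV surface with columns age, year, deaths, population."""
    df = pd.read_csv(path)
    need = {"age", "year", "deaths", "population"}
    if not need.issubset(df.columns):
        raise ValueError(f"surface CSV must have columns {sorted(need)}, got {list(df.columns)}")
    ages = np.sort(df["age"].unique())
    periods = np.sort(df["year"].unique())
    wide_d = df.pivot(index="age", columns="year", values="deaths")
    wide_p = df.pivot(index="age", columns="year", values="population")
    if wide_d.isna().any().any():
        gone = [(int(a), int(y)) for a, y in zip(*np.where(wide_d.isna().values))]
        raise ValueError(f"incomplete surface: {len(gone)} missing cells")
    return MortalitySurface(
        ages, periods,
        wide_d.loc[ages, periods].to_numpy(),
        wide_p.loc[ages, periods].to_numpy(),
        stratum_label, rate_scale,
    )


def write_surface_csv(surface: MortalitySurface, path) -> None:
    ii, jj = np.meshgrid(np.arange(surface.ages.size), np.arange(surface.periods.size), indexing="ij")
    pd.DataFrame({
        "age": surface.ages[ii.ravel()],
        "year": surface.periods[jj.ravel()],
        "deaths": surface.deaths.ravel(),
        "population": surface.population.ravel(),
    }).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Prevalence and rate series
# ---------------------------------------------------------------------------

def read_prevalence_csv(path, label: str = "") -> PrevalenceSeries:
    """Read a two-column (year, percent) CSV, returning the series sorted by year."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("prevalence CSV needs two columns: year, percent")
    years = df.iloc[:, 0].to_numpy(dtype=int)
    values = df.iloc[:, 1].to_numpy(dtype=float)
    if np.unique(years).size != years.size:
        dupes = sorted({int(y) for y in years if (years == y).sum() > 1})
        raise ValueError(f"duplicate years in prevalence series: {dupes}")
    order = np.argsort(years)
    return PrevalenceSeries(years[order], values[order], label or str(path))


def write_prevalence_csv(series: PrevalenceSeries, path) -> None:
    pd.DataFrame({"year": series.years, "percent": series.values}).to_csv(
        path, index=False, float_format="%.10g"
    )


def write_rate_series_csv(series, path) -> None:
    """Write a RateSeries as tidy CSV (year, rate_per_scale, scale); 10-digit round-trip."""
    if len(series.years) == 0:
        raise ValueError("cannot write an empty rate series")
    pd.DataFrame({
        "year": np.asarray(series.years, dtype=int),
        "rate_per_scale": np.asarray(series.rates, dtype=float),
        "scale": float(series.rate_scale),
        "kind": series.kind,
        "variant": series.link_variant or "",
    }).to_csv(path, index=False, float_format="%.10g")


def read_rate_series_csv(path):
    from .adjusted_rates import RateSeries  # local import to avoid a cycle

    df = pd.read_csv(path, keep_default_na=False)
    if df.empty:
        raise ValueError("empty rate series file")
    variant = str(df["variant"].iloc[0]) if "variant" in df else ""
    return RateSeries(
        years=df["year"].to_numpy(dtype=int),
        rates=df["rate_per_scale"].to_numpy(dtype=float),
        rate_scale=float(df["scale"].iloc[0]),
        kind=str(df["kind"].iloc[0]) if "kind" in df else "crude",
        link_variant=variant or None,
    )


# ---------------------------------------------------------------------------
# Fitted effects and correlation results
# ---------------------------------------------------------------------------

def write_effects_csv(estimates, path) -> None:
    """Write fitted effects as tidy CSV: block (intercept|age|period|cohort), category, estimate."""
    rows = [("intercept", "", estimates.intercept)]
    for block, labels, vec in (
        ("age", estimates.ages, estimates.age_effects),
        ("period", estimates.periods, estimates.period_effects),
        ("cohort", estimates.cohorts, estimates.cohort_effects),
    ):
        rows += [(block, int(lab), float(v)) for lab, v in zip(labels, vec)]
    pd.DataFrame(rows, columns=["block", "category", "estimate"]).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_effects_csv(path):
    from .apc_core import EffectEstimates  # local import to avoid a cycle

    df = pd.read_csv(path, keep_default_na=False)
    blocks = {}
    for block in ("age", "period", "cohort"):
        sub = df[df["block"] == block].copy()
        if sub.empty:
            raise ValueError(f"effects CSV missing block '{block}'")
        sub["category"] = sub["category"].astype(int)
        sub = sub.sort_values("category")
        blocks[block] = (sub["category"].to_numpy(), sub["estimate"].to_numpy(dtype=float))
    icpt = df[df["block"] == "intercept"]
    if icpt.empty:
        raise ValueError("effects CSV missing intercept row")
    return EffectEstimates(
        intercept=float(icpt["estimate"].iloc[0]),
        age_effects=blocks["age"][1], period_effects=blocks["period"][1],
        cohort_effects=blocks["cohort"][1],
        ages=blocks["age"][0], periods=blocks["period"][0], cohorts=blocks["cohort"][0],
        deviance=float("nan"), converged=True, n_iterations=0,
    )


def write_correlation_csv(results, path) -> None:
    """Write one or more CorrelationResults as tidy CSV (label, r, n, t, df, p)."""
    if not isinstance(results, (list, tuple)):
        results = [results]
    pd.DataFrame([
        {"label": c.pair_label, "r": c.r, "n": c.n, "t": c.t_statistic, "df": c.df, "p": c.p_value}
        for c in results
    ]).to_csv(path, index=False, float_format="%.10g")
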