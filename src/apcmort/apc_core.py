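"""Age-period-cohort design construction and the Intrinsic Estimator.

The model decomposes a log mortality proportion additively,

    log r_ij = u + alpha_i + beta_j + gamma_k,      k = j - i (birth year),

with deviation (sum-to-zero) coded age, period, and cohort blocks.  Because
cohort = period - age exactly, the design matrix has a one-dimensional null
space and the effects are identified only up to a linear trend.  The Intrinsic
Estimator (IE) resolves this by fitting the Poisson likelihood on the
orthogonal complement of the null vector: eigendecompose X'X, drop the single
null eigenvector, run iteratively reweighted least squares in the reduced
basis, and map the coefficients back.  Any just-identified constrained fit
shares all estimable functions (fitted rates, second differences of effects)
with the IE, which is how the implementation is validated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .data_io import MortalitySurface

__all__ = [
    "APCDesign",
    "EffectEstimates",
    "build_design",
    "null_vector",
    "fit_intrinsic_estimator",
    "fit_constrained",
    "second_differences",
    "fitted_log_rates",
]

log = logging.getLogger(__name__)

#: Relative eigenvalue threshold below which a direction of X'X counts as null.
NULL_EIGVAL_RTOL = 1e-8


@dataclass
class APCDesign:
    """Deviation-coded APC design on an A x P Lexis grid with C = A + P - 1 cohorts.

    Rows iterate ages (outer) then periods (inner), matching ``deaths.ravel()``
    on the corresponding surface.  Columns are intercept, then the first A-1
    age, P-1 period, and C-1 cohort categories; the last category of each
    block is the omitted one and its effect is minus the sum of the others.
    """

    ages: np.ndarray
    periods: np.ndarray
    cohorts: np.ndarray
    matrix: np.ndarray
    column_map: list[tuple[str, int | None]]
    null_vector: np.ndarray

    @property
    def n_ages(self) -> int:
        return self.ages.size

    @property
    def n_periods(self) -> int:
        return self.periods.size

    @property
    def n_cohorts(self) -> int:
        return self.cohorts.size


@dataclass
class EffectEstimates:
    """Intercept plus centered age/period/cohort effect vectors from one fit.

    The intercept is on the log scale of the modeled proportion (deaths per
    person-year); a reporting rate scale is applied only downstream.
    """

    intercept: float
    age_effects: np.ndarray
    period_effects: np.ndarray
    cohort_effects: np.ndarray
    ages: np.ndarray = field(default=None)
    periods: np.ndarray = field(default=None)
    cohorts: np.ndarray = field(default=None)
    deviance: float = float("nan")
    converged: bool = True
    n_iterations: int = 0

    def __post_init__(self) -> None:
        self.age_effects = np.asarray(self.age_effects, dtype=float)
        self.period_effects = np.asarray(self.period_effects, dtype=float)
        self.cohort_effects = np.asarray(self.cohort_effects, dtype=float)

    def stacked_coefficients(self) -> np.ndarray:
        """Intercept plus deviation-coded coefficients (last category of each block dropped)."""
        return np.concatenate([
            [self.intercept],
            self.age_effects[:-1],
            self.period_effects[:-1],
            self.cohort_effects[:-1],
        ])


def _deviation_block(codes: np.ndarray, n_cat: int) -> np.ndarray:
    """Sum-to-zero coding, last category omitted: row in last category gets -1 everywhere."""
    block = np.zeros((codes.size, n_cat - 1))
    idx = np.arange(codes.size)
    interior = codes < n_cat - 1
    block[idx[interior], codes[interior]] = 1.0
    block[~interior, :] = -1.0
    return block


def build_design(ages, periods) -> APCDesign:
    """Build the effect-coded APC design and its unit null vector.

    Requires at least 3 consecutive ages and 3 consecutive periods; with fewer
    categories the null space is not guaranteed to be one-dimensional.
    """
    ages = np.asarray(ages, dtype=int)
    periods = np.asarray(periods, dtype=int)
    for vals, name in ((ages, "ages"), (periods, "periods")):
        if vals.size < 3:
            raise ValueError(f"need at least 3 {name}, got {vals.size}")
        if not np.all(np.diff(vals) == 1):
            raise ValueError(f"{name} must be consecutive years")

    A, P = ages.size, periods.size
    C = A + P - 1
    cohorts = np.arange(periods[0] - ages[-1], periods[-1] - ages[0] + 1)

    ii, jj = np.meshgrid(np.arange(A), np.arange(P), indexing="ij")
    i = ii.ravel()
    j = jj.ravel()
    k = j - i + (A - 1)  # cohort category of row (i, j)

    matrix = np.hstack([
        np.ones((A * P, 1)),
        _deviation_block(i, A),
        _deviation_block(j, P),
        _deviation_block(k, C),
    ])
    column_map: list[tuple[str, int | None]] = [("intercept", None)]
    column_map += [("age", int(a)) for a in ages[:-1]]
    column_map += [("period", int(p)) for p in periods[:-1]]
    column_map += [("cohort", int(c)) for c in cohorts[:-1]]

    v = null_vector(matrix)
    return APCDesign(ages, periods, cohorts, matrix, column_map, v)


def null_vector(matrix: np.ndarray, rtol: float = NULL_EIGVAL_RTOL) -> np.ndarray:
    """Unit-norm right-singular vector of the single zero singular value of *matrix*.

    The sign is fixed so the first entry exceeding 1e-10 in magnitude is
    positive.  Raises if the matrix has no null direction, or more than one,
    at relative tolerance *rtol* — the error reports the tail of the spectrum.
    """
    s = np.linalg.svd(matrix, compute_uv=False)
    null_mask = s < rtol * s[0]
    n_null = int(null_mask.sum())
    if n_null != 1:
        tail = np.array2string(s[-min(5, s.size):], precision=3)
        what = "no null dimension" if n_null == 0 else f"{n_null} null dimensions"
        raise ValueError(f"expected exactly one null dimension, found {what}; spectrum tail {tail}")
    _, _, vt = np.linalg.svd(matrix)
    v = vt[-1]
    lead = np.flatnonzero(np.abs(v) > 1e-10)[0]
    if v[lead] < 0:
        v = -v
    return v / np.linalg.norm(v)


def second_differences(effects) -> np.ndarray:
    """Second differences v[t+1] - 2 v[t] + v[t-1]; estimable in any APC parameterization."""
    effects = np.asarray(effects, dtype=float)
    if effects.size < 3:
        raise ValueError("need at least 3 values for second differences")
    return np.diff(effects, n=2)


def fitted_log_rates(design: APCDesign, estimates: EffectEstimates) -> np.ndarray:
    """Cell-level fitted log proportions u + alpha_i + beta_j + gamma_k on the grid."""
    A, P = design.n_ages, design.n_periods
    i, j = np.meshgrid(np.arange(A), np.arange(P), indexing="ij")
    k = j - i + (A - 1)
    return (
        estimates.intercept
        + estimates.age_effects[i]
        + estimates.period_effects[j]
        + estimates.cohort_effects[k]
    )


# ---------------------------------------------------------------------------
# Poisson IRLS in a reduced basis
# ---------------------------------------------------------------------------

def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return float(2.0 * np.sum(xlogy(y, y / mu) - (y - mu)))


def _irls_poisson(X: np.ndarray, y: np.ndarray, offset: np.ndarray,
                  max_iter: int, tol: float) -> tuple[np.ndarray, float, bool, int]:
    """IRLS for Poisson regression with log link and offset; relative-deviance stopping.

    Start values come from a least-squares fit to log((y + 0.5) / exposure),
    which is finite for zero-count cells.
    """
    # start from a least-squares fit to the smoothed log proportion
    z0 = np.log(y + 0.5) - offset
    beta, *_ = np.linalg.lstsq(X, z0, rcond=None)
    eta = X @ beta + offset
    mu = np.exp(eta)
    if not np.all(np.isfinite(mu)):
        raise FloatingPointError("non-finite fitted means at start values")
    dev = _poisson_deviance(y, mu)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.any(mu <= 0) or not np.all(np.isfinite(mu)):
            raise FloatingPointError("degenerate IRLS weights (zero or non-finite fitted mean)")
        z = (eta - offset) + (y - mu) / mu
        Xw = X * mu[:, None]
        try:
            beta = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        except np.linalg.LinAlgError as exc:
            raise FloatingPointError(f"singular weighted normal equations: {exc}") from exc
        eta = X @ beta + offset
        mu = np.exp(eta)
        if not np.all(np.isfinite(mu)):
            raise FloatingPointError("fitted means overflowed during IRLS")
        dev_new = _poisson_deviance(y, mu)
        if abs(dev - dev_new) <= tol * (abs(dev_new) + 0.1):
            dev = dev_new
            converged = True
            break
        dev = dev_new
    if not converged:
        log.warning("IRLS did not converge in %d iterations (deviance %.6g)", max_iter, dev)
        warnings.warn(f"IRLS did not converge in {max_iter} iterations", RuntimeWarning)
    return beta, dev, converged, it


def _expand(design: APCDesign, coefs: np.ndarray, deviance: float,
            converged: bool, n_iter: int) -> EffectEstimates:
    """Expand deviation-coded coefficients to full centered effect vectors."""
    A, P, C = design.n_ages, design.n_periods, design.n_cohorts
    u = float(coefs[0])
    pos = 1
    blocks = []
    for size in (A, P, C):
        part = coefs[pos:pos + size - 1]
        blocks.append(np.concatenate([part, [-part.sum()]]))
        pos += size - 1
    return EffectEstimates(
        intercept=u,
        age_effects=blocks[0], period_effects=blocks[1], cohort_effects=blocks[2],
        ages=design.ages, periods=design.periods, cohorts=design.cohorts,
        deviance=deviance, converged=converged, n_iterations=n_iter,
    )


def _prepare(surface: MortalitySurface, design: APCDesign | None):
    if design is None:
        design = build_design(surface.ages, surface.periods)
    if not (np.array_equal(design.ages, surface.ages)
            and np.array_equal(design.periods, surface.periods)):
        raise ValueError("design age/period grid does not match the surface")
    y = surface.deaths.ravel()
    offset = np.log(surface.population.ravel())
    return design, y, offset


def fit_intrinsic_estimator(
    surface: MortalitySurface,
    design: APCDesign | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> EffectEstimates:
    """Fit the APC Poisson model by the Intrinsic Estimator.

    The deaths are modeled as Poisson with log person-years offset, so the
    linear predictor is the log of the mortality proportion.  The fit is run
    in the eigenbasis of X'X with the single null eigenvector removed, which
    makes the coefficient vector orthogonal to the design null vector — the
    defining property of the IE.
    """
    design, y, offset = _prepare(surface, design)
    X = design.matrix
    eigval, eigvec = np.linalg.eigh(X.T @ X)
    null_mask = eigval < NULL_EIGVAL_RTOL * eigval[-1]
    if int(null_mask.sum()) != 1:
        raise ValueError(
            f"design must have exactly one null eigenvalue, found {int(null_mask.sum())}"
        )
    basis = eigvec[:, ~null_mask]
    beta_r, dev, converged, n_iter = _irls_poisson(X @ basis, y, offset, max_iter, tol)
    return _expand(design, basis @ beta_r, dev, converged, n_iter)


def fit_constrained(
    surface: MortalitySurface,
    design: APCDesign | None = None,
    constraint: tuple[int, int] = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> EffectEstimates:
    """Fit the APC model under an equality constraint on two cohort effects.

    ``constraint`` names two distinct cohort birth years whose effects are set
    equal (default: the two oldest cohorts).  Every such just-identified fit
    spans the same model space as the IE, so fitted rates, deviance, and all
    estimable functions agree with the IE fit; only the effect-vector split
    differs.  Used as the validation oracle for the IE.
    """
    design, y, offset = _prepare(surface, design)
    if constraint is None:
        constraint = (int(design.cohorts[0]), int(design.cohorts[1]))
    k1, k2 = constraint
    if k1 == k2:
        raise ValueError("constraint must name two distinct cohort categories")

    ncol = design.matrix.shape[1]
    c = np.zeros(ncol)
    cohort_cols = {cat: idx for idx, (blk, cat) in enumerate(design.column_map) if blk == "cohort"}
    last = int(design.cohorts[-1])
    for year, sign in ((int(k1), 1.0), (int(k2), -1.0)):
        if year == last:
            # omitted category: its effect is minus the sum of the block's coefficients
            for idx in cohort_cols.values():
                c[idx] -= sign
        elif year in cohort_cols:
            c[cohort_cols[year]] += sign
        else:
            raise ValueError(f"cohort year {year} not on the design grid")

    if abs(c @ design.null_vector) < 1e-10:
        raise ValueError("constraint does not remove the null direction")
    # orthonormal basis of the constraint hyperplane {b : c.b = 0}
    cn = c / np.linalg.norm(c)
    u_, _, _ = np.linalg.svd(np.eye(ncol) - np.outer(cn, cn))
    basis = u_[:, :ncol - 1]
    beta_r, dev, converged, n_iter = _irls_poisson(
        design.matrix @ basis, y, offset, max_iter, tol
    )
    return _expand(design, basis @ beta_r, dev, converged, n_iter)
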