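"""Design construction, null-space handling, and Intrinsic Estimator correctness.

The load-bearing checks are the oracle equivalences: the IE and any
just-identified constrained fit must agree on every estimable function
(fitted log rates, second differences, deviance), and the IE's fitted values
must match an independent GLM fit of the same reduced-basis model.
"""

import numpy as np
import pytest

from apcmort import (
    MortalitySurface,
    SyntheticConfig,
    build_design,
    fit_constrained,
    fit_intrinsic_estimator,
    fitted_log_rates,
    generate_true_effects,
    null_vector,
    second_differences,
    simulate_surface,
)


class TestBuildDesign:
    def test_study_grid_bookkeeping(self, study_design):
        d = study_design
        assert d.matrix.shape == (60 * 20, 157)
        assert d.n_cohorts == 79
        assert d.cohorts[0] == 1915 and d.cohorts[-1] == 1993
        assert np.linalg.matrix_rank(d.matrix) == 156

    def test_small_grid_dimensions(self):
        d = build_design(np.arange(60, 63), np.arange(2000, 2003))
        assert d.matrix.shape == (9, 9)
        assert np.linalg.matrix_rank(d.matrix) == 8
        assert d.n_cohorts == 5

    @pytest.mark.parametrize("ages,periods", [
        (np.arange(60, 63), np.arange(2000, 2003)),
        (np.arange(25, 45), np.arange(1999, 2009)),
    ])
    def test_null_vector_annihilated(self, ages, periods):
        d = build_design(ages, periods)
        assert np.abs(d.matrix @ d.null_vector).max() < 1e-10
        assert abs(np.linalg.norm(d.null_vector) - 1.0) < 1e-12

    def test_degenerate_dimensions_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            build_design(np.array([60, 61]), np.arange(2000, 2004))

    def test_column_map_covers_all_columns(self, study_design):
        blocks = [b for b, _ in study_design.column_map]
        assert blocks.count("intercept") == 1
        assert blocks.count("age") == 59
        assert blocks.count("period") == 19
        assert blocks.count("cohort") == 78


class TestNullVector:
    def test_full_rank_matrix_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="no null dimension"):
            null_vector(rng.normal(size=(20, 5)))

    def test_multiple_null_dimensions_rejected(self):
        X = np.zeros((6, 4))
        X[:, 0] = 1.0  # columns 1..3 all zero: 3 null dimensions
        with pytest.raises(ValueError, match="null dimensions"):
            null_vector(X)

    def test_row_permutation_invariance(self):
        """The null space is a property of the column space; row order is irrelevant."""
        d = build_design(np.arange(60, 66), np.arange(2000, 2006))
        rng = np.random.default_rng(20220817)
        perm = rng.permutation(d.matrix.shape[0])
        v1, v2 = d.null_vector, null_vector(d.matrix[perm])
        assert min(np.abs(v1 - v2).max(), np.abs(v1 + v2).max()) < 1e-10

    def test_sign_convention(self, study_design):
        v = study_design.null_vector
        assert v[np.flatnonzero(np.abs(v) > 1e-10)[0]] > 0


class TestSecondDifferences:
    def test_known_values(self):
        np.testing.assert_allclose(second_differences([0, 1, 4, 9]), [2, 2])
        np.testing.assert_allclose(second_differences(np.arange(7) * 3.5), 0.0, atol=1e-12)

    def test_matches_diff_of_diff_oracle(self):
        rng = np.random.default_rng(20220817)
        v = rng.normal(size=30)
        manual = np.diff(np.diff(v))
        np.testing.assert_allclose(second_differences(v), manual, atol=1e-14)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            second_differences([1.0, 2.0])


def _flat_surface(rate=1e-3, pop=1e6):
    ages = np.arange(60, 66)
    periods = np.arange(2000, 2008)
    population = np.full((ages.size, periods.size), pop)
    deaths = population * rate  # exact Poisson means: the MLE is the flat model
    return MortalitySurface(ages, periods, deaths, population)


class TestIntrinsicEstimator:
    def test_flat_model_limit(self):
        """Deaths exactly at a flat model's means: all effects zero, intercept = log rate."""
        est = fit_intrinsic_estimator(_flat_surface())
        assert est.converged
        assert est.intercept == pytest.approx(np.log(1e-3), abs=1e-8)
        for vec in (est.age_effects, est.period_effects, est.cohort_effects):
            assert np.abs(vec).max() < 1e-7

    def test_effect_blocks_centered_and_orthogonal(self, paradox_bundle, paradox_fit):
        est = paradox_fit
        for vec in (est.age_effects, est.period_effects, est.cohort_effects):
            assert abs(vec.sum()) < 1e-8
        dot = est.stacked_coefficients() @ paradox_bundle["design"].null_vector
        assert abs(dot) < 1e-6

    def test_population_scaling_shifts_only_intercept(self, small_grid):
        surf = small_grid["surface"]
        doubled = MortalitySurface(surf.ages, surf.periods, surf.deaths,
                                   2.0 * surf.population)
        est1 = fit_intrinsic_estimator(surf, tol=1e-12, max_iter=200)
        est2 = fit_intrinsic_estimator(doubled, tol=1e-12, max_iter=200)
        assert est2.intercept - est1.intercept == pytest.approx(-np.log(2.0), abs=1e-8)
        for blk in ("age_effects", "period_effects", "cohort_effects"):
            np.testing.assert_allclose(getattr(est1, blk), getattr(est2, blk), atol=1e-8)

    def test_parameter_recovery_dense_population(self):
        """With 1e7 person-years/cell and truth orthogonal to the null vector,
        the IE recovers each effect block to within 0.01."""
        from apcmort import recovery_config

        cfg = recovery_config()
        truth = generate_true_effects(cfg)
        est = fit_intrinsic_estimator(simulate_surface(truth, cfg))
        for blk in ("age_effects", "period_effects", "cohort_effects"):
            t, e = getattr(truth, blk), getattr(est, blk)
            assert np.corrcoef(t, e)[0, 1] > 0.999
            assert np.abs(t - e).max() < 0.01

    def test_matches_independent_glm_fit(self, small_grid):
        """Dual route: IE fitted log rates vs statsmodels GLM on the reduced basis."""
        sm = pytest.importorskip("statsmodels.api")
        d, surf = small_grid["design"], small_grid["surface"]
        est = fit_intrinsic_estimator(surf, tol=1e-12, max_iter=200)
        w, V = np.linalg.eigh(d.matrix.T @ d.matrix)
        basis = V[:, w >= 1e-8 * w[-1]]
        res = sm.GLM(surf.deaths.ravel(), d.matrix @ basis,
                     family=sm.families.Poisson(),
                     offset=np.log(surf.population.ravel())).fit()
        theirs = (d.matrix @ basis @ res.params).reshape(surf.deaths.shape)
        assert np.abs(fitted_log_rates(d, est) - theirs).max() < 1e-8
        assert est.deviance == pytest.approx(res.deviance, abs=1e-6)

    def test_mismatched_design_rejected(self, small_grid, study_design):
        with pytest.raises(ValueError, match="does not match"):
            fit_intrinsic_estimator(small_grid["surface"], design=study_design)


class TestConstrainedOracle:
    @pytest.mark.parametrize("idx_pair", [(0, 1), (5, 10), (2, 16)])
    def test_estimable_functions_match_ie(self, small_grid, idx_pair):
        d, surf = small_grid["design"], small_grid["surface"]
        constraint = (int(d.cohorts[idx_pair[0]]), int(d.cohorts[idx_pair[1]]))
        ie = fit_intrinsic_estimator(surf, design=d, tol=1e-10, max_iter=200)
        con = fit_constrained(surf, design=d, constraint=constraint,
                              tol=1e-10, max_iter=200)
        assert np.abs(fitted_log_rates(d, ie) - fitted_log_rates(d, con)).max() < 1e-6
        for blk in ("age_effects", "period_effects", "cohort_effects"):
            np.testing.assert_allclose(
                second_differences(getattr(ie, blk)),
                second_differences(getattr(con, blk)), atol=1e-6)
        assert abs(ie.deviance - con.deviance) < 1e-8

    def test_effect_vectors_differ_but_deviance_agrees(self, small_grid):
        """Different identifying constraints give different effect splits but
        the same model space (deviance)."""
        d, surf = small_grid["design"], small_grid["surface"]
        c1 = fit_constrained(surf, design=d,
                             constraint=(int(d.cohorts[0]), int(d.cohorts[1])),
                             tol=1e-10, max_iter=200)
        c2 = fit_constrained(surf, design=d,
                             constraint=(int(d.cohorts[-2]), int(d.cohorts[-1])),
                             tol=1e-10, max_iter=200)
        assert abs(c1.deviance - c2.deviance) < 1e-8

    def test_identical_categories_rejected(self, small_grid):
        with pytest.raises(ValueError, match="distinct"):
            fit_constrained(small_grid["surface"], constraint=(1950, 1950))

    def test_unknown_cohort_year_rejected(self, small_grid):
        with pytest.raises(ValueError, match="not on the design grid"):
            fit_constrained(small_grid["surface"], constraint=(1800, 1801))


def test_nonconvergence_flagged():
    """An absurdly tight tolerance with one iteration must flag, not raise."""
    cfg = SyntheticConfig(ages=(60, 65), periods=(2000, 2006),
                          population_per_cell=1e5)
    surf = simulate_surface(generate_true_effects(cfg), cfg)
    with pytest.warns(RuntimeWarning, match="did not converge"):
        est = fit_intrinsic_estimator(surf, max_iter=1, tol=1e-15)
    assert not est.converged
    assert est.n_iterations == 1
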