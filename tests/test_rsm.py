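"""Quadratic model matrix, OLS fit, inference and prediction."""

import numpy as np
import pytest

from phytodoe import (build_model_matrix, coefficient_tests, fit_rsm,
                      quadratic_expand, report_frame)
from phytodoe import reference as R
from phytodoe.rsm import (RSMFit, SingularDesignError, stars_for,
                          natural_units_coefficients, term_names, term_symbols)

from conftest import ols_oracle


class TestModelMatrix:
    def test_corner_row_sign_algebra(self):
        row = quadratic_expand(np.array([[-1.0, -1.0, -1.0]]))[0]
        np.testing.assert_array_equal(
            row, [1, -1, -1, -1, 1, 1, 1, 1, 1, 1])

    def test_origin_row(self):
        row = quadratic_expand(np.array([[0.0, 0.0, 0.0]]))[0]
        np.testing.assert_array_equal(row, [1] + [0] * 9)

    def test_central_coded_row_products(self):
        # the study's true central coded levels
        a, b, c = -0.08, -0.07, -0.18
        row = quadratic_expand(np.array([[a, b, c]]))[0]
        np.testing.assert_allclose(
            row, [1, a, b, c, a * b, a * c, b * c, a**2, b**2, c**2],
            rtol=1e-15)

    def test_term_order_matches_symbols(self):
        assert term_names(["Cd", "Pb", "Cr"]) == [
            "Intercept", "Cd", "Pb", "Cr", "Cd:Pb", "Cd:Cr", "Pb:Cr",
            "Cd^2", "Pb^2", "Cr^2"]
        assert term_symbols(3) == [
            "b0", "b1", "b2", "b3", "b12", "b13", "b23", "b11", "b22", "b33"]

    def test_from_design_table(self, study_design):
        X, terms = build_model_matrix(study_design)
        assert X.shape == (81, 10)
        assert terms[0] == "Intercept"

    def test_missing_coded_columns(self, study_uptake):
        with pytest.raises(KeyError):
            build_model_matrix(study_uptake.drop(columns=["Cd_coded"]),
                               factors=["Cd", "Pb", "Cr"])


class TestFit:
    def test_noise_free_recovery(self, study_design):
        X, _ = build_model_matrix(study_design)
        b_true = R.COEFFICIENTS["Cd"]
        fit = fit_rsm(X, X @ b_true, factors=R.FACTOR_NAMES)
        np.testing.assert_allclose(fit.coef, b_true, atol=1e-10)
        assert fit.dof == 71

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_normal_equation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(12, 50)
        pts = rng.uniform(-1, 1, size=(n, 3))
        X = quadratic_expand(pts)
        y = rng.normal(size=n)
        fit = fit_rsm(X, y)
        np.testing.assert_allclose(fit.coef, ols_oracle(X, y), atol=1e-8)

    def test_matches_statsmodels(self, study_design, study_uptake):
        sm = pytest.importorskip("statsmodels.api")
        X, _ = build_model_matrix(study_design)
        y = study_uptake["Zn"].to_numpy()
        fit = fit_rsm(X, y, factors=R.FACTOR_NAMES, response="Zn")
        res = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.coef, res.params, rtol=1e-9)
        np.testing.assert_allclose(fit.se, res.bse, rtol=1e-9)
        np.testing.assert_allclose(fit.p, res.pvalues, rtol=1e-8, atol=1e-12)

    def test_permutation_invariance(self, study_design, study_uptake):
        X, _ = build_model_matrix(study_design)
        y = study_uptake["Cd"].to_numpy()
        perm = np.random.default_rng(5).permutation(len(y))
        a = fit_rsm(X, y)
        b = fit_rsm(X[perm], y[perm])
        np.testing.assert_allclose(a.coef, b.coef, atol=1e-10)
        np.testing.assert_allclose(a.residual_sd, b.residual_sd, atol=1e-10)

    def test_residual_orthogonality(self, study_design, study_uptake):
        X, _ = build_model_matrix(study_design)
        y = study_uptake["Pb"].to_numpy()
        fit = fit_rsm(X, y)
        resid = y - X @ fit.coef
        assert np.max(np.abs(X.T @ resid)) < 1e-8

    def test_constant_shift_moves_only_intercept(self, study_design, study_uptake):
        X, _ = build_model_matrix(study_design)
        y = study_uptake["Cu"].to_numpy()
        a = fit_rsm(X, y)
        b = fit_rsm(X, y + 7.5)
        assert b.coef[0] - a.coef[0] == pytest.approx(7.5, abs=1e-9)
        np.testing.assert_allclose(a.coef[1:], b.coef[1:], atol=1e-9)

    def test_singular_design_names_columns(self):
        # a 2-level design cannot separate intercept from squared terms
        pts = np.array(list(np.ndindex(2, 2, 2)), dtype=float) * 2 - 1
        pts = np.vstack([pts, pts])  # 16 rows, still rank deficient
        X = quadratic_expand(pts)
        with pytest.raises(SingularDesignError, match="rank deficient"):
            fit_rsm(X, np.zeros(len(X)), factors=["Cd", "Pb", "Cr"])

    def test_run_means_option(self, study_design, study_uptake):
        fit_all = fit_rsm(study_design, study_uptake["Cd"].to_numpy())
        fit_means = fit_rsm(study_design, study_uptake["Cd"].to_numpy(),
                            run_means=True)
        assert fit_all.n_obs == 81 and fit_all.dof == 71
        assert fit_means.n_obs == 27 and fit_means.dof == 17
        # run means preserve the OLS solution on a balanced design
        np.testing.assert_allclose(fit_means.coef, fit_all.coef, atol=1e-9)


class TestInference:
    @pytest.mark.parametrize("p, expected", [
        (0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.2, ""),
        (0.001, "**"), (0.05, ""),
    ])
    def test_star_convention(self, p, expected):
        assert stars_for(p) == expected

    def test_coefficient_tests_respect_alpha(self, cd_fit):
        strict = coefficient_tests(cd_fit, alpha=1e-12)
        loose = coefficient_tests(cd_fit, alpha=0.99)
        assert strict.significant.sum() <= loose.significant.sum()
        assert loose.significant.all()

    def test_type_one_error_rate(self, study_design):
        """A true-zero coefficient is flagged at about the nominal rate."""
        X, _ = build_model_matrix(study_design)
        n, p = X.shape
        dof = n - p
        xtx_inv = np.linalg.inv(X.T @ X)
        rng = np.random.default_rng(314)
        reps = 2000
        # all-zero truth: every term is a true null; test b2's rate
        Y = rng.normal(0.0, 1.0, size=(reps, n))
        B = Y @ np.linalg.pinv(X).T
        resid = Y - B @ X.T
        s2 = np.sum(resid**2, axis=1) / dof
        se2 = np.sqrt(s2 * xtx_inv[2, 2])
        from scipy import stats
        pvals = 2 * stats.t.sf(np.abs(B[:, 2] / se2), dof)
        rate = float(np.mean(pvals < 0.05))
        assert 0.035 <= rate <= 0.065

    def test_coverage_of_confidence_intervals(self, study_design):
        """95% coefficient CIs cover the simulated truth at ~95%."""
        from scipy import stats
        X, _ = build_model_matrix(study_design)
        n, p = X.shape
        dof = n - p
        b_true = R.COEFFICIENTS["Cd"]
        sigma = 0.31
        rng = np.random.default_rng(99)
        reps = 400
        Y = (X @ b_true)[None, :] + rng.normal(0, sigma, size=(reps, n))
        pinv = np.linalg.pinv(X)
        B = Y @ pinv.T
        resid = Y - B @ X.T
        s = np.sqrt(np.sum(resid**2, axis=1) / dof)
        d = np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
        tq = stats.t.ppf(0.975, dof)
        half = tq * s[:, None] * d[None, :]
        cover = np.mean(np.abs(B - b_true[None, :]) <= half)
        assert 0.93 <= cover <= 0.97


class TestPredict:
    def test_published_cd_model_at_origin(self, published_fits):
        yhat, se = published_fits["Cd"].predict([0.0, 0.0, 0.0])
        assert yhat == pytest.approx(3.1)
        assert np.isnan(se)  # published fits carry no inferential state

    def test_zero_residual_gives_zero_se(self, study_design):
        X, _ = build_model_matrix(study_design)
        y = X @ R.COEFFICIENTS["Cr"]
        fit = fit_rsm(X, y, factors=R.FACTOR_NAMES)
        _, se = fit.predict([0.5, -0.5, 0.0])
        assert se == pytest.approx(0.0, abs=1e-8)

    def test_se_matches_parametric_bootstrap(self, study_design):
        """se(yhat) agrees with the spread of refitted predictions."""
        X, _ = build_model_matrix(study_design)
        b_true = R.COEFFICIENTS["Cd"]
        sigma = 0.31
        point = np.array([0.3, -0.4, 0.7])
        rng = np.random.default_rng(7)
        reps = 3000
        Y = (X @ b_true)[None, :] + rng.normal(0, sigma, size=(reps, len(X)))
        B = Y @ np.linalg.pinv(X).T
        x0 = quadratic_expand(point[None, :])[0]
        spread = np.std(B @ x0, ddof=1)
        fit = fit_rsm(X, Y[0], factors=R.FACTOR_NAMES)
        # analytic se uses the estimated sigma; compare on the true-sigma scale
        analytic = sigma * np.sqrt(x0 @ np.linalg.inv(X.T @ X) @ x0)
        assert spread == pytest.approx(analytic, rel=0.05)
        _, se_hat = fit.predict(point)
        assert se_hat == pytest.approx(analytic, rel=0.15)

    def test_outside_cube_warns(self, cd_fit):
        with pytest.warns(UserWarning, match="outside the coded cube"):
            cd_fit.predict([1.5, 0.0, 0.0])

    def test_dimension_mismatch(self, cd_fit):
        with pytest.raises(ValueError):
            cd_fit.predict([0.0, 0.0])


class TestSerialisation:
    def test_json_round_trip(self, cd_fit, tmp_path):
        path = tmp_path / "cd.json"
        cd_fit.save_json(path)
        back = RSMFit.load_json(path)
        np.testing.assert_allclose(back.coef, cd_fit.coef)
        np.testing.assert_allclose(back.xtx_inv, cd_fit.xtx_inv)
        assert back.dof == cd_fit.dof
        assert back.terms == cd_fit.terms
        assert back.predict([0.1, 0.2, 0.3]) == pytest.approx(
            cd_fit.predict([0.1, 0.2, 0.3]))

    def test_report_frame_shape(self, cd_fit):
        df = report_frame(cd_fit)
        assert list(df["symbol"]) == term_symbols(3)
        assert len(df) == 10


class TestNaturalUnits:
    def test_back_transform_reproduces_predictions(self, cd_fit, factors):
        """Natural-unit coefficients give the same surface as coded ones."""
        nat = natural_units_coefficients(cd_fit, factors)
        rng = np.random.default_rng(11)
        for _ in range(5):
            coded = rng.uniform(-1, 1, 3)
            conc = [f.midrange + c * f.halfwidth for f, c in zip(factors, coded)]
            y_coded, _ = cd_fit.predict(coded)
            c1, c2, c3 = conc
            y_nat = (nat["b0"] + nat["b1"] * c1 + nat["b2"] * c2 + nat["b3"] * c3
                     + nat["b12"] * c1 * c2 + nat["b13"] * c1 * c3
                     + nat["b23"] * c2 * c3
                     + nat["b11"] * c1**2 + nat["b22"] * c2**2 + nat["b33"] * c3**2)
            assert y_nat == pytest.approx(y_coded, rel=1e-9)
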