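"""Estimator contracts, checked against independent oracles.

The OLS oracle is an explicit normal-equations solve; CLAD is checked
against the generating parameters of simulated censored data and
against plain median regression when censoring is inactive.
"""

import numpy as np
import pytest

from headmap.estimators import (BoundsError, CLADRegressor,
                                ConfigurationError, DegenerateCensoringError,
                                FractionalLogitRegressor, GLMRegressor,
                                OLSRegressor, SingularDesignError, fit_clad,
                                fit_flogit, fit_glm, fit_ols)
from headmap.simulate import CohortSpec, simulate_true_mapping


@pytest.fixture(scope="module")
def xy():
    rng = np.random.default_rng(123)
    X = rng.normal(size=(300, 3))
    y = 0.4 + X @ np.array([0.25, -0.15, 0.05]) + 0.1 * rng.normal(size=300)
    return X, y


class TestOLS:
    def test_exact_fit_without_noise(self):
        X = np.arange(10, dtype=float)[:, None]
        y = 2.0 - 0.3 * X[:, 0]
        est = OLSRegressor().fit(X, y)
        assert est.intercept_ == pytest.approx(2.0, abs=1e-10)
        assert est.coef_[0] == pytest.approx(-0.3, abs=1e-10)
        assert np.allclose(est.predict(X), y)

    def test_matches_normal_equations_oracle(self, xy):
        X, y = xy
        Xc = np.column_stack([np.ones(len(y)), X])
        beta_oracle = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
        est = OLSRegressor().fit(X, y)
        assert est.intercept_ == pytest.approx(beta_oracle[0], abs=1e-8)
        np.testing.assert_allclose(est.coef_, beta_oracle[1:], atol=1e-8)

    def test_duplicated_column_is_singular(self, xy):
        X, y = xy
        Xdup = np.column_stack([X, X[:, 0]])
        with pytest.raises(SingularDesignError):
            OLSRegressor().fit(Xdup, y)

    def test_aic_matches_gaussian_closed_form(self, xy):
        X, y = xy
        fr = fit_ols(X, y)
        n, k = len(y), X.shape[1] + 1
        resid = y - fr.predictor.predict(X)
        rss = float(resid @ resid)
        loglik = -n / 2 * (np.log(2 * np.pi * rss / n) + 1)
        assert fr.aic == pytest.approx(2 * k - 2 * loglik, rel=1e-10)


class TestFractionalLogit:
    def test_transform_endpoints_and_midpoint(self):
        est = FractionalLogitRegressor(bounds=(-0.594, 1.0))
        assert est.transform_response(1.0) == pytest.approx(1.0)
        assert est.transform_response(-0.594) == pytest.approx(0.0)
        assert est.transform_response(0.203) == pytest.approx(0.5)

    def test_round_trip_is_affine_inverse(self):
        est = FractionalLogitRegressor(bounds=(-0.594, 1.0))
        y = np.linspace(-0.594, 1.0, 23)
        back = est.inverse_transform_response(est.transform_response(y))
        np.testing.assert_allclose(back, y, atol=1e-12)

    def test_out_of_bounds_response_rejected(self, xy):
        X, _ = xy
        y = np.full(X.shape[0], 0.5)
        y[0] = 1.2
        with pytest.raises(BoundsError):
            FractionalLogitRegressor(bounds=(0.0, 1.0)).fit(X, y)

    def test_equals_binomial_logit_glm_on_transformed_response(self, xy):
        X, y = xy
        y01 = (y - y.min()) / (y.max() - y.min())
        lo, hi = y.min(), y.max()
        fl = FractionalLogitRegressor(bounds=(lo, hi)).fit(X, y)
        glm = GLMRegressor(family="binomial", link="logit").fit(X, y01)
        np.testing.assert_allclose(fl.coef_, glm.coef_, atol=1e-8)
        assert fl.intercept_ == pytest.approx(glm.intercept_, abs=1e-8)

    def test_predictions_stay_in_bounds(self, xy):
        X, y = xy
        y01 = (y - y.min()) / (y.max() - y.min() + 1e-9)
        est = FractionalLogitRegressor(bounds=(0.0, 1.0)).fit(X, y01)
        preds = est.predict(10 * X)
        assert preds.min() >= 0.0 and preds.max() <= 1.0


class TestGLM:
    def test_gaussian_identity_equals_ols(self, xy):
        X, y = xy
        ols = OLSRegressor().fit(X, y)
        glm = GLMRegressor(family="gaussian", link="identity").fit(X, y)
        np.testing.assert_allclose(glm.coef_, ols.coef_, atol=1e-8)
        assert glm.intercept_ == pytest.approx(ols.intercept_, abs=1e-8)

    def test_unsupported_pair_rejected(self, xy):
        X, y = xy
        with pytest.raises(ConfigurationError):
            GLMRegressor(family="binomial", link="log").fit(X, y)

    def test_gamma_identity_nonpositive_shifted_response_flags(self, xy):
        X, y = xy
        est = GLMRegressor(family="gamma", link="identity", shift=0.0).fit(
            X, y - y.max())  # responses <= 0 after (explicit) zero shift
        assert est.converged_ is False
        assert "nonpositive" in est.notes_

    def test_gamma_shift_recorded_and_inverted(self, xy):
        X, y = xy
        est = GLMRegressor(family="gamma", link="log").fit(X, y - y.min())
        assert est.shift_ > 0
        if est.converged_:
            preds = est.predict(X)
            assert abs(preds.mean() - (y - y.min()).mean()) < 0.5


class TestCLAD:
    def test_equals_lad_when_censoring_inactive(self, xy):
        X, y = xy  # max(y) well below 10
        clad = CLADRegressor(censor_upper=10.0).fit(X, y)
        lad = CLADRegressor(censor_upper=np.inf).fit(X, y)
        np.testing.assert_allclose(clad.coef_, lad.coef_, atol=1e-8)
        assert clad.n_iter_ == 1 and clad.converged_

    def test_all_censored_is_degenerate(self):
        X = np.arange(5, dtype=float)[:, None]
        with pytest.raises(DegenerateCensoringError):
            CLADRegressor(censor_upper=1.0).fit(X, np.ones(5))

    def test_slope_recovery_under_censoring(self):
        tm = simulate_true_mapping(
            CohortSpec(n=5000, seed=17), beta={"hit6": -0.02}, constant=2.2,
            noise="laplace", noise_scale=0.1, censor_upper=1.0)
        X = np.array([[r.hit6] for r in tm.cohort], dtype=float)
        y = np.array([r.eq5d_utility for r in tm.cohort])
        assert (y == 1.0).mean() > 0.2  # ceiling genuinely binds
        fr = fit_clad(X, y)
        slope = fr.model.terms[0][1]
        assert slope == pytest.approx(-0.02, abs=0.003)
        assert fr.converged and fr.aic is None

    def test_bias_shrinks_with_sample_size(self):
        errs = {}
        for n in (500, 5000):
            tm = simulate_true_mapping(
                CohortSpec(n=n, seed=29), beta={"hit6": -0.02}, constant=1.9,
                noise="laplace", noise_scale=0.15, censor_upper=1.0)
            X = np.array([[r.hit6] for r in tm.cohort], dtype=float)
            y = np.array([r.eq5d_utility for r in tm.cohort])
            fr = fit_clad(X, y)
            errs[n] = abs(fr.model.terms[0][1] + 0.02)
        assert errs[5000] <= errs[500] + 5e-4

    def test_bootstrap_stderr_positive(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(40, 78, size=(400, 1))
        y = np.minimum(1.0, 1.9 - 0.02 * X[:, 0] + rng.laplace(0, 0.1, 400))
        fr = fit_clad(X, y, compute_stderr=True, n_bootstrap=30, seed=5)
        assert fr.stderr is not None and (fr.stderr > 0).all()

    def test_predictions_not_clipped_by_default(self):
        X = np.array([[40.0], [78.0]])
        est = CLADRegressor().fit(
            np.linspace(40, 78, 50)[:, None],
            np.minimum(1, 1.9 - 0.02 * np.linspace(40, 78, 50)))
        assert est.predict(X)[0] > 1.0  # mild severity extrapolates above 1
        est_clip = CLADRegressor(clip=(-0.594, 1.0)).fit(
            np.linspace(40, 78, 50)[:, None],
            np.minimum(1, 1.9 - 0.02 * np.linspace(40, 78, 50)))
        assert est_clip.predict(X).max() <= 1.0


def test_wrappers_return_fit_results(xy):
    X, y = xy
    for fr in (fit_ols(X, y), fit_flogit(X, (y - y.min()) / 2, bounds=(0, 1)),
               fit_glm(X, y)):
        assert fr.n_used == X.shape[0]
        assert fr.aic is not None
        assert len(fr.model.terms) == X.shape[1]
    fr = fit_clad(X, y, censor_upper=10.0)
    assert fr.aic is None and fr.iterations >= 1
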