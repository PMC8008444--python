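"""Penalized BCCG fitting: recovery, calibration, model selection."""

import numpy as np
import pandas as pd
import pytest

from growthdesign import (
    BCCGParams,
    FitConfig,
    FitError,
    MomentCurveSet,
    SamplingScheme,
    fit_bccg,
    information_criteria,
    mu_se_z_curve,
    random_bccg,
    residual_zscores,
    se_z_normal,
    select_xi,
    simulate_dataset,
)
from growthdesign.fitting import _zscores, refit_fixed


def make_dataset(mu_f, sigma_f, nu_f, n, seed, age_min=0.0, age_max=20.0):
    model = MomentCurveSet(
        age_min=age_min, age_max=age_max,
        mu_curve=mu_f, sigma_curve=sigma_f, nu_curve=nu_f,
    )
    scheme = SamplingScheme(lambda_age=1.0, age_min=age_min, age_max=age_max, n=n)
    return simulate_dataset(model, scheme, np.random.default_rng(seed))


class TestParameterRecovery:
    def test_constant_parameters(self):
        data = make_dataset(
            lambda t: np.full_like(t, 50.0),
            lambda t: np.full_like(t, 0.1),
            lambda t: np.full_like(t, 1.0),
            n=5000, seed=2,
        )
        cfg = FitConfig(
            mu_curve_class="constant", sigma_curve_class="constant",
            nu_curve_class="constant", xi=1.0,
        )
        fit = fit_bccg(data, cfg)
        mu, sigma, nu = fit.moments([10.0])
        assert mu[0] == pytest.approx(50.0, abs=0.5)
        assert sigma[0] == pytest.approx(0.1, abs=0.005)
        assert nu[0] == pytest.approx(1.0, abs=0.5)

    def test_fixture_centile_recovery(self, height_model, height_fit):
        """Fitted median curve within |z| < 0.05 of truth over 2-18 y,
        < 0.12 near the edges."""
        grid = np.arange(2.0, 18.01, 0.1)
        mu_t, _, _ = height_model.moments(grid)
        mu_f, s_f, nu_f = height_fit.moments(grid)
        dz = _zscores(mu_t, mu_f, s_f, nu_f)
        assert np.median(np.abs(dz)) < 0.05
        edge = np.concatenate([np.arange(0.2, 2.0, 0.1), np.arange(18.0, 19.9, 0.1)])
        mu_t, _, _ = height_model.moments(edge)
        mu_f, s_f, nu_f = height_fit.moments(edge)
        assert np.median(np.abs(_zscores(mu_t, mu_f, s_f, nu_f))) < 0.12

    def test_residual_calibration_on_training_data(self, height_fit, height_dataset):
        z = residual_zscores(height_fit, height_dataset)
        assert abs(z.mean()) < 0.03
        assert z.std() == pytest.approx(1.0, abs=0.03)

    def test_residuals_on_data_from_fitted_model(self, height_fit):
        from scipy import stats

        curves = height_fit.to_moment_curves()
        scheme = SamplingScheme(
            lambda_age=0.8, age_min=curves.age_min + 0.01,
            age_max=curves.age_max - 0.01, n=4000,
        )
        fresh = simulate_dataset(curves, scheme, np.random.default_rng(9))
        z = residual_zscores(height_fit, fresh)
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_median_scores_to_zero(self, height_fit):
        ages = np.array([1.0, 5.0, 10.0, 15.0])
        mu, _, _ = height_fit.moments(ages)
        z = residual_zscores(height_fit, pd.DataFrame({"age": ages, "y": mu}))
        assert np.allclose(z, 0.0, atol=1e-8)

    def test_likelihood_ascent_at_fixed_smoothing(self, height_dataset):
        cfg = FitConfig(
            xi=0.5, nu_curve_class="linear", fixed_lambdas=(10.0, 10.0, None)
        )
        fit = fit_bccg(height_dataset, cfg)
        h = np.asarray(fit.loglik_history)
        assert np.all(np.diff(h) >= -1e-6 * np.abs(h[:-1]))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_bccg(pd.DataFrame({"age": [1.0] * 10, "y": [5.0] * 10}))
        data = make_dataset(
            lambda t: np.full_like(t, 50.0),
            lambda t: np.full_like(t, 0.1),
            lambda t: np.ones_like(t),
            n=100, seed=3,
        )
        bad = data.copy()
        bad.loc[0, "y"] = -1.0
        with pytest.raises(ValueError):
            fit_bccg(bad)

    def test_nonconvergence_raises(self, height_dataset):
        with pytest.raises(FitError):
            fit_bccg(
                height_dataset,
                FitConfig(xi=0.5, nu_curve_class="linear", max_iter=1, tol=1e-14),
            )


class TestXiSelection:
    def test_sqrt_age_truth(self):
        data = make_dataset(
            lambda t: 60.0 + 20.0 * np.sqrt(t),
            lambda t: np.full_like(t, 0.05),
            lambda t: np.ones_like(t),
            n=4000, seed=4,
        )
        xi = select_xi(data, FitConfig(xi=1.0, nu_curve_class="constant"))
        assert 0.4 <= xi <= 0.6

    def test_linear_age_truth(self):
        data = make_dataset(
            lambda t: 50.0 + 5.0 * t,
            lambda t: np.full_like(t, 0.05),
            lambda t: np.ones_like(t),
            n=4000, seed=5,
        )
        xi = select_xi(data, FitConfig(xi=1.0, nu_curve_class="constant"))
        assert 0.85 <= xi <= 1.0

    def test_never_worse_than_untransformed(self):
        data = make_dataset(
            lambda t: 60.0 + 20.0 * np.sqrt(t),
            lambda t: np.full_like(t, 0.05),
            lambda t: np.ones_like(t),
            n=3000, seed=6,
        )
        cfg = FitConfig(nu_curve_class="constant", xi=1.0)
        xi = select_xi(data, cfg)
        fit_hat = fit_bccg(data, FitConfig(nu_curve_class="constant", xi=xi))
        fit_one = fit_bccg(data, cfg)
        assert (
            information_criteria(fit_hat, 3.0)["gaic_k"]
            <= information_criteria(fit_one, 3.0)["gaic_k"] + 1e-6
        )


class TestInformationCriteria:
    def test_gaic_logn_equals_bic(self, single_age_fit):
        ic = information_criteria(single_age_fit, k=np.log(single_age_fit.n_obs))
        assert ic["gaic_k"] == pytest.approx(ic["bic"], rel=1e-12)

    def test_gaic3_below_bic_for_large_n(self, height_fit):
        ic = information_criteria(height_fit, k=3.0)
        assert ic["gaic_k"] < ic["bic"]

    def test_selection_never_worse_than_forced_constant(self):
        data = make_dataset(
            lambda t: np.full_like(t, 50.0),
            lambda t: np.full_like(t, 0.1),
            lambda t: np.ones_like(t),
            n=1000, seed=7,
        )
        forced = fit_bccg(
            data,
            FitConfig(
                mu_curve_class="constant", sigma_curve_class="constant",
                nu_curve_class="constant", xi=1.0,
            ),
        )
        selected = fit_bccg(
            data,
            FitConfig(
                mu_curve_class="constant", sigma_curve_class="constant",
                nu_curve_class="select", xi=1.0,
            ),
        )
        assert (
            information_criteria(selected, 3.0)["gaic_k"]
            <= information_criteria(forced, 3.0)["gaic_k"] + 1e-6
        )


class TestMuSEZCurve:
    def test_single_age_group_normal_theory_limit(self, single_age_fit):
        se = mu_se_z_curve(single_age_fit, [8.0])
        assert se[0] == pytest.approx(se_z_normal(0.0, 1000), rel=0.15)

    def test_positive_everywhere(self, height_fit):
        grid = np.arange(0.5, 19.5, 0.1)
        assert np.all(mu_se_z_curve(height_fit, grid) > 0)

    def test_quarter_sample_doubles_se(self, height_model, height_fit):
        """At fixed design and model complexity, dividing n by 4 roughly
        doubles the median SE_z (multiplier in [1.7, 2.2])."""
        scheme = SamplingScheme(lambda_age=0.5, age_min=0.0, age_max=20.0, n=1750)
        small = simulate_dataset(height_model, scheme, np.random.default_rng(8))
        ratio = 1750 / height_fit.n_obs
        cfg = FitConfig(
            xi=0.5, nu_curve_class="linear",
            fixed_lambdas=(
                height_fit.terms["mu"].lam * ratio,
                height_fit.terms["sigma"].lam * ratio,
                None,
            ),
        )
        fit_small = fit_bccg(small, cfg)
        grid = np.arange(2.0, 18.01, 0.1)
        m = np.exp(
            np.mean(np.log(mu_se_z_curve(fit_small, grid)))
            - np.mean(np.log(mu_se_z_curve(height_fit, grid)))
        )
        assert 1.7 <= m <= 2.2

    def test_grid_outside_range_rejected(self, height_fit):
        with pytest.raises(ValueError):
            mu_se_z_curve(height_fit, [25.0])


class TestRefitFixed:
    def test_refit_reproduces_on_same_data(self, height_fit, height_dataset):
        refit = refit_fixed(height_fit, height_dataset)
        grid = np.arange(1.0, 19.01, 0.5)
        mu0, _, _ = height_fit.moments(grid)
        mu1, _, _ = refit.moments(grid)
        assert np.allclose(mu0, mu1, rtol=1e-3)


class TestBicGridSmoothing:
    def test_bic_grid_never_worse_than_ml(self, height_dataset):
        ml = fit_bccg(
            height_dataset, FitConfig(xi=0.5, nu_curve_class="constant")
        )
        refined = fit_bccg(
            height_dataset,
            FitConfig(
                xi=0.5, nu_curve_class="constant",
                smoothing_selection="bic-grid",
            ),
        )
        n = ml.n_obs
        assert (
            information_criteria(refined, np.log(n))["gaic_k"]
            <= information_criteria(ml, np.log(n))["gaic_k"] + 1e-6
        )
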