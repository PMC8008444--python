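"""Design meta-regression calculators and their refitting."""

import math

import numpy as np
import pytest

from growthdesign import (
    DEFAULT_DESIGN_MODEL,
    DesignModel,
    FitConfig,
    SamplingScheme,
    bootstrap_se_curves,
    centile_ci,
    design_table,
    fit_bccg,
    fit_design_model,
    make_fixture,
    optimal_lambda,
    predict_se_z,
    required_n,
    simulate_dataset,
)
from growthdesign.bootstrap import SEZCurve

M = DEFAULT_DESIGN_MODEL


def synthetic_curve(lam, zs, noise_sd=0.0, rng=None):
    """SE_z surface generated exactly from the default design model."""
    ages = np.arange(0.0, 20.01, 0.1)
    a = ages - M.age_centre
    se = np.empty((len(ages), len(zs)))
    for j, z in enumerate(zs):
        zt = math.log(1 + z**2 / 2)
        log_se = (
            M.b0 + M.b_z * zt + M.b_lambda * lam
            + a * (M.b_age + M.b_age_z * zt + M.b_age_lambda * lam)
        )
        se[:, j] = np.exp(log_se)
    if noise_sd > 0:
        se *= np.exp(rng.normal(0.0, noise_sd, size=se.shape))
    return SEZCurve(ages=ages, centile_zs=np.asarray(zs, float), se_z=se,
                    n_replicates=500)


class TestOptimalLambda:
    @pytest.mark.parametrize(
        "z,expected",
        [(0.0, 0.38), (0.67, 0.45), (1.33, 0.60), (2.0, 0.76),
         (2.67, 0.90), (1.88, 0.73)],
    )
    def test_published_values(self, z, expected):
        assert round(optimal_lambda(M, z), 2) == expected

    def test_even_in_z(self):
        assert optimal_lambda(M, 2.0) == optimal_lambda(M, -2.0)

    def test_strictly_increasing_in_abs_z(self):
        lams = [optimal_lambda(M, z) for z in (0.0, 0.67, 1.33, 2.0, 2.67)]
        assert np.all(np.diff(lams) > 0)

    def test_infeasible_raises(self):
        with pytest.raises(ValueError):
            optimal_lambda(M, 4.0)


class TestPredictSEZ:
    @pytest.mark.parametrize(
        "z,n,expected",
        [(0.0, 6878, 0.041), (2.0, 6878, 0.066), (1.88, 6878, 0.064),
         (2.0, 7200, 0.065), (2.0, 93_000, 0.016)],
    )
    def test_published_values(self, z, n, expected):
        lam = optimal_lambda(M, z)
        assert round(predict_se_z(M, z, lam, n), 3) == expected

    def test_monotone_in_z_and_n(self):
        se_z = [predict_se_z(M, z, 0.5, 6878) for z in (0.0, 1.0, 2.0)]
        assert np.all(np.diff(se_z) > 0)
        se_n = [predict_se_z(M, 2.0, 0.5, n) for n in (2000, 7000, 93_000)]
        assert np.all(np.diff(se_n) < 0)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            predict_se_z(M, 0.0, 0.0, 1000)
        with pytest.raises(ValueError):
            predict_se_z(M, 0.0, 0.5, 0)


class TestRequiredN:
    def test_healy_97th_centile_example(self):
        # 97th centile (z=1.88) to SE_z = 0.053 needs ~9910 (within ~2%:
        # printed-coefficient rounding)
        n = required_n(M, 1.88, 0.053)
        assert n == pytest.approx(9910, rel=0.02)

    def test_fixed_point_at_reference(self):
        target = predict_se_z(M, 0.0, optimal_lambda(M, 0.0), M.n_ref)
        assert required_n(M, 0.0, target) == M.n_ref

    def test_halving_target_scales_by_2_pow_exponent(self):
        n1 = required_n(M, 2.0, 0.06)
        n2 = required_n(M, 2.0, 0.03)
        assert n2 / n1 == pytest.approx(2**1.85, rel=0.001)

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            required_n(M, 0.0, -0.01)


class TestCentileCI:
    def test_median_published_interval(self):
        lo, hi = centile_ci(0.0, 0.041)
        assert (round(lo, 1), round(hi, 1)) == (46.7, 53.3)

    def test_2nd_centile_published_intervals(self):
        se = predict_se_z(M, 2.0, optimal_lambda(M, 2.0), 7200)
        lo, hi = centile_ci(-2.0, se)
        assert (round(lo, 1), round(hi, 1)) == (1.7, 3.1)
        se = predict_se_z(M, 2.0, optimal_lambda(M, 2.0), 93_000)
        lo, hi = centile_ci(-2.0, se)
        assert (round(lo, 1), round(hi, 1)) == (2.1, 2.5)

    def test_zero_width(self):
        lo, hi = centile_ci(1.0, 0.0)
        assert lo == pytest.approx(hi)
        assert lo == pytest.approx(84.1, abs=0.05)


class TestDesignTable:
    def test_published_rows(self):
        tab = design_table(M, [2000, 7200, 93_000])
        r93 = tab[tab.n == 93_000].iloc[0]
        assert round(r93["se_z_2.27501"], 3) == 0.016
        assert round(r93["ci_lo_2.27501"], 1) == 2.1
        assert round(r93["ci_hi_2.27501"], 1) == 2.5
        r2000 = tab[tab.n == 2000].iloc[0]
        assert round(r2000["se_z_50"], 2) == 0.08

    def test_upper_centile_by_symmetry(self):
        lam = optimal_lambda(M, 2.0)
        se = predict_se_z(M, 2.0, lam, 7200)
        lo2, hi2 = centile_ci(-2.0, se)
        lo98, hi98 = centile_ci(2.0, se)
        assert lo98 == pytest.approx(100.0 - hi2, abs=1e-9)
        assert hi98 == pytest.approx(100.0 - lo2, abs=1e-9)

    def test_ci_width_shrinks_with_n(self):
        tab = design_table(M, [2000, 7200, 93_000])
        widths = tab["ci_hi_50"] - tab["ci_lo_50"]
        assert np.all(np.diff(widths.to_numpy()) < 0)


class TestFitDesignModel:
    def test_exact_recovery_from_noiseless_surfaces(self):
        curves = [
            (synthetic_curve(lam, [0.0, 0.67, 1.33, 2.0, 2.67]), lam)
            for lam in (0.31, 0.5, 0.75, 1.0)
        ]
        refit = fit_design_model(curves)
        for attr in ("b0", "b_z", "b_lambda", "b_age", "b_age_z", "b_age_lambda"):
            assert getattr(refit, attr) == pytest.approx(
                getattr(M, attr), abs=1e-10
            )

    def test_noisy_recovery_within_3_se(self):
        rng = np.random.default_rng(12)
        curves = [
            (synthetic_curve(lam, [0.0, 0.67, 1.33, 2.0, 2.67], 0.1, rng), lam)
            for lam in (0.31, 0.5, 0.75, 1.0)
        ]
        refit = fit_design_model(curves)
        # OLS oracle: rebuild the design matrix to get coefficient SEs
        X_rows, y_rows = [], []
        for curve, lam in curves:
            sel = (curve.ages >= 2.0) & (curve.ages <= 18.0)
            a = curve.ages[sel] - 10.0
            for j, z in enumerate(curve.centile_zs):
                zt = math.log(1 + z**2 / 2)
                X_rows.append(np.column_stack([
                    np.ones_like(a), np.full_like(a, zt), np.full_like(a, lam),
                    a, a * zt, a * lam,
                ]))
                y_rows.append(np.log(curve.se_z[sel, j]))
        X = np.vstack(X_rows)
        y = np.concatenate(y_rows)
        coef, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma2 = rss[0] / (len(y) - 6)
        se = np.sqrt(sigma2 * np.diag(np.linalg.inv(X.T @ X)))
        truth = [M.b0, M.b_z, M.b_lambda, M.b_age, M.b_age_z, M.b_age_lambda]
        got = [refit.b0, refit.b_z, refit.b_lambda, refit.b_age,
               refit.b_age_z, refit.b_age_lambda]
        for g, t, s in zip(got, truth, se):
            assert abs(g - t) <= 3 * s

    def test_requires_two_lambdas_and_two_zs(self):
        c = synthetic_curve(0.5, [0.0, 2.0])
        with pytest.raises(ValueError):
            fit_design_model([(c, 0.5)])
        c1 = synthetic_curve(0.5, [0.0])
        c2 = synthetic_curve(1.0, [0.0])
        with pytest.raises(ValueError):
            fit_design_model([(c1, 0.5), (c2, 1.0)])

    def test_z_term_dominates_variance_in_pipeline_run(self):
        """In a scaled-down full pipeline (simulate, fit, bootstrap at two
        compositions), the centile term log(1+z^2/2) explains by far the
        largest share of the meta-regression model sum of squares."""
        model = make_fixture("weight")
        rng = np.random.default_rng(31)
        curves = []
        for lam in (0.4, 1.0):
            scheme = SamplingScheme(lambda_age=lam, age_min=0.0, age_max=20.0,
                                    n=2000)
            data = simulate_dataset(model, scheme, rng)
            fit = fit_bccg(data, FitConfig(xi=0.7, nu_curve_class="linear"))
            curves.append((bootstrap_se_curves(
                data, fit, centile_zs=[-2.0, -0.67, 0.0, 0.67, 2.0], B=60,
                rng=rng,
            ), lam))
        # sequential sums of squares, adding terms in a fixed order
        X_rows, y_rows = [], []
        for curve, lam in curves:
            sel = (curve.ages >= 2.0) & (curve.ages <= 18.0)
            a = curve.ages[sel] - 10.0
            for j, z in enumerate(curve.centile_zs):
                zt = math.log(1 + z**2 / 2)
                X_rows.append(np.column_stack([
                    np.ones_like(a), a, np.full_like(a, zt),
                    np.full_like(a, lam), a * zt, a * lam,
                ]))
                y_rows.append(np.log(curve.se_z[sel, j]))
        X = np.vstack(X_rows)
        y = np.concatenate(y_rows)

        def rss(k):
            beta, *_ = np.linalg.lstsq(X[:, :k], y, rcond=None)
            return float(np.sum((y - X[:, :k] @ beta) ** 2))

        seq = [rss(k) for k in range(1, 7)]
        drops = -np.diff(seq)  # SS explained by age, z, lambda, age:z, age:lam
        assert drops[1] == max(drops)
        assert drops[1] > 2 * sorted(drops)[-2]
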