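"""Two-level analyses: ICC, latent covariate regression, correlations, mediation."""
import numpy as np
import pandas as pd
import pytest

from emadiff import multilevel as ml


def _balanced_null(rng, J=300, n=15, tau2=0.06, sigma2=0.09, mean=1.425):
    u = rng.normal(0, np.sqrt(tau2), J)
    y = mean + u[:, None] + rng.normal(0, np.sqrt(sigma2), (J, n))
    return y.ravel(), np.repeat(np.arange(J), n)


class TestICC:
    @pytest.mark.parametrize(
        "tau2,sigma2,expected",
        [(0.058, 0.084, 0.408), (0.193, 0.425, 0.312), (0.062, 0.096, 0.392)],
    )
    def test_printed_variance_components(self, tau2, sigma2, expected):
        assert round(ml.icc(tau2, sigma2), 3) == expected

    def test_degenerate_components(self):
        assert ml.icc(0.0, 0.5) == 0.0
        assert ml.icc(0.5, 0.0) == 1.0
        with pytest.raises(ValueError):
            ml.icc(0.0, 0.0)
        with pytest.raises(ValueError):
            ml.icc(-0.1, 0.5)


class TestNullModel:
    def test_component_recovery(self):
        y, g = _balanced_null(np.random.default_rng(42), J=500, n=20)
        vc = ml.fit_null_model(y, g)
        assert vc.tau2 == pytest.approx(0.06, rel=0.15)
        assert vc.sigma2 == pytest.approx(0.09, rel=0.15)
        assert vc.icc == pytest.approx(ml.icc(vc.tau2, vc.sigma2))
        assert vc.se_icc > 0 and vc.se_tau2 > 0

    def test_reml_matches_anova_closed_form_when_balanced(self):
        # independent oracle: one-way ANOVA moment estimators
        y, g = _balanced_null(np.random.default_rng(7), J=120, n=8)
        Y = y.reshape(120, 8)
        msb = 8 * np.var(Y.mean(axis=1), ddof=1)
        msw = float(np.mean(np.var(Y, axis=1, ddof=1)))
        vc = ml.fit_null_model(y, g, method="reml")
        assert vc.sigma2 == pytest.approx(msw, abs=1e-6)
        assert vc.tau2 == pytest.approx((msb - msw) / 8, abs=1e-6)

    def test_matches_statsmodels_mixedlm(self):
        # independent ML route through statsmodels
        import statsmodels.formula.api as smf

        y, g = _balanced_null(np.random.default_rng(3), J=80, n=6)
        df = pd.DataFrame({"y": y, "g": g})
        res = smf.mixedlm("y ~ 1", df, groups=df["g"]).fit(reml=False)
        vc = ml.fit_null_model(y, g, method="ml")
        assert vc.tau2 == pytest.approx(float(res.cov_re.iloc[0, 0]), rel=1e-3)
        assert vc.sigma2 == pytest.approx(float(res.scale), rel=1e-3)
        assert vc.grand_mean == pytest.approx(float(res.params["Intercept"]), abs=1e-4)

    def test_equal_person_means_give_near_zero_icc(self):
        rng = np.random.default_rng(1)
        J, n = 100, 10
        y = rng.normal(0, 1, (J, n))
        y = y - y.mean(axis=1, keepdims=True) + 5.0   # all person means equal
        vc = ml.fit_null_model(y.ravel(), np.repeat(np.arange(J), n))
        assert vc.icc < 0.01

    def test_single_occasion_everywhere_unidentified(self):
        with pytest.raises(ValueError, match="single occasion"):
            ml.fit_null_model([1.0, 2.0, 3.0], ["a", "b", "c"])


def _latent_regression_data(rng, J=500, n=20, bw=(-0.7, 0.6), bb=(-0.6, 0.75)):
    xb, zb = rng.normal(0, 1, (2, J))
    xw, zw = rng.normal(0, 1, (2, J, n))
    ew = rng.normal(0, np.sqrt(max(1 - bw[0] ** 2 - bw[1] ** 2, 0.02)), (J, n))
    eb = rng.normal(0, np.sqrt(max(1 - bb[0] ** 2 - bb[1] ** 2, 0.02)), J)
    y = (bb[0] * xb + bb[1] * zb + eb)[:, None] + bw[0] * xw + bw[1] * zw + ew
    g = np.repeat(np.arange(J), n)
    return y.ravel(), (xb[:, None] + xw).ravel(), (zb[:, None] + zw).ravel(), g


class TestLatentRegression:
    def test_standardized_coefficient_recovery(self):
        y, x, z, g = _latent_regression_data(np.random.default_rng(42))
        fit = ml.fit_latent_regression(y, x, z, g)
        assert fit.beta_within_std["x"] == pytest.approx(-0.7, abs=0.05)
        assert fit.beta_within_std["z"] == pytest.approx(0.6, abs=0.05)
        assert fit.beta_between_std["x"] == pytest.approx(-0.6, abs=0.05)
        assert fit.beta_between_std["z"] == pytest.approx(0.75, abs=0.05)
        for r2 in (fit.r2_within, fit.r2_between):
            assert 0.0 <= r2 <= 1.0

    def test_identical_predictors_raise_collinearity(self):
        y, x, _, g = _latent_regression_data(np.random.default_rng(0), J=60, n=5)
        with pytest.raises(ValueError, match="collinear"):
            ml.fit_latent_regression(y, x, x, g)

    def test_latent_between_beats_manifest_mean_regression(self):
        # small clusters with unreliable person means: the manifest-mean
        # between slope shrinks toward the within slope; the latent one
        # should stay near the truth
        rng = np.random.default_rng(12)
        J, n = 500, 5
        beta_b, beta_w = 1.0, 0.0
        xb = rng.normal(0, 0.5, J)                      # reliability ~ 0.56
        xw = rng.normal(0, 1.0, (J, n))
        y = beta_b * xb[:, None] + beta_w * xw + rng.normal(0, 0.5, (J, n))
        x = xb[:, None] + xw
        g = np.repeat(np.arange(J), n)
        xbar = x.mean(axis=1)
        manifest_b = np.polyfit(xbar, y.mean(axis=1), 1)[0]
        manifest_bias = abs(manifest_b - beta_b)
        assert manifest_bias > 0.25  # the construction really biases it
        z = rng.normal(0, 1, (J, n)) + rng.normal(0, 0.5, J)[:, None]
        fit = ml.fit_latent_regression(y.ravel(), x.ravel(), z.ravel(), g)
        latent_bias = abs(fit.beta_between["x"] - beta_b)
        assert latent_bias < manifest_bias / 3


class TestCorrelations:
    def test_duplicated_variable_correlates_perfectly(self):
        rng = np.random.default_rng(2)
        J, n = 80, 6
        a = (rng.normal(0, 1, J)[:, None] + rng.normal(0, 1, (J, n))).ravel()
        df = pd.DataFrame({"a": a, "b": a, "g": np.repeat(np.arange(J), n)})
        pair = ml.multilevel_correlations(df, ["a", "b"], "g")
        assert pair.within.loc["a", "b"] == pytest.approx(1.0, abs=1e-4)
        assert pair.between.loc["a", "b"] == pytest.approx(1.0, abs=1e-3)

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(6)
        J, n = 500, 10
        g = np.repeat(np.arange(J), n)
        df = pd.DataFrame({
            "a": (rng.normal(0, 1, J)[:, None] + rng.normal(0, 1, (J, n))).ravel(),
            "b": (rng.normal(0, 1, J)[:, None] + rng.normal(0, 1, (J, n))).ravel(),
            "g": g,
        })
        pair = ml.multilevel_correlations(df, ["a", "b"], "g")
        assert abs(pair.within.loc["a", "b"]) < 0.05
        assert abs(pair.between.loc["a", "b"]) < 0.05

    def test_recovery_at_reported_magnitudes(self):
        # within r = 0.39, between r = 0.66
        rng = np.random.default_rng(9)
        J, n = 500, 10
        g = np.repeat(np.arange(J), n)
        cb = np.linalg.cholesky([[1, 0.66], [0.66, 1]])
        cw = np.linalg.cholesky([[1, 0.39], [0.39, 1]])
        b = rng.normal(0, 1, (J, 2)) @ cb.T
        w = rng.normal(0, 1, (J * n, 2)) @ cw.T
        df = pd.DataFrame({
            "a": b[np.repeat(np.arange(J), n), 0] + w[:, 0],
            "b": b[np.repeat(np.arange(J), n), 1] + w[:, 1],
            "g": g,
        })
        pair = ml.multilevel_correlations(df, ["a", "b"], "g")
        assert pair.within.loc["a", "b"] == pytest.approx(0.39, abs=0.05)
        assert pair.between.loc["a", "b"] == pytest.approx(0.66, abs=0.05)
        assert pair.fisher_z_within.loc["a", "b"] == pytest.approx(
            np.arctanh(pair.within.loc["a", "b"])
        )

    def test_fisher_z_of_zero(self):
        assert np.arctanh(0.0) == 0.0


class TestDependentCorrelations:
    def _corr_data(self, rng, r1, r2, J=500, n=8):
        g = np.repeat(np.arange(J), n)
        # x correlates r1 with u and r2 with v at the within level
        x = rng.normal(0, 1, J * n)
        u = r1 * x + np.sqrt(1 - r1**2) * rng.normal(0, 1, J * n)
        v = r2 * x + np.sqrt(1 - r2**2) * rng.normal(0, 1, J * n)
        base = rng.normal(0, 0.6, J)[g]
        return pd.DataFrame({"x": x + base, "u": u + base * 0.5,
                             "v": v + rng.normal(0, 0.6, J)[g], "g": g})

    def test_same_entry_twice_gives_p_one(self):
        df = self._corr_data(np.random.default_rng(3), 0.4, 0.2, J=120)
        res = ml.compare_dependent_correlations(
            df, "g", ("x", "u"), ("u", "x"), "within", n_boot=199, seed=1
        )
        assert res.z_diff == 0.0 and res.pvalue == pytest.approx(1.0)

    def test_power_at_constructed_gap(self):
        df = self._corr_data(np.random.default_rng(4), 0.6, 0.0)
        res = ml.compare_dependent_correlations(
            df, "g", ("x", "u"), ("x", "v"), "within", n_boot=999, seed=2
        )
        assert res.pvalue < 0.001
        assert res.r_a > res.r_b

    def test_few_persons_warns(self):
        df = self._corr_data(np.random.default_rng(5), 0.5, 0.1, J=30)
        with pytest.warns(UserWarning, match="50 persons"):
            ml.compare_dependent_correlations(
                df, "g", ("x", "u"), ("x", "v"), "within", n_boot=99, seed=3
            )


def _mediation_111(rng, J=300, n=12, a1=-0.25, b1=-0.2, a2=-0.13, b2=0.19,
                   direct=0.0):
    g = np.repeat(np.arange(J), n)
    work = (rng.random((J, n)) < 0.3).astype(float)
    m1 = a1 * work + rng.normal(0, 1, (J, n)) + rng.normal(0, 0.5, J)[:, None]
    m2 = a2 * work + rng.normal(0, 1, (J, n)) + rng.normal(0, 0.5, J)[:, None]
    y = (b1 * m1 + b2 * m2 + direct * work
         + rng.normal(0, 0.6, (J, n)) + rng.normal(0, 0.4, J)[:, None])
    return pd.DataFrame({"work": work.ravel(), "m1": m1.ravel(),
                         "m2": m2.ravel(), "y": y.ravel(), "g": g})


class TestMediation:
    def test_total_equals_direct_plus_indirect(self):
        df = _mediation_111(np.random.default_rng(7))
        med = ml.fit_mediation(df, "work", ("m1", "m2"), "y", "g",
                               predictor_level="within", seed=1, n_mc=20_000)
        assert med.total == pytest.approx(
            med.direct + sum(med.indirect.values()), abs=1e-10
        )
        assert med.binary_predictor

    def test_opposite_sign_indirects_recovered(self):
        df = _mediation_111(np.random.default_rng(8), J=400)
        med = ml.fit_mediation(df, "work", ("m1", "m2"), "y", "g",
                               predictor_level="within", seed=1, n_mc=50_000)
        assert med.indirect["m1"] == pytest.approx(0.05, abs=0.02)
        assert med.indirect["m2"] == pytest.approx(-0.0247, abs=0.02)
        lo1, hi1 = med.indirect_ci["m1"]
        lo2, hi2 = med.indirect_ci["m2"]
        assert lo1 > 0 and hi2 < 0

    def test_null_predictor_intervals_cover_zero(self):
        df = _mediation_111(np.random.default_rng(9), a1=0.0, a2=0.0)
        med = ml.fit_mediation(df, "work", ("m1", "m2"), "y", "g",
                               predictor_level="within", seed=2, n_mc=50_000)
        for lo, hi in med.indirect_ci.values():
            assert lo < 0 < hi

    def test_between_level_predictor(self):
        rng = np.random.default_rng(10)
        J, n = 250, 8
        g = np.repeat(np.arange(J), n)
        neuro = rng.normal(0, 1, J)
        m1b = -0.3 * neuro + rng.normal(0, 1, J)
        m2b = -0.2 * neuro + rng.normal(0, 1, J)
        y = (-0.5 * m1b + 0.6 * m2b + rng.normal(0, 0.5, J))[g] + rng.normal(0, 1, J * n)
        df = pd.DataFrame({
            "neuro": neuro[g],
            "m1": m1b[g] + rng.normal(0, 1, J * n),
            "m2": m2b[g] + rng.normal(0, 1, J * n),
            "y": y, "g": g,
        })
        med = ml.fit_mediation(df, "neuro", ("m1", "m2"), "y", "g",
                               predictor_level="between", seed=3, n_mc=20_000)
        assert not med.binary_predictor
        assert med.a_paths["m1"] == pytest.approx(-0.3, abs=0.12)
        assert med.total == pytest.approx(
            med.direct + sum(med.indirect.values()), abs=1e-10
        )

    def test_constant_predictor_rejected(self):
        df = _mediation_111(np.random.default_rng(1), J=40, n=5)
        df["work"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            ml.fit_mediation(df, "work", ("m1", "m2"), "y", "g")

    def test_level_mismatch_rejected(self):
        df = _mediation_111(np.random.default_rng(1), J=40, n=5)
        with pytest.raises(ValueError, match="declared person-level"):
            ml.fit_mediation(df, "work", ("m1", "m2"), "y", "g",
                             predictor_level="between")
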