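"""The mixed-model engine against OLS, closed-form, dense-oracle and
statsmodels cross-checks."""

import math

import numpy as np
import pandas as pd
import pytest

from treenbh.lmm import (
    ModelFit,
    ModelSpec,
    RandomTerm,
    StandardizationRecord,
    akaike_compare,
    fit_lmm,
    loglik_bruteforce,
    lr_test,
    predict_fixed,
    r2_nakagawa,
    standardize,
    vif,
)


def _crossed_data(
    n=400, n_f1=10, n_f2=6, beta=(1.0, 0.7), sd1=0.5, sd2=0.3, sd_e=0.4, seed=0,
    extra_cov=False,
):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "x": rng.normal(size=n),
            "f1": rng.integers(0, n_f1, n).astype(str),
            "f2": rng.integers(0, n_f2, n).astype(str),
        }
    )
    u1 = dict(zip(map(str, range(n_f1)), rng.normal(0, sd1, n_f1)))
    u2 = dict(zip(map(str, range(n_f2)), rng.normal(0, sd2, n_f2)))
    df["y"] = (
        beta[0]
        + beta[1] * df.x
        + df.f1.map(u1)
        + df.f2.map(u2)
        + rng.normal(0, sd_e, n)
    )
    if extra_cov:
        df["z"] = rng.normal(size=n)
    return df


class TestStandardize:
    def test_unit_sd_unchanged(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        x = x / x.std(ddof=1)
        df = pd.DataFrame({"a": x})
        out, rec = standardize(df, ["a"])
        assert np.allclose(out["a"], x)
        assert rec.divisors["a"] == pytest.approx(1.0)

    def test_divides_by_sample_sd(self):
        df = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        out, rec = standardize(df, ["a"])
        assert rec.divisors["a"] == pytest.approx(2.0)  # sd(2,4,6) = 2
        assert np.allclose(out["a"], [1.0, 2.0, 3.0])
        # not mean-centred
        assert out["a"].mean() != pytest.approx(0.0)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            standardize(pd.DataFrame({"a": [1.0, 1.0, 1.0]}), ["a"])


class TestFitAgainstOracles:
    def test_zero_variance_truth_matches_ols(self):
        rng = np.random.default_rng(1)
        df = _crossed_data(sd1=0.0, sd2=0.0, sd_e=0.3, seed=1)
        fit = fit_lmm(
            df,
            ModelSpec("y", (("x",),), (RandomTerm("f1"), RandomTerm("f2")), "ML"),
        )
        X = np.column_stack([np.ones(len(df)), df.x])
        ols, *_ = np.linalg.lstsq(X, df.y, rcond=None)
        assert np.allclose(fit.beta, ols, atol=1e-6)
        assert sum(fit.varcomps.values()) < 1e-3

    @pytest.mark.parametrize("method", ["REML", "ML"])
    def test_optimizer_loglik_matches_dense_oracle(self, method):
        df = _crossed_data(n=250, seed=2)
        spec = ModelSpec("y", (("x",),), (RandomTerm("f1"), RandomTerm("f2")), method)
        fit = fit_lmm(df, spec)
        bf = loglik_bruteforce(df, spec, fit.varcomps, math.sqrt(fit.resid_var))
        assert fit.loglik == pytest.approx(bf, abs=1e-6)

    def test_zero_varcomps_match_iid_gaussian_loglik(self):
        df = _crossed_data(n=100, seed=3)
        spec = ModelSpec("y", (("x",),), (RandomTerm("f1"),), "ML")
        sd = 0.7
        ll = loglik_bruteforce(df, spec, {"f1": 0.0}, sd)
        X = np.column_stack([np.ones(len(df)), df.x])
        beta, *_ = np.linalg.lstsq(X, df.y, rcond=None)
        r = df.y - X @ beta
        expected = -0.5 * (
            len(df) * math.log(2 * math.pi * sd**2) + float(r @ r) / sd**2
        )
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_balanced_one_way_closed_form(self):
        """Dense oracle matches the textbook one-way random-effects ML
        likelihood on a balanced design (eigenvalue decomposition of V)."""
        rng = np.random.default_rng(4)
        g, k = 12, 5  # 12 groups of 5
        df = pd.DataFrame({"f1": np.repeat([str(i) for i in range(g)], k)})
        df["y"] = rng.normal(size=g * k)
        sa2, se2 = 0.4, 0.9
        spec = ModelSpec("y", (), (RandomTerm("f1"),), "ML")
        ll = loglik_bruteforce(df, spec, {"f1": sa2}, math.sqrt(se2))
        # closed form: per group, V_g = se2 I_k + sa2 J_k
        mu_hat_num = mu_hat_den = 0.0
        lam1 = se2 + k * sa2
        for i in range(g):
            ybar = df.y[df.f1 == str(i)].mean()
            mu_hat_num += ybar / lam1
            mu_hat_den += 1.0 / lam1
        mu = mu_hat_num / mu_hat_den
        ll_cf = 0.0
        for i in range(g):
            yg = df.y[df.f1 == str(i)].to_numpy() - mu
            ybar = yg.mean()
            ss_within = float(((yg - ybar) ** 2).sum())
            ll_cf += -0.5 * (
                k * math.log(2 * math.pi)
                + (k - 1) * math.log(se2)
                + math.log(lam1)
                + ss_within / se2
                + k * ybar**2 / lam1
            )
        assert ll == pytest.approx(ll_cf, abs=1e-8)

    def test_constant_response_intercept_only(self):
        df = pd.DataFrame({"y": np.full(20, 3.5), "f1": list("ab") * 10})
        fit = fit_lmm(df, ModelSpec("y", (), (RandomTerm("f1"),), "ML"))
        assert fit.beta[0] == pytest.approx(3.5)
        assert fit.resid_var < 1e-10

    def test_cross_check_against_statsmodels(self):
        sm = pytest.importorskip("statsmodels.formula.api")
        df = _crossed_data(n=300, seed=5)
        fit = fit_lmm(
            df,
            ModelSpec("y", (("x",),), (RandomTerm("f1"), RandomTerm("f2")), "REML"),
        )
        m = sm.mixedlm(
            "y ~ x",
            df,
            groups=np.ones(len(df)),
            vc_formula={"f1": "0 + C(f1)", "f2": "0 + C(f2)"},
        ).fit(reml=True)
        assert np.allclose(fit.beta, m.fe_params.values, atol=1e-4)
        assert fit.varcomps["f1"] == pytest.approx(m.vcomp[0], abs=1e-4)
        assert fit.resid_var == pytest.approx(m.scale, abs=1e-4)


class TestRandomSlope:
    def test_slope_test_has_two_df_and_detects_truth(self):
        rng = np.random.default_rng(6)
        n, nsp = 1200, 15
        df = pd.DataFrame(
            {"x": rng.normal(size=n), "sp": rng.integers(0, nsp, n).astype(str)}
        )
        ui = rng.normal(0, 0.4, nsp)
        us = rng.normal(0, 0.5, nsp)
        codes = df.sp.astype(int)
        df["y"] = 1.0 + 0.5 * df.x + ui[codes] + us[codes] * df.x + rng.normal(0, 0.3, n)
        base = fit_lmm(df, ModelSpec("y", (("x",),), (RandomTerm("sp"),), "REML"))
        slope = fit_lmm(
            df, ModelSpec("y", (("x",),), (RandomTerm("sp", slope="x"),), "REML")
        )
        chi2, dof, p = lr_test(base, slope)
        assert dof == 2
        assert p < 1e-6  # strong true slope variance
        assert slope.varcomps["sp"]["slope"] > 0.05

    def test_null_slope_usually_not_significant(self):
        df = _crossed_data(n=600, seed=7)
        base = fit_lmm(df, ModelSpec("y", (("x",),), (RandomTerm("f1"), RandomTerm("f2")), "REML"))
        slope = fit_lmm(
            df,
            ModelSpec(
                "y", (("x",),), (RandomTerm("f1", slope="x"), RandomTerm("f2")), "REML"
            ),
        )
        chi2, dof, p = lr_test(base, slope)
        assert dof == 2 and chi2 >= 0


class TestComparison:
    def _dummy_fit(self, aic, terms=(("x",),)):
        spec = ModelSpec("y", terms, (), "ML")
        k = len(terms) + 2
        return ModelFit(
            spec=spec, fixed_names=spec.fixed_labels(), beta=np.zeros(len(terms) + 1),
            se=np.ones(len(terms) + 1), varcomps={}, resid_var=1.0,
            theta=np.empty(0), loglik=-(aic - 2 * k) / 2, aic=aic, n_obs=50,
            n_params=k, converged=True, singular=False, var_fixed=0.0, ranef_var={},
        )

    def test_akaike_weights_for_delta_two(self):
        tab = akaike_compare(
            [self._dummy_fit(10.0), self._dummy_fit(12.0, (("x",), ("z", "x")))],
            labels=["m1", "m2"],
        )
        assert tab.loc["m1", "weight"] == pytest.approx(0.7311, abs=1e-4)
        assert tab.loc["m2", "weight"] == pytest.approx(0.2689, abs=1e-4)
        assert tab["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_model_weight_one(self):
        tab = akaike_compare([self._dummy_fit(5.0)], labels=["m"])
        assert tab["weight"].iloc[0] == pytest.approx(1.0)

    def test_equal_aics_equal_weights(self):
        tab = akaike_compare(
            [self._dummy_fit(8.0), self._dummy_fit(8.0, (("z",),))], labels=["a", "b"]
        )
        assert np.allclose(tab["weight"], 0.5)

    def test_reml_fixed_structure_comparison_refused(self):
        df = _crossed_data(n=120, seed=8, extra_cov=True)
        f1 = fit_lmm(df, ModelSpec("y", (("x",),), (RandomTerm("f1"),), "REML"))
        f2 = fit_lmm(df, ModelSpec("y", (("x",), ("z",)), (RandomTerm("f1"),), "REML"))
        with pytest.raises(ValueError):
            akaike_compare([f1, f2])
        with pytest.raises(ValueError):
            lr_test(f1, f2)

    def test_lr_test_identical_models(self):
        df = _crossed_data(n=120, seed=9)
        f = fit_lmm(df, ModelSpec("y", (("x",),), (RandomTerm("f1"),), "ML"))
        chi2, dof, p = lr_test(f, f)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert dof == 0 and p == 1.0

    def test_ml_nested_fixed_effects(self):
        df = _crossed_data(n=300, seed=10, extra_cov=True)
        nested = fit_lmm(df, ModelSpec("y", (("x",),), (RandomTerm("f1"),), "ML"))
        full = fit_lmm(df, ModelSpec("y", (("x",), ("z",)), (RandomTerm("f1"),), "ML"))
        chi2, dof, p = lr_test(nested, full)
        assert dof == 1 and chi2 >= 0 and 0 <= p <= 1

    def test_aic_invariant_to_row_permutation(self):
        df = _crossed_data(n=200, seed=11)
        spec = ModelSpec("y", (("x",),), (RandomTerm("f1"), RandomTerm("f2")), "ML")
        f1 = fit_lmm(df, spec)
        f2 = fit_lmm(df.sample(frac=1.0, random_state=3), spec)
        assert f1.aic == pytest.approx(f2.aic, abs=1e-5)

    def test_type_i_error_rate_of_lrt(self):
        """Under a null extra covariate the 1-df ML LRT rejects at about
        the nominal 5% rate (seeded simulation)."""
        rng = np.random.default_rng(12)
        rejections = 0
        reps = 150
        for i in range(reps):
            df = _crossed_data(n=300, seed=1000 + i, extra_cov=True)
            nested = fit_lmm(df, ModelSpec("y", (("x",),), (RandomTerm("f1"), RandomTerm("f2")), "ML"))
            full = fit_lmm(
                df, ModelSpec("y", (("x",), ("z",)), (RandomTerm("f1"), RandomTerm("f2")), "ML"),
                theta0=nested.theta,
            )
            _, _, p = lr_test(nested, full)
            rejections += p < 0.05
        assert 0.013 <= rejections / reps <= 0.10


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        n = 64
        t = np.arange(n)
        df = pd.DataFrame(
            {"a": np.cos(2 * np.pi * t / n), "b": np.sin(2 * np.pi * t / n)}
        )
        v = vif(df, ["a", "b"])
        assert np.allclose(v, 1.0, atol=1e-10)

    def test_duplicated_predictor_flags_infinite(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
        with pytest.warns(RuntimeWarning):
            v = vif(df, ["a", "b"])
        assert np.isinf(v).all()

    def test_correlation_09_gives_vif_526(self):
        rng = np.random.default_rng(13)
        n = 500
        x1 = rng.normal(size=n)
        x1 = (x1 - x1.mean()) / x1.std(ddof=1)
        e = rng.normal(size=n)
        e = e - e.mean()
        e -= x1 * (e @ x1) / (x1 @ x1)  # orthogonalise
        e /= e.std(ddof=1)
        x2 = 0.9 * x1 + math.sqrt(1 - 0.81) * e
        v = vif(pd.DataFrame({"a": x1, "b": x2}), ["a", "b"])
        assert np.allclose(v, 1 / (1 - 0.81), atol=1e-6)


class TestR2AndPrediction:
    def test_zero_betas_zero_marginal_r2(self):
        df = _crossed_data(beta=(0.0, 0.0), seed=14)
        fit = fit_lmm(df, ModelSpec("y", (("x",),), (RandomTerm("f1"), RandomTerm("f2")), "REML"))
        r2m, r2c = r2_nakagawa(fit)
        assert r2m < 0.02
        assert r2c > r2m  # random effects explain something

    def test_zero_varcomps_marginal_equals_conditional(self):
        df = _crossed_data(sd1=0.0, sd2=0.0, seed=15)
        fit = fit_lmm(df, ModelSpec("y", (("x",),), (RandomTerm("f1"),), "REML"))
        r2m, r2c = r2_nakagawa(fit)
        assert r2c == pytest.approx(r2m, abs=1e-3)

    def test_recovers_designed_variance_shares(self):
        # fixed 0.5, factor 0.2, residual 0.3 of total variance
        rng = np.random.default_rng(16)
        n, nf = 5000, 40
        df = pd.DataFrame(
            {"x": rng.normal(size=n), "f1": rng.integers(0, nf, n).astype(str)}
        )
        u = dict(zip(map(str, range(nf)), rng.normal(0, math.sqrt(0.2), nf)))
        df["y"] = (
            math.sqrt(0.5) * df.x + df.f1.map(u) + rng.normal(0, math.sqrt(0.3), n)
        )
        fit = fit_lmm(df, ModelSpec("y", (("x",),), (RandomTerm("f1"),), "REML"))
        r2m, r2c = r2_nakagawa(fit)
        assert r2m == pytest.approx(0.5, abs=0.05)
        assert r2c == pytest.approx(0.7, abs=0.05)

    def test_prediction_at_zero_covariates_is_ten_to_alpha(self):
        df = _crossed_data(seed=17)
        fit = fit_lmm(df, ModelSpec("y", (("x",),), (RandomTerm("f1"),), "REML"))
        new = pd.DataFrame({"x": [0.0]})
        assert predict_fixed(fit, None, new)[0] == pytest.approx(10.0 ** fit.beta[0])

    def test_back_transform_round_trip(self):
        df = _crossed_data(seed=18)
        fit = fit_lmm(df, ModelSpec("y", (("x",),), (RandomTerm("f1"),), "REML"))
        new = pd.DataFrame({"x": np.linspace(-2, 2, 7)})
        eta = predict_fixed(fit, None, new, back_transform=False)
        g = predict_fixed(fit, None, new, back_transform=True)
        assert np.allclose(np.log10(g), eta)

    def test_standardization_record_applied(self):
        df = _crossed_data(seed=19)
        rec = StandardizationRecord({"x": 2.0})
        fit = fit_lmm(df, ModelSpec("y", (("x",),), (RandomTerm("f1"),), "REML"))
        new = pd.DataFrame({"x": [2.0]})
        scaled = predict_fixed(fit, rec, new, back_transform=False)[0]
        manual = fit.beta[0] + fit.beta[1] * 1.0
        assert scaled == pytest.approx(manual)

    def test_linearity_in_coefficient(self):
        df = _crossed_data(seed=20)
        fit = fit_lmm(df, ModelSpec("y", (("x",),), (RandomTerm("f1"),), "REML"))
        import copy

        fit2 = copy.deepcopy(fit)
        fit2.beta[1] *= 2.0
        new = pd.DataFrame({"x": [1.5]})
        d1 = predict_fixed(fit, None, new, back_transform=False)[0] - fit.beta[0]
        d2 = predict_fixed(fit2, None, new, back_transform=False)[0] - fit.beta[0]
        assert d2 == pytest.approx(2 * d1)

    def test_missing_covariate_rejected(self):
        df = _crossed_data(seed=21)
        fit = fit_lmm(df, ModelSpec("y", (("x",),), (RandomTerm("f1"),), "REML"))
        with pytest.raises(KeyError):
            predict_fixed(fit, None, pd.DataFrame({"other": [1.0]}))

    def test_json_round_trip_preserves_predictions(self):
        df = _crossed_data(seed=22)
        fit = fit_lmm(
            df,
            ModelSpec("y", (("x",),), (RandomTerm("f1"),), "REML"),
            standardization=StandardizationRecord({"x": 1.3}, {"x": (-3.0, 3.0)}),
        )
        clone = ModelFit.from_json(fit.to_json())
        new = pd.DataFrame({"x": np.linspace(-1, 1, 5)})
        assert np.allclose(
            predict_fixed(fit, fit.standardization, new),
            predict_fixed(clone, clone.standardization, new),
        )
        assert clone.aic == pytest.approx(fit.aic)
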