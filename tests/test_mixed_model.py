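import numpy as np
import pandas as pd
import pytest

from linetrend.data_model import RepeatedMeasuresDataset
from linetrend.exceptions import ConfigurationError, FeasibilityError
from linetrend.mixed_model import (
    LMMSpec,
    _n_theta,
    build_design,
    fit_model_menu,
    information_criteria,
    reml_fit,
    wald_f_tests,
)
from linetrend.simulation import SimulationConfig, generate_dataset

from conftest import make_dataset


def one_group_dataset(n=12, m=4, b0_sd=0.5, sigma=0.4, beta2=0.3, seed=0):
    rng = np.random.default_rng(seed)
    t = 2.0 * np.arange(1, m + 1)
    rows = []
    for i in range(n):
        u = rng.normal(0, b0_sd)
        for tj in t:
            rows.append((f"s{i:02d}", "g", tj, 1.0 + beta2 * tj + u
                         + rng.normal(0, sigma)))
    return make_dataset(rows)


class TestDesign:
    def test_fixed_matrix_layout(self):
        ds = generate_dataset(SimulationConfig(m=5, n_per_group=3), 0, seed=0)
        design = build_design(ds, LMMSpec())
        assert design.fixed_names == [
            "intercept", "group[g1]", "time", "group[g1]:time"
        ]
        pat = design.patterns[0]
        assert pat.x.shape == (6, 5, 4)
        t = 2.0 * np.arange(1, 6)
        for i, subj in enumerate(pat.subjects):
            x = pat.x[i]
            np.testing.assert_allclose(x[:, 0], 1.0)
            np.testing.assert_allclose(x[:, 2], t)
            # interaction column is x_i * t: all zero for the reference group
            np.testing.assert_allclose(x[:, 3], x[0, 1] * t)

    def test_random_slope_z(self):
        ds = generate_dataset(SimulationConfig(m=5, n_per_group=3), 0, seed=0)
        design = build_design(ds, LMMSpec(random="intercept-slope"))
        z = design.z_for(design.time_grid)
        assert z.shape == (5, 2)
        np.testing.assert_allclose(z[:, 0], 1.0)
        np.testing.assert_allclose(z[:, 1], design.time_grid)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            LMMSpec(random="spline")
        with pytest.raises(ConfigurationError):
            LMMSpec(structure="toeplitz")


class TestREML:
    def test_balanced_variance_components_match_closed_form(self):
        """For balanced one-group data with iid errors and a random
        intercept, REML separates: the error variance comes from the
        within-subject (time-adjusted) residuals and the between-subject
        variance of the subject means estimates sigma_b^2 + sigma^2/m."""
        n, m = 15, 5
        ds = one_group_dataset(n=n, m=m, seed=3)
        fit = reml_fit(ds, LMMSpec(random="intercept", structure="ind"))
        wide = ds.data.pivot(index="subject", columns="time", values="response")
        y = wide.to_numpy()
        t = wide.columns.to_numpy(float)
        # within: pooled OLS of centred response on centred time
        yc = y - y.mean(axis=1, keepdims=True)
        tc = t - t.mean()
        slope = (yc @ tc).sum() / (n * tc @ tc)
        sse_w = ((yc - np.outer(np.full(n, slope), tc)) ** 2).sum()
        sigma2_hat = sse_w / (n * (m - 1) - 1)
        # between: subject means, variance tau = sigma_b^2 + sigma^2/m
        ybar = y.mean(axis=1)
        tau_hat = ybar.var(ddof=1)
        sigma_b2_hat = tau_hat - sigma2_hat / m
        assert fit.vc.sigma2 == pytest.approx(sigma2_hat, rel=1e-4)
        assert fit.vc.g_matrix[0, 0] == pytest.approx(sigma_b2_hat, rel=1e-3)

    def test_matches_statsmodels_mixedlm(self):
        """Independent REML route for the iid-error random-intercept model."""
        import statsmodels.formula.api as smf

        ds = generate_dataset(
            SimulationConfig(m=4, n_per_group=20, beta=(2, 0.3, 0.1, 0.05)),
            0, seed=5,
        )
        fit = reml_fit(ds, LMMSpec(structure="ind"))
        df = ds.data.copy()
        df["x"] = (df["group"] == "g1").astype(float)
        sm_fit = smf.mixedlm(
            "response ~ x * time", df, groups=df["subject"]
        ).fit(reml=True)
        np.testing.assert_allclose(
            fit.beta.to_numpy(),
            sm_fit.params[["Intercept", "x", "time", "x:time"]].to_numpy(),
            rtol=1e-4,
        )
        assert fit.vc.sigma2 == pytest.approx(sm_fit.scale, rel=1e-3)
        assert fit.vc.g_matrix[0, 0] == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), rel=1e-3
        )

    def test_ar1_never_fits_worse_than_nested_ind(self):
        for rep in range(3):
            ds = generate_dataset(
                SimulationConfig(m=5, n_per_group=15, structure="ar1"),
                rep, seed=2,
            )
            ll_ind = reml_fit(ds, LMMSpec(structure="ind")).reml_loglik
            ll_ar1 = reml_fit(ds, LMMSpec(structure="ar1")).reml_loglik
            assert ll_ar1 >= ll_ind - 1e-6

    def test_parameter_recovery_large_sample(self):
        """beta, rho and sigma2 recovered from one large AR1 dataset."""
        truth = (2.0, 0.3, 0.1, 0.05)
        ds = generate_dataset(
            SimulationConfig(m=10, n_per_group=200, beta=truth,
                             structure="ar1", rho=0.7, sigma2=0.5,
                             b0_sd=0.25),
            0, seed=17,
        )
        fit = reml_fit(ds, LMMSpec(structure="ar1"))
        se = np.sqrt(np.diag(fit.beta_cov))
        np.testing.assert_array_less(
            np.abs(fit.beta.to_numpy() - np.array(truth)), 3 * se
        )
        assert fit.vc.rho == pytest.approx(0.7, abs=0.05)
        assert fit.vc.sigma2 == pytest.approx(0.5, rel=0.15)

    def test_reml_invariant_to_fixed_effect_shift(self):
        ds = generate_dataset(SimulationConfig(m=5, n_per_group=10), 0, seed=9)
        shifted = RepeatedMeasuresDataset(
            ds.data.assign(response=ds.data["response"] + 3.0 * ds.data["time"])
        )
        f0 = reml_fit(ds, LMMSpec(structure="ar1"))
        f1 = reml_fit(shifted, LMMSpec(structure="ar1"))
        assert f1.reml_loglik == pytest.approx(f0.reml_loglik, abs=1e-4)
        assert f1.vc.sigma2 == pytest.approx(f0.vc.sigma2, rel=1e-3)

    def test_compound_symmetry_of_fitted_marginal_covariance(self):
        """Random intercept + iid errors implies equal covariances
        sigma_b^2 between all pairs of measurements."""
        ds = generate_dataset(SimulationConfig(m=5, n_per_group=20), 0, seed=4)
        fit = reml_fit(ds, LMMSpec(structure="ind"))
        v = fit.marginal_covariance()
        off = v[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, fit.vc.g_matrix[0, 0], rtol=1e-10)
        np.testing.assert_allclose(
            np.diag(v), fit.vc.g_matrix[0, 0] + fit.vc.sigma2, rtol=1e-10
        )

    def test_zero_between_subject_variance_hits_boundary(self):
        ds = generate_dataset(
            SimulationConfig(m=4, n_per_group=15, b0_sd=0.0), 0, seed=6
        )
        fit = reml_fit(ds, LMMSpec(structure="ind"))
        assert fit.vc.g_matrix[0, 0] < 0.01  # at/near the boundary, no error

    def test_uns_with_too_few_observations_infeasible(self):
        ds = generate_dataset(
            SimulationConfig(m=14, n_per_group=2), 0, seed=0
        )
        with pytest.raises(FeasibilityError):
            reml_fit(ds, LMMSpec(structure="uns"))


class TestWaldF:
    def test_duplicated_groups_give_zero_f(self):
        """If group g1 is an exact copy of g0, the marginal group and
        interaction coefficients are exactly zero."""
        base = generate_dataset(
            SimulationConfig(m=4, n_per_group=8), 0, seed=7
        )
        half = base.data[base.data["group"] == "g0"]
        dup = half.assign(
            group="g1", subject=half["subject"] + "_copy"
        )
        ds = RepeatedMeasuresDataset(pd.concat([half, dup], ignore_index=True))
        fit = reml_fit(ds, LMMSpec(structure="ind"))
        tests = {t.effect: t for t in wald_f_tests(fit, test_type="marginal")}
        assert tests["group"].statistic == pytest.approx(0.0, abs=1e-8)
        assert tests["group"].p_value == pytest.approx(1.0)
        assert tests["interaction"].statistic == pytest.approx(0.0, abs=1e-8)

    def test_single_df_f_equals_squared_wald_t(self):
        ds = generate_dataset(
            SimulationConfig(m=5, n_per_group=10, beta=(2, 0.2, 0.05, 0.01)),
            0, seed=8,
        )
        fit = reml_fit(ds, LMMSpec(structure="ind"))
        tests = {t.effect: t for t in wald_f_tests(fit, test_type="marginal")}
        i = fit.design.fixed_names.index("time")
        t_wald = fit.beta.iloc[i] / np.sqrt(fit.beta_cov[i, i])
        assert tests["time"].statistic == pytest.approx(t_wald**2, rel=1e-10)

    def test_marginal_f_matches_brute_force_gls(self):
        """Independent matrix-algebra route: stack all subjects into one
        block-diagonal GLS problem at the fitted V and recompute F."""
        ds = generate_dataset(
            SimulationConfig(m=4, n_per_group=6, beta=(2, 0.2, 0.05, 0.02)),
            0, seed=11,
        )
        fit = reml_fit(ds, LMMSpec(structure="ind"))
        v1 = fit.marginal_covariance()
        xs, ys = [], []
        for _, grp, t, y in ds.subject_records():
            x = (grp == "g1") * 1.0
            xs.append(np.column_stack(
                [np.ones_like(t), np.full_like(t, x), t, t * x]))
            ys.append(y)
        nblocks = len(xs)
        bigv = np.kron(np.eye(nblocks), v1)
        bigx = np.vstack(xs)
        bigy = np.concatenate(ys)
        vinv = np.linalg.inv(bigv)
        a = bigx.T @ vinv @ bigx
        beta = np.linalg.solve(a, bigx.T @ vinv @ bigy)
        cov = np.linalg.inv(a)
        f_time = beta[2] ** 2 / cov[2, 2]
        tests = {t.effect: t for t in wald_f_tests(fit, test_type="marginal")}
        np.testing.assert_allclose(fit.beta.to_numpy(), beta, rtol=1e-8)
        assert tests["time"].statistic == pytest.approx(f_time, rel=1e-8)

    def test_inner_outer_denominator_df(self):
        ds = generate_dataset(SimulationConfig(m=5, n_per_group=50), 0, seed=1)
        fit = reml_fit(ds, LMMSpec(structure="ind"))
        tests = {t.effect: t for t in wald_f_tests(fit)}
        assert tests["group"].df_den == 100 - 2
        assert tests["time"].df_den == 500 - 100 - 2
        assert tests["interaction"].df_den == 500 - 100 - 2


class TestCriteriaAndMenu:
    def test_aic_bic_arithmetic(self):
        ds = one_group_dataset(seed=10)
        fit = reml_fit(ds, LMMSpec(structure="ind"))
        aic, bic = information_criteria(fit)
        d, nobs = fit.n_params, fit.design.n_obs
        assert aic == pytest.approx(-2 * fit.reml_loglik + 2 * d)
        assert bic == pytest.approx(-2 * fit.reml_loglik + d * np.log(nobs))
        assert aic - bic == pytest.approx(2 * d - d * np.log(nobs))

    def test_uns_random_slope_parameter_count(self):
        # 3 groups, m=14: 6 fixed + 3 G + 105 error-covariance parameters
        p_fixed = 2 * 3  # intercept+2 group, time+2 interactions
        d = p_fixed + _n_theta(LMMSpec("intercept-slope", "uns"), 14)
        assert d == 114

    def test_menu_selects_true_model_by_bic(self):
        ds = generate_dataset(
            SimulationConfig(m=5, n_per_group=30, beta=(2, 0.3, 0.1, 0.0)),
            0, seed=13,
        )
        menu = fit_model_menu(ds)
        assert len(menu) == 6
        best_bic = menu.sort_values("bic").iloc[0]
        assert (best_bic["random"], best_bic["structure"]) == ("intercept", "ind")
        # output is AIC-ranked
        aics = menu["aic"].dropna().to_numpy()
        assert (np.diff(aics) >= -1e-9).all()

    def test_menu_flags_infeasible_uns(self):
        ds = generate_dataset(SimulationConfig(m=14, n_per_group=2), 0, seed=0)
        menu = fit_model_menu(ds)
        uns_rows = menu[menu["structure"] == "uns"]
        assert (uns_rows["fit"].isna()).all()
        assert uns_rows["reason"].str.contains("Feasibility").all()
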