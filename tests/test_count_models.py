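"""Count-model suite: fits, comparison, diagnostics, simulation, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

import fincam.count_models as cm

VOL = 6000.0
BETA_MAIN = np.array([np.log(5e-4), 0.3, -0.2, 1.0])


def sim(family, n_per_cell, seed, theta=None, pi=None, beta=BETA_MAIN):
    design = cm.full_factorial_design(n_per_cell)
    return cm.simulate_counts(family, beta, design,
                              np.full(len(design), VOL), seed,
                              theta=theta, pi=pi)


class TestDesignMatrix:
    @pytest.mark.parametrize("formula,ncols",
                             [("intercept", 1), ("main", 4),
                              ("two_way", 7), ("three_way", 8)])
    def test_column_counts_on_full_design(self, formula, ncols):
        X, names = cm.design_matrix(cm.full_factorial_design(2), formula)
        assert X.shape[1] == len(names) == ncols
        assert np.linalg.matrix_rank(X) == ncols
        assert names[0] == "(Intercept)"

    def test_two_way_columns_equal_indicator_products(self):
        data = cm.full_factorial_design(3)
        X, names = cm.design_matrix(data, "two_way")
        # oracle: explicit products of the raw indicator columns
        h = (data["H"] == "side").to_numpy(float)
        v = (data["V"] == "lower").to_numpy(float)
        t = (data["T"] == "flood").to_numpy(float)
        oracle = np.column_stack(
            [np.ones(len(data)), h, v, t, h * v, h * t, v * t])
        np.testing.assert_array_equal(X, oracle)

    def test_reference_levels_are_ebb_center_upper(self):
        data = pd.DataFrame({"T": ["ebb"], "H": ["center"], "V": ["upper"]})
        X, _ = cm.design_matrix(data, "main")
        np.testing.assert_array_equal(X, [[1.0, 0.0, 0.0, 0.0]])

    def test_unknown_level_rejected(self):
        data = pd.DataFrame({"T": ["slack"], "H": ["center"], "V": ["upper"]})
        with pytest.raises(ValueError, match="slack"):
            cm.design_matrix(data, "main")


class TestPoisson:
    def test_intercept_only_matches_closed_form(self):
        data = pd.DataFrame({"y": [1, 2, 3], "volume_m3": [2.0] * 3,
                             "T": ["ebb"] * 3, "H": ["center"] * 3,
                             "V": ["upper"] * 3})
        fit = cm.fit_poisson(data, "intercept")
        # MLE mean = ybar; with offset log v the intercept is log(ybar/v)
        assert fit.coef["(Intercept)"] == pytest.approx(np.log(2 / 2.0),
                                                        abs=1e-8)
        assert fit.converged

    def test_one_factor_coefficient_is_log_mean_ratio(self):
        data = pd.DataFrame({
            "y": [1, 2, 3, 5, 7, 9], "volume_m3": [1.0] * 6,
            "T": ["ebb"] * 3 + ["flood"] * 3,
            "H": ["center"] * 6, "V": ["upper"] * 6,
        })
        fit = cm.fit_poisson(data, "main")
        assert fit.coef["T[flood]"] == pytest.approx(np.log(7 / 2), abs=1e-8)

    def test_all_zero_counts_flagged_as_divergent(self):
        data = pd.DataFrame({"y": [0, 0, 0], "volume_m3": [1.0] * 3,
                             "T": ["ebb"] * 3, "H": ["center"] * 3,
                             "V": ["upper"] * 3})
        fit = cm.fit_poisson(data, "intercept")
        assert any("divergence" in f for f in fit.flags)

    def test_mu_includes_volume_offset(self):
        data = sim("poisson", 25, seed=1)
        fit = cm.fit_poisson(data, "main")
        X, _ = cm.design_matrix(data, "main")
        beta = np.array(list(fit.coef.values()))
        np.testing.assert_allclose(
            fit.mu, data["volume_m3"].to_numpy() * np.exp(X @ beta))

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as smapi

        data = sim("poisson", 25, seed=3)
        fit = cm.fit_poisson(data, "main")
        X, _ = cm.design_matrix(data, "main")
        ref = smapi.GLM(data["y"], X, family=smapi.families.Poisson(),
                        offset=np.log(data["volume_m3"])).fit()
        np.testing.assert_allclose(list(fit.coef.values()), ref.params,
                                   atol=1e-6)
        np.testing.assert_allclose(list(fit.se.values()), ref.bse, atol=1e-5)


class TestQuasiPoisson:
    def test_equidispersed_simulation_has_phi_near_one(self):
        data = sim("poisson", 63, seed=5)     # n = 504
        fit = cm.fit_quasipoisson(data, "main")
        assert 0.8 <= fit.dispersion <= 1.2

    def test_betas_identical_to_poisson(self):
        data = sim("negbin", 10, seed=6, theta=1.0)
        pois = cm.fit_poisson(data, "main")
        quasi = cm.fit_quasipoisson(data, "main")
        assert quasi.coef == pois.coef

    def test_duplication_preserves_dispersion_via_pearson_oracle(self):
        data = sim("negbin", 8, seed=7, theta=0.8)
        big = pd.concat([data] * 4, ignore_index=True)
        fit1 = cm.fit_quasipoisson(data, "main")
        fit4 = cm.fit_quasipoisson(big, "main")
        # oracle: explicit Pearson sum / (n - p)
        y = big["y"].to_numpy(float)
        pearson = np.sum((y - fit4.mu) ** 2 / fit4.mu)
        assert fit4.dispersion == pytest.approx(pearson / (len(big) - 4))
        # duplication changes df, not the dispersion estimate materially
        assert fit4.dispersion == pytest.approx(fit1.dispersion, rel=0.1)

    def test_no_likelihood_no_aic_and_scaled_se(self):
        data = sim("negbin", 10, seed=8, theta=0.5)
        pois = cm.fit_poisson(data, "main")
        quasi = cm.fit_quasipoisson(data, "main")
        assert quasi.loglik is None and quasi.aic is None
        ratio = quasi.se["T[flood]"] / pois.se["T[flood]"]
        assert ratio == pytest.approx(np.sqrt(quasi.dispersion), rel=1e-6)

    def test_matches_statsmodels_quasipoisson_scale(self):
        import statsmodels.api as smapi

        data = sim("negbin", 12, seed=9, theta=0.7)
        fit = cm.fit_quasipoisson(data, "main")
        X, _ = cm.design_matrix(data, "main")
        ref = smapi.GLM(data["y"], X, family=smapi.families.Poisson(),
                        offset=np.log(data["volume_m3"])).fit(scale="X2")
        assert fit.dispersion == pytest.approx(ref.scale, rel=1e-6)
        np.testing.assert_allclose(list(fit.se.values()), ref.bse, rtol=1e-5)


class TestNegBin:
    def test_parameter_recovery_at_n2000(self):
        data = sim("negbin", 250, seed=42, theta=0.2)
        fit = cm.fit_negbin(data, "main")
        assert fit.theta == pytest.approx(0.2, rel=0.25)
        for name, truth in zip(fit.coef, BETA_MAIN):
            assert abs(fit.coef[name] - truth) <= 3 * fit.se[name]

    def test_poisson_data_hits_theta_cap_with_flag(self):
        data = sim("poisson", 63, seed=10)
        fit = cm.fit_negbin(data, "main")
        assert fit.theta >= 100
        assert any("Poisson-like" in f for f in fit.flags)

    def test_fitted_loglik_beats_truth(self):
        data = sim("negbin", 100, seed=11, theta=0.4)
        fit = cm.fit_negbin(data, "main")
        X, _ = cm.design_matrix(data, "main")
        offset = np.log(data["volume_m3"].to_numpy())
        ll_truth = cm.nb_loglik(data["y"].to_numpy(float), offset, X,
                                BETA_MAIN, 0.4)
        assert fit.loglik >= ll_truth - 1e-6

    def test_matches_statsmodels_negbin_mle(self):
        from statsmodels.discrete.discrete_model import NegativeBinomial

        data = sim("negbin", 50, seed=12, theta=0.5)
        fit = cm.fit_negbin(data, "main")
        X, _ = cm.design_matrix(data, "main")
        ref = NegativeBinomial(data["y"], X,
                               offset=np.log(data["volume_m3"])).fit(disp=0)
        np.testing.assert_allclose(list(fit.coef.values()), ref.params[:4],
                                   atol=2e-4)
        assert 1 / fit.theta == pytest.approx(ref.params[4], rel=1e-3)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)


class TestZinb:
    def test_parameter_recovery_at_n2000(self):
        data = sim("zinb", 250, seed=7, theta=0.5, pi=0.6)
        fit = cm.fit_zinb(data, "main")
        assert 0.5 <= fit.pi <= 0.7
        assert fit.theta == pytest.approx(0.5, rel=0.30)

    def test_no_inflation_reduces_to_negbin(self):
        data = sim("negbin", 250, seed=9, theta=0.5)
        zinb = cm.fit_zinb(data, "main")
        nb = cm.fit_negbin(data, "main")
        assert zinb.pi < 0.05
        assert abs(zinb.loglik - nb.loglik) < 0.5

    def test_optimum_beats_grid_search_oracle(self):
        data = sim("zinb", 40, seed=13, theta=0.5, pi=0.6)
        fit = cm.fit_zinb(data, "main")
        y = data["y"].to_numpy(float)
        offset = np.log(data["volume_m3"].to_numpy())
        X, _ = cm.design_matrix(data, "main")
        beta = np.array(list(fit.coef.values()))
        gammas = np.linspace(fit.gamma - 1.5, fit.gamma + 1.5, 20)
        thetas = np.exp(np.linspace(np.log(fit.theta) - 1.0,
                                    np.log(fit.theta) + 1.0, 20))
        grid_best = max(cm.zinb_loglik(y, offset, X, beta, th, g)
                        for g in gammas for th in thetas)
        assert fit.loglik >= grid_best - 1e-6

    def test_analytic_gradient_matches_finite_differences(self):
        data = sim("zinb", 15, seed=14, theta=0.6, pi=0.5)
        y = data["y"].to_numpy(float)
        offset = np.log(data["volume_m3"].to_numpy())
        X, _ = cm.design_matrix(data, "main")
        x0 = np.concatenate([BETA_MAIN, [np.log(0.6), 0.0]])
        _, grad = cm._zinb_negll_grad(x0, y, offset, X)
        num = np.empty_like(x0)
        for i in range(x0.size):
            e = np.zeros_like(x0)
            e[i] = 1e-6
            fp, _ = cm._zinb_negll_grad(x0 + e, y, offset, X)
            fm, _ = cm._zinb_negll_grad(x0 - e, y, offset, X)
            num[i] = (fp - fm) / 2e-6
        np.testing.assert_allclose(grad, num, rtol=1e-4, atol=1e-5)

    def test_all_zero_rejected_and_no_zero_flagged(self):
        base = dict(volume_m3=[1.0] * 4, T=["ebb"] * 4, H=["center"] * 4,
                    V=["upper"] * 4)
        with pytest.raises(ValueError, match="zero"):
            cm.fit_zinb(pd.DataFrame({"y": [0, 0, 0, 0], **base}), "intercept")
        fit = cm.fit_zinb(pd.DataFrame({"y": [3, 4, 5, 6], **base}),
                          "intercept")
        assert fit.pi < 0.05
        assert any("no zeros" in f for f in fit.flags)

    def test_matches_statsmodels_zinb(self):
        from statsmodels.discrete.count_model import (
            ZeroInflatedNegativeBinomialP,
        )

        data = sim("zinb", 125, seed=15, theta=0.5, pi=0.6)
        fit = cm.fit_zinb(data, "main")
        X, _ = cm.design_matrix(data, "main")
        ref = ZeroInflatedNegativeBinomialP(
            data["y"], X, exog_infl=np.ones((len(data), 1)),
            offset=np.log(data["volume_m3"]), p=2,
        ).fit(disp=0, maxiter=500)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-3)
        assert fit.gamma == pytest.approx(ref.params[0], abs=1e-2)
        np.testing.assert_allclose(list(fit.coef.values()), ref.params[1:5],
                                   atol=1e-2)


class TestCompareModels:
    @staticmethod
    def _stub(family, formula, aic, loglik=None, **kw):
        return cm.CountModelFit(
            family=family, formula=formula, coef={}, se={},
            loglik=loglik, k=4, aic=aic, mu=np.zeros(1), n=52,
            data_signature=(52, 35, 1.0), **kw)

    def test_close_aics_flagged_negligible(self):
        zinb = self._stub("zinb", "main", 162.8)
        nb = self._stub("negbin", "main", 164.5)
        ranking = cm.compare_models([nb, zinb])
        assert ranking.order[0].family == "zinb"
        assert len(ranking.negligible_pairs) == 1
        a, b, d = ranking.negligible_pairs[0]
        assert d == pytest.approx(1.7, abs=1e-9)

    def test_single_fit_trivial_ranking(self):
        ranking = cm.compare_models([self._stub("poisson", "main", 348.0)])
        assert len(ranking.order) == 1
        assert ranking.negligible_pairs == []

    def test_quasi_excluded_with_note(self):
        quasi = self._stub("quasipoisson", "main", None, dispersion=7.6)
        pois = self._stub("poisson", "main", 348.0)
        ranking = cm.compare_models([quasi, pois])
        assert [f.family for f in ranking.order] == ["poisson"]
        assert "quasi" in ranking.excluded[0]
        assert "only" in ranking.excluded[0]

    def test_mixed_datasets_rejected(self):
        a = self._stub("poisson", "main", 100.0)
        b = cm.CountModelFit(family="negbin", formula="main", coef={},
                             se={}, loglik=None, k=5, aic=90.0,
                             mu=np.zeros(1), n=40,
                             data_signature=(40, 10, 2.0))
        with pytest.raises(ValueError, match="different"):
            cm.compare_models([a, b])


class TestDispersionDiagnostic:
    def test_exact_fit_gives_zero_residuals(self):
        data = sim("poisson", 5, seed=16)
        fit = cm.fit_poisson(data, "main")
        fit.mu = data["y"].to_numpy(float)  # force y == mu
        pairs = cm.dispersion_diagnostic(fit, data)
        assert all(sq == 0.0 for sq, _ in pairs)
        assert len(pairs) == len(data)

    def test_poisson_variance_is_linear_in_mu(self):
        data = sim("poisson", 250, seed=17)
        fit = cm.fit_poisson(data, "main")
        pairs = np.array(cm.dispersion_diagnostic(fit, data))
        sq, mu = pairs[:, 0], pairs[:, 1]
        slope = np.sum(sq * mu) / np.sum(mu ** 2)  # LS through origin
        assert 0.7 <= slope <= 1.3

    def test_negbin_variance_curves_upward(self):
        # squared residuals of a small-theta NB are 4th-moment noisy, so
        # the curvature needs a wide mu range and a large sample
        beta = np.array([np.log(3e-4), 0.3, -0.2, 2.0])
        design = cm.full_factorial_design(1250)
        data = cm.simulate_counts("negbin", beta, design,
                                  np.full(len(design), VOL), seed=18,
                                  theta=0.5)
        fit = cm.fit_negbin(data, "main")
        pairs = np.array(cm.dispersion_diagnostic(fit, data))
        sq, mu = pairs[:, 0], pairs[:, 1]
        # regression of (y-mu)^2 on mu and mu^2: quadratic term present
        A = np.column_stack([np.ones_like(mu), mu, mu ** 2])
        coef = np.linalg.lstsq(A, sq, rcond=None)[0]
        assert coef[2] > 0


class TestWaldTests:
    @staticmethod
    def _fit_with(coef, se, se_df=None):
        return cm.CountModelFit(
            family="poisson", formula="main", coef=coef, se=se,
            loglik=-10.0, k=len(coef), aic=0.0, mu=np.zeros(1), n=52,
            se_df=se_df)

    def test_zero_coefficient_p_is_one(self):
        wt = cm.wald_tests(self._fit_with({"b": 0.0}, {"b": 1.0}))
        assert wt.loc[0, "p"] == pytest.approx(1.0)
        assert wt.loc[0, "code"] == ""

    def test_z_at_0p01_boundary(self):
        wt = cm.wald_tests(self._fit_with({"b": 2.576}, {"b": 1.0}))
        assert wt.loc[0, "p"] == pytest.approx(0.010, abs=5e-4)
        # the boundary rule is strict: p just under 0.01 earns **
        assert wt.loc[0, "code"] == "**"

    def test_monotone_in_z(self):
        fit = self._fit_with({"a": 0.5, "b": 1.5, "c": 2.5},
                             {"a": 1.0, "b": 1.0, "c": 1.0})
        wt = cm.wald_tests(fit).set_index("coef")
        assert wt.loc["a", "p"] > wt.loc["b", "p"] > wt.loc["c", "p"]

    def test_zero_se_flagged_undefined(self):
        wt = cm.wald_tests(self._fit_with({"b": 1.0}, {"b": 0.0}))
        assert wt.loc[0, "code"] == "undefined"
        assert np.isnan(wt.loc[0, "p"])

    def test_quasi_uses_t_reference(self):
        z_fit = cm.wald_tests(self._fit_with({"b": 2.0}, {"b": 1.0}))
        t_fit = cm.wald_tests(self._fit_with({"b": 2.0}, {"b": 1.0},
                                             se_df=10))
        assert t_fit.loc[0, "p"] > z_fit.loc[0, "p"]
        assert t_fit.loc[0, "p"] == pytest.approx(
            2 * stats.t.sf(2.0, df=10))


class TestSimulateCounts:
    def test_pi_one_gives_all_zeros(self):
        data = sim("zinb", 10, seed=19, theta=0.5, pi=1.0)
        assert (data["y"] == 0).all()

    def test_poisson_dispersion_near_one_at_n10000(self):
        design = cm.full_factorial_design(1250)
        data = cm.simulate_counts("poisson", BETA_MAIN, design,
                                  np.full(len(design), VOL), seed=20)
        # pool within cells so the mean is constant within each group
        ratios = []
        for _, grp in data.groupby(["T", "H", "V"], observed=True):
            ratios.append(grp["y"].var() / grp["y"].mean())
        assert 0.9 <= np.mean(ratios) <= 1.1

    def test_cell_means_approach_truth(self):
        design = cm.full_factorial_design(1250)
        data = cm.simulate_counts("negbin", BETA_MAIN, design,
                                  np.full(len(design), VOL), seed=21,
                                  theta=2.0)
        X, _ = cm.design_matrix(design, "main")
        mu = VOL * np.exp(X @ BETA_MAIN)
        for cell, grp in data.groupby(["T", "H", "V"], observed=True):
            truth = mu[data.groupby(["T", "H", "V"], observed=True)
                       .indices[cell]].mean()
            mc_se = grp["y"].std() / np.sqrt(len(grp))
            assert abs(grp["y"].mean() - truth) <= 3 * mc_se

    def test_same_seed_identical(self):
        a = sim("zinb", 10, seed=22, theta=0.5, pi=0.3)
        b = sim("zinb", 10, seed=22, theta=0.5, pi=0.3)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_truth_rejected(self):
        design = cm.full_factorial_design(2)
        with pytest.raises(ValueError, match="theta"):
            cm.simulate_counts("negbin", BETA_MAIN, design,
                               np.full(16, VOL), seed=0)
        with pytest.raises(ValueError, match="pi"):
            cm.simulate_counts("zinb", BETA_MAIN, design,
                               np.full(16, VOL), seed=0, theta=1.0)


class TestPowerPairwise:
    def test_design_values_for_deltas_three_and_four(self):
        p3 = cm.power_pairwise(cm.PowerSpec(7, 2.1, 3.0))
        p4 = cm.power_pairwise(cm.PowerSpec(7, 2.1, 4.0))
        assert p3 == pytest.approx(0.79, abs=0.02)
        assert p4 == pytest.approx(0.95, abs=0.01)

    def test_null_power_equals_alpha(self):
        assert cm.power_pairwise(cm.PowerSpec(7, 2.1, 0.0)) == \
            pytest.approx(0.05, abs=1e-9)

    def test_monte_carlo_agrees_with_analytic(self):
        spec = cm.PowerSpec(7, 2.1, 3.0)
        mc = cm.power_pairwise_mc(spec, reps=200_000, seed=0)
        assert abs(mc - cm.power_pairwise(spec)) < 0.005

    def test_two_sided_option_is_less_powerful(self):
        one = cm.power_pairwise(cm.PowerSpec(7, 2.1, 3.0, sidedness="one"))
        two = cm.power_pairwise(cm.PowerSpec(7, 2.1, 3.0, sidedness="two"))
        assert two < one

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            cm.PowerSpec(1, 2.1, 3.0)
        with pytest.raises(ValueError):
            cm.PowerSpec(7, 0.0, 3.0)
        with pytest.raises(ValueError):
            cm.PowerSpec(7, 2.1, -1.0, sidedness="one")


class TestPowerFactorial:
    def test_null_size_matches_alpha(self):
        p = cm.power_factorial(7, 2.1, np.zeros(8), alpha=0.05,
                               reps=4000, seed=23)
        mc_se = np.sqrt(0.05 * 0.95 / 4000)
        assert abs(p - 0.05) <= 2.5 * mc_se

    def test_huge_effect_is_always_detected(self):
        effects = np.zeros(8)
        effects[0] = 21.0   # 10 SD
        assert cm.power_factorial(7, 2.1, effects, reps=1000, seed=24) >= 0.99

    def test_reproducible_across_independent_seeds(self):
        effects = np.zeros(8)
        effects[0] = 3.0
        p1 = cm.power_factorial(7, 2.1, effects, reps=4000, seed=25)
        p2 = cm.power_factorial(7, 2.1, effects, reps=4000, seed=26)
        mc_se = np.sqrt(p1 * (1 - p1) / 4000)
        assert abs(p1 - p2) <= 2 * np.sqrt(2) * mc_se

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="reps"):
            cm.power_factorial(7, 2.1, np.zeros(8), reps=10)
        with pytest.raises(ValueError, match="estimable"):
            cm.power_factorial(1, 2.1, np.zeros(8))


class TestFamilyInvariants:
    def test_aic_identity_and_likelihood_nesting(self):
        data = sim("zinb", 30, seed=27, theta=0.5, pi=0.4)
        for family in ("poisson", "negbin", "zinb"):
            lls = []
            for formula in ("main", "two_way", "three_way"):
                fit = cm.fit_family(data, family, formula)
                assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)
                lls.append(fit.loglik)
            assert lls[2] >= lls[1] - 1e-6
            assert lls[1] >= lls[0] - 1e-6

    def test_parameter_counts_cover_all_estimated_parameters(self):
        data = sim("zinb", 20, seed=28, theta=0.5, pi=0.4)
        assert cm.fit_poisson(data, "main").k == 4
        assert cm.fit_negbin(data, "main").k == 5       # beta + theta
        assert cm.fit_zinb(data, "main").k == 6         # beta + theta + gamma

    def test_negbin_approaches_poisson_at_large_theta(self):
        data = sim("poisson", 20, seed=29)
        pois = cm.fit_poisson(data, "main")
        beta = np.array(list(pois.coef.values()))
        X, _ = cm.design_matrix(data, "main")
        offset = np.log(data["volume_m3"].to_numpy())
        ll_nb = cm.nb_loglik(data["y"].to_numpy(float), offset, X, beta, 1e6)
        assert abs(ll_nb - pois.loglik) < 1e-3

    def test_zinb_zero_probability_accounting(self):
        data = sim("zinb", 250, seed=30, theta=0.5, pi=0.6)
        fit = cm.fit_zinb(data, "main")
        p0_nb = (fit.theta / (fit.theta + fit.mu)) ** fit.theta
        fitted_zero = fit.pi + (1 - fit.pi) * p0_nb
        empirical = (data["y"] == 0).mean()
        mc_se = np.sqrt(empirical * (1 - empirical) / len(data))
        assert abs(fitted_zero.mean() - empirical) <= 3 * mc_se

    @pytest.mark.parametrize("family,theta,pi",
                             [("poisson", None, None),
                              ("negbin", 0.5, None),
                              ("zinb", 0.5, 0.5)])
    def test_recovery_suite_median_bias_small(self, family, theta, pi):
        """100 seeded replicates at n ~ 500: median estimation error per
        coefficient within 2 empirical SEs of zero."""
        errors = []
        for rep in range(100):
            data = sim(family, 63, seed=1000 + rep, theta=theta, pi=pi)
            fit = cm.fit_family(data, family, "main")
            errors.append([fit.coef[n] - b
                           for n, b in zip(fit.coef, BETA_MAIN)])
        errors = np.array(errors)
        med = np.median(errors, axis=0)
        # SE of a sample median under normality is 1.2533 * sd / sqrt(R)
        med_se = 1.2533 * errors.std(axis=0) / np.sqrt(len(errors))
        assert (np.abs(med) <= 2 * med_se).all()
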