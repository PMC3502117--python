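"""First-stage fits, two-stage pooling, diagnostics, one-stage model."""

import numpy as np
import pytest
from scipy.special import expit

import statsmodels.api as sm
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.meta_analysis import combine_effects

from poolgen import pooling


def _make_effects(betas, variances):
    return [pooling.StudyEffect(f"s{i}", b, v)
            for i, (b, v) in enumerate(zip(betas, variances))]


class TestFirstStage:
    def test_univariable_fit_matches_woolf_2x2(self):
        # cases: 30 exposed / 70 not; controls: 10 / 90
        y = np.r_[np.ones(100), np.zeros(100)]
        x = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
        eff = pooling.fit_study_logistic(y, x)
        assert eff.beta == pytest.approx(np.log(30 * 90 / (70 * 10)), abs=1e-6)
        assert eff.var_beta == pytest.approx(1/30 + 1/70 + 1/10 + 1/90, rel=1e-4)
        assert eff.converged

    def test_constant_exposure_errors(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(ValueError, match="invariant"):
            pooling.fit_study_logistic(y, np.ones(10))

    def test_separation_continuity_fallback(self):
        # zero cell: no exposed controls
        y = np.r_[np.ones(50), np.zeros(50)]
        x = np.r_[np.ones(20), np.zeros(30), np.zeros(50)]
        eff = pooling.fit_study_logistic(y, x, separation="continuity")
        expected = np.log((20.5 * 50.5) / (30.5 * 0.5))
        assert eff.beta == pytest.approx(expected)
        assert not eff.converged

    def test_noise_confounder_leaves_estimate_stable(self):
        rng = np.random.default_rng(5)
        x = (rng.random(800) < 0.3).astype(float)
        y = (rng.random(800) < expit(-0.2 + 0.4 * x)).astype(float)
        z = rng.normal(size=800)
        plain = pooling.fit_study_logistic(y, x)
        adj = pooling.fit_study_logistic(y, x, z[:, None])
        assert abs(adj.beta - plain.beta) < 3 * plain.se


class TestTwoStagePooling:
    def test_hand_derived_two_study_example(self):
        effects = _make_effects([0.2, 0.6], [0.04, 0.09])
        pooled, het = pooling.pool_two_stage(effects, "moment")
        assert het.q == pytest.approx(1.2306, abs=2e-4)
        assert pooled.sigma2_b == pytest.approx(0.01498, abs=2e-5)
        assert pooled.beta == pytest.approx(0.3376, abs=2e-4)
        assert pooled.var_beta == pytest.approx(0.0361, abs=2e-4)
        assert het.i2 == pytest.approx(18.7, abs=0.1)

    def test_matches_independent_dl_implementation(self):
        rng = np.random.default_rng(1)
        betas = rng.normal(0.3, 0.5, size=12)
        variances = rng.uniform(0.01, 0.05, size=12)
        pooled, het = pooling.pool_two_stage(_make_effects(betas, variances))
        ref = combine_effects(betas, variances, method_re="dl")
        assert float(ref.tau2) > 0  # heterogeneous draw: no flooring involved
        assert pooled.sigma2_b == pytest.approx(float(ref.tau2), rel=1e-8)
        assert pooled.beta == pytest.approx(float(ref.mean_effect_re), rel=1e-8)
        assert het.q == pytest.approx(float(ref.q), rel=1e-8)

    def test_weight_identities_hold_exactly(self):
        pooled, _ = pooling.pool_two_stage(
            _make_effects([0.1, 0.5, 0.3], [0.05, 0.02, 0.08]), "pml")
        betas = np.array([0.1, 0.5, 0.3])
        w = pooled.weights
        assert pooled.beta == pytest.approx(np.sum(w * betas) / np.sum(w))
        assert pooled.var_beta == pytest.approx(1 / np.sum(w))
        assert (w > 0).all()

    def test_homogeneous_case_degenerates(self):
        effects = _make_effects([0.4, 0.4, 0.4], [0.05, 0.02, 0.08])
        for method in ("moment", "pml"):
            pooled, het = pooling.pool_two_stage(effects, method)
            assert het.q == pytest.approx(0.0, abs=1e-12)
            assert pooled.sigma2_b == 0.0
            assert pooled.beta == pytest.approx(0.4)

    def test_equal_variances_zero_tau_is_arithmetic_mean(self):
        effects = _make_effects([0.2, 0.3, 0.4], [0.05, 0.05, 0.05])
        pooled, _ = pooling.pool_two_stage(effects, "pml")
        if pooled.sigma2_b == 0.0:
            assert pooled.beta == pytest.approx(0.3)

    def test_ci_coverage_in_calibrated_band(self):
        # K=20 studies, sigma_b=0.15, beta=log 1.5; per-study 2x2 data
        # simulated under the random-slope model; DL CI should cover the
        # true pooled effect 92-98% of the time over 500 replicates.
        rng = np.random.default_rng(42)
        beta, sigma_b, K = np.log(1.5), 0.15, 20
        p0, n = 0.16, 200
        covered = 0
        reps = 500
        for _ in range(reps):
            betas, variances = [], []
            for _k in range(K):
                bk = rng.normal(0, sigma_b)
                odds1 = np.exp(beta + bk) * p0 / (1 - p0)
                p1 = odds1 / (1 + odds1)
                a = rng.binomial(n, p1) or 1
                b = rng.binomial(n, p0) or 1
                a, b = min(a, n - 1), min(b, n - 1)
                c, d = n - a, n - b
                betas.append(np.log(a * d / (b * c)))
                variances.append(1/a + 1/b + 1/c + 1/d)
            pooled, _ = pooling.pool_two_stage(_make_effects(betas, variances))
            lo, hi = pooled.ci()
            covered += lo <= beta <= hi
        assert 0.92 * reps <= covered <= 0.98 * reps

    def test_needs_two_studies(self):
        with pytest.raises(ValueError):
            pooling.pool_two_stage(_make_effects([0.2], [0.05]))


class TestHeterogeneity:
    def test_identical_estimates_give_zero(self):
        het = pooling.heterogeneity(_make_effects([0.3, 0.3], [0.1, 0.2]))
        assert het.q == pytest.approx(0.0, abs=1e-12)
        assert het.i2 == 0.0

    def test_i2_truncated_at_zero_when_q_below_df(self):
        het = pooling.heterogeneity(
            _make_effects([0.30, 0.31, 0.29], [0.5, 0.5, 0.5]))
        assert het.q < het.df
        assert het.i2 == 0.0


class TestMetaRegression:
    def test_intercept_only_reproduces_dl(self):
        betas = [0.2, 0.6, 0.1, 0.4]
        variances = [0.04, 0.09, 0.03, 0.06]
        effects = _make_effects(betas, variances)
        pooled, _ = pooling.pool_two_stage(effects, "moment")
        res = pooling.meta_regression(effects, np.zeros((4, 0)))
        assert res["table"].loc["intercept", "coef"] == pytest.approx(
            pooled.beta, rel=1e-8)
        assert res["sigma2_b"] == pytest.approx(pooled.sigma2_b, rel=1e-8)

    def test_saturating_covariate_explains_everything(self):
        betas = np.array([0.2, 0.6, 0.1, 0.4, 0.5])
        effects = _make_effects(betas, [0.04] * 5)
        res = pooling.meta_regression(effects, betas[:, None])
        assert res["sigma2_b"] == pytest.approx(0.0, abs=1e-10)
        assert res["r2"] == pytest.approx(1.0, abs=1e-8)

    def test_recovers_planted_design_effect(self):
        rng = np.random.default_rng(8)
        K = 40
        design = np.repeat([0.0, 1.0], K // 2)
        variances = rng.uniform(0.02, 0.06, K)
        betas = 0.2 + 0.3 * design + rng.normal(0, np.sqrt(variances))
        res = pooling.meta_regression(_make_effects(betas, variances),
                                      design[:, None])
        coef = res["table"].iloc[1]
        assert abs(coef["coef"] - 0.3) < 3 * coef["se"]

    def test_collinear_covariates_rejected(self):
        effects = _make_effects([0.1, 0.2, 0.3, 0.4, 0.5], [0.05] * 5)
        x = np.arange(5.0)
        with pytest.raises(ValueError, match="collinear"):
            pooling.meta_regression(effects, np.column_stack([x, 2 * x]))


class TestEgger:
    def test_constant_effects_zero_intercept(self):
        effects = _make_effects([0.4] * 5, [0.02, 0.05, 0.1, 0.2, 0.3])
        res = pooling.egger_test(effects)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)
        assert res.slope == pytest.approx(0.4, abs=1e-10)

    def test_type_i_error_near_alpha_on_symmetric_funnel(self):
        rng = np.random.default_rng(17)
        rejections = 0
        reps = 200
        for _ in range(reps):
            variances = rng.uniform(0.01, 0.3, size=30)
            betas = rng.normal(0.2, np.sqrt(variances))
            if pooling.egger_test(_make_effects(betas, variances)).pvalue < 0.05:
                rejections += 1
        # binomial(200, 0.05) 3-SD band ~ [1, 19]
        assert rejections <= 22

    def test_recovers_planted_small_study_bias(self):
        rng = np.random.default_rng(23)
        variances = rng.uniform(0.01, 0.3, size=100)
        se = np.sqrt(variances)
        bias = 1.2
        betas = 0.1 + bias * se + rng.normal(0, se)
        res = pooling.egger_test(_make_effects(betas, variances))
        assert abs(res.intercept - bias) < 3 * res.se

    def test_needs_three_studies(self):
        with pytest.raises(ValueError):
            pooling.egger_test(_make_effects([0.1, 0.2], [0.1, 0.1]))


class TestBreslowDay:
    def test_identical_strata_give_zero(self):
        t = np.array([[30, 70], [20, 80]])
        stat, df, p = pooling.breslow_day([t, t])
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert df == 1

    def test_matches_statsmodels_tarone(self):
        tables = [np.array([[20, 80], [20, 80]]),
                  np.array([[40, 60], [20, 80]])]
        stat, df, p = pooling.breslow_day(tables)
        ref = StratifiedTable([t for t in tables]).test_equal_odds(adjust=True)
        assert stat == pytest.approx(float(ref.statistic), rel=1e-10)
        assert p == pytest.approx(float(ref.pvalue), rel=1e-10)
        assert stat > 0

    def test_invariant_to_stratum_order(self):
        t1 = np.array([[25, 75], [15, 85]])
        t2 = np.array([[40, 60], [30, 70]])
        assert pooling.breslow_day([t1, t2])[0] == pytest.approx(
            pooling.breslow_day([t2, t1])[0])

    def test_zero_margin_stratum_dropped(self):
        good = [np.array([[20, 80], [20, 80]]),
                np.array([[40, 60], [20, 80]])]
        with pytest.warns(UserWarning, match="zero margin"):
            stat, df, p = pooling.breslow_day(
                good + [np.array([[0, 0], [10, 20]])])
        assert stat == pytest.approx(pooling.breslow_day(good)[0])


def _simulate_random_slope(rng, K, n, beta, sigma_b, p_exposure=0.3):
    ys, xs, ss = [], [], []
    for k in range(K):
        bk = rng.normal(0, sigma_b)
        x = (rng.random(n) < p_exposure).astype(float)
        y = (rng.random(n) < expit(-0.3 + (beta + bk) * x)).astype(float)
        ys.append(y); xs.append(x); ss.append(np.repeat(k, n))
    return map(np.concatenate, (ys, xs, ss))


class TestOneStage:
    def test_reduces_to_ordinary_logistic_when_sigma_zero(self):
        rng = np.random.default_rng(3)
        y, x, s = _simulate_random_slope(rng, 4, 400, np.log(2), 0.0)
        fit = pooling.fit_one_stage(y, x, s)
        assert fit.sigma2_b < 1e-3
        # compare with fixed-intercept logistic (study dummies)
        dummies = np.column_stack([(s == k).astype(float) for k in range(4)])
        res = sm.Logit(y, np.column_stack([dummies, x])).fit(disp=0)
        assert fit.beta == pytest.approx(float(res.params[-1]), abs=1e-3)

    def test_marginal_likelihood_matches_monte_carlo(self):
        # 2-study toy: compare GH-integrated loglik with brute-force MC
        rng = np.random.default_rng(6)
        y = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=float)
        x = np.array([1, 0, 1, 0, 1, 0, 0, 1], dtype=float)
        s = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        alphas, beta, sigma = np.array([0.2, -0.4]), 0.7, 0.5
        nodes, weights = np.polynomial.hermite.hermgauss(21)
        params = np.r_[alphas, beta, np.log(sigma)]
        y_by = [y[s == k] for k in range(2)]
        x_by = [x[s == k] for k in range(2)]
        gh = -pooling._one_stage_negloglik(params, y_by, x_by, nodes, weights,
                                           False)
        draws = rng.normal(0, sigma, size=1_000_000)
        mc_ll, mc_se = 0.0, 0.0
        for k in range(2):
            eta = alphas[k] + np.outer(x_by[k], beta + draws)
            ll = (y_by[k][:, None] * eta - np.logaddexp(0, eta)).sum(axis=0)
            lik = np.exp(ll)
            mc_ll += np.log(lik.mean())
            mc_se += (lik.std() / lik.mean() / np.sqrt(draws.size)) ** 2
        assert gh == pytest.approx(mc_ll, abs=3 * max(np.sqrt(mc_se), 1e-4))

    def test_one_and_two_stage_agree_on_simulated_data(self):
        rng = np.random.default_rng(15)
        beta, sigma_b = np.log(1.5), 0.2
        K, n = 12, 400
        y, x, s = _simulate_random_slope(rng, K, n, beta, sigma_b)
        one = pooling.fit_one_stage(y, x, s)
        effects = [pooling.fit_study_logistic(y[s == k], x[s == k],
                                              study=str(k))
                   for k in range(K)]
        two, _ = pooling.pool_two_stage(effects, "pml")
        assert abs(one.beta - beta) < 3 * max(one.se_beta, two.se)
        assert abs(two.beta - beta) < 3 * two.se
        assert abs(one.beta - two.beta) < 3 * two.se


class TestStratified:
    def test_constant_stratum_matches_unstratified(self, small_dataset):
        import pandas as pd
        studies = []
        for df in small_dataset.studies:
            t = pd.DataFrame({"status": df["status"],
                              "_x": (df["R151C"] >= 1).astype(float),
                              "grp": "all"})
            studies.append(t)
        res = pooling.stratified_association(studies, "_x", "grp")
        pooled, _ = res["all"]
        effects = [pooling.fit_study_logistic(
            t["status"].to_numpy(float), t["_x"].to_numpy(float),
            study=str(i), separation="continuity")
            for i, t in enumerate(studies)]
        direct, _ = pooling.pool_two_stage(effects)
        assert pooled.beta == pytest.approx(direct.beta, rel=1e-8)

    def test_detects_effect_confined_to_one_stratum(self):
        # planted OR ratio 2 between strata; Breslow-Day should flag it in
        # most replicates
        rng = np.random.default_rng(9)
        import pandas as pd
        hits = 0
        reps = 40
        for _ in range(reps):
            studies = []
            for _k in range(4):
                n = 600
                strat = rng.integers(0, 2, n)
                x = (rng.random(n) < 0.3).astype(float)
                lo = np.where(strat == 1, np.log(3.0), np.log(1.0))
                y = (rng.random(n) < expit(-0.5 + lo * x)).astype(float)
                studies.append(pd.DataFrame(
                    {"status": y, "_x": x, "grp": strat}))
            res = pooling.stratified_association(studies, "_x", "grp")
            if "breslow_day" in res and res["breslow_day"][2] < 0.05:
                hits += 1
        assert hits >= 0.8 * reps

    def test_relabeling_strata_changes_nothing(self):
        rng = np.random.default_rng(2)
        import pandas as pd
        studies = []
        for _k in range(3):
            n = 300
            studies.append(pd.DataFrame({
                "status": rng.integers(0, 2, n).astype(float),
                "_x": (rng.random(n) < 0.4).astype(float),
                "grp": rng.choice(["a", "b"], n),
            }))
        res1 = pooling.stratified_association(studies, "_x", "grp")
        renamed = [df.assign(grp=df["grp"].map({"a": "zzz", "b": "qqq"}))
                   for df in studies]
        res2 = pooling.stratified_association(renamed, "_x", "grp")
        assert res1["a"][0].beta == pytest.approx(res2["zzz"][0].beta)
        assert res1["breslow_day"][0] == pytest.approx(res2["breslow_day"][0])
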