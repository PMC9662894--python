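"""Model core: hazard offset, predictions, likelihood, IRLS fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from joinpoint_survival import (
    FitError,
    ModelParams,
    SimulationConfig,
    SurvivalTable,
    conditional_death_prob,
    fit_fixed_joinpoints,
    hazard_offset,
    log_likelihood,
    predict_cumulative_survival,
    predict_interval_survival,
    simulate_table,
)
from joinpoint_survival.model import information_criteria


def params_strategy():
    """Random small-but-varied model parameters over 1990-2010."""
    return st.builds(
        lambda alphas, beta, delta: ModelParams(
            alphas=np.array(alphas), beta=beta, deltas=np.array([delta]),
            taus=np.array([2000]), year_anchor=1990),
        alphas=st.lists(st.floats(-3, 0.5), min_size=2, max_size=6),
        beta=st.floats(-0.1, 0.1),
        delta=st.floats(-0.1, 0.1),
    )


class TestHazardOffset:
    def test_hand_evaluated_hinge(self):
        p = ModelParams(alphas=np.zeros(3), beta=0.1, deltas=np.array([-0.15]),
                        taus=np.array([2000]), year_anchor=1990)
        assert hazard_offset(1995, p) == pytest.approx(0.5)
        assert hazard_offset(2005, p) == pytest.approx(1.5 - 0.75)
        # piecewise slopes: +0.1 before the joinpoint, -0.05 after
        assert hazard_offset(1996, p) - hazard_offset(1995, p) == pytest.approx(0.1)
        assert hazard_offset(2006, p) - hazard_offset(2005, p) == pytest.approx(-0.05)

    def test_no_joinpoint_is_linear(self):
        p = ModelParams(alphas=np.zeros(2), beta=0.03, year_anchor=1990)
        years = np.arange(1980, 2020)
        np.testing.assert_allclose(hazard_offset(years, p),
                                   0.03 * (years - 1990))

    def test_zero_coefficients_give_zero(self):
        p = ModelParams(alphas=np.zeros(2), beta=0.0,
                        deltas=np.array([0.0]), taus=np.array([2000]))
        assert hazard_offset(1234.5, p) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(params_strategy(), st.integers(1991, 2009))
    def test_continuity_at_every_year(self, p, x):
        eps = 1e-7
        left = hazard_offset(x - eps, p)
        right = hazard_offset(x + eps, p)
        assert abs(right - left) < 1e-5


class TestPredictions:
    def test_cloglog_inverse_at_baseline(self):
        alpha = np.log(-np.log(0.9))
        p = ModelParams(alphas=np.array([alpha]), beta=0.0, year_anchor=2000)
        assert predict_interval_survival(p, 2000, 1) == pytest.approx(0.9, abs=1e-14)

    def test_proportionality_relation(self):
        p = ModelParams(alphas=np.array([-1.0, -1.5]), beta=-0.04,
                        year_anchor=1990)
        for j in (1, 2):
            s1 = predict_interval_survival(p, 1995, j)
            s2 = predict_interval_survival(p, 2005, j)
            ratio = np.log(s2) / np.log(s1)
            expect = np.exp(hazard_offset(2005, p) - hazard_offset(1995, p))
            assert ratio == pytest.approx(expect, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(params_strategy(), st.integers(1985, 2015))
    def test_product_equals_power_form(self, p, x):
        J = p.n_intervals
        prod = np.prod([predict_interval_survival(p, x, j)
                        for j in range(1, J + 1)])
        assert predict_cumulative_survival(p, x, J) == pytest.approx(
            prod, rel=1e-12, abs=1e-300)

    def test_cumulative_t1_equals_interval(self):
        p = ModelParams(alphas=np.array([-1.0, -2.0]), beta=0.01,
                        year_anchor=2000)
        assert predict_cumulative_survival(p, 2005, 1) == pytest.approx(
            predict_interval_survival(p, 2005, 1), rel=1e-15)

    def test_cumulative_non_increasing_in_t(self):
        p = ModelParams(alphas=np.array([-1.0, -1.2, -1.4]), beta=-0.02,
                        year_anchor=2000)
        S = [predict_cumulative_survival(p, 2003, t) for t in (1, 2, 3)]
        assert S[0] >= S[1] >= S[2]

    def test_death_prob_ratio_approaches_exp_beta(self):
        # small-hazard approximation: lambda(x+1)/lambda(x) -> exp(beta*)
        beta = -0.05
        for alpha in (-2.0, -5.0, -9.0):
            p = ModelParams(alphas=np.array([alpha]), beta=beta,
                            year_anchor=2000)
            r = (conditional_death_prob(p, 2001, 1)
                 / conditional_death_prob(p, 2000, 1))
            if alpha == -9.0:
                assert r == pytest.approx(np.exp(beta), rel=1e-4)
        # and it is monotone increasing in the offset
        s = [conditional_death_prob(
            ModelParams(alphas=np.array([-2.0]), beta=b, year_anchor=2000),
            2010, 1) for b in (-0.05, 0.0, 0.05)]
        assert s[0] < s[1] < s[2]

    def test_out_of_range_interval_raises(self):
        p = ModelParams(alphas=np.array([-1.0]), beta=0.0)
        with pytest.raises(FitError):
            predict_interval_survival(p, 2000, 2)
        with pytest.raises(FitError):
            predict_cumulative_survival(p, 2000, 0)


class TestLogLikelihood:
    def _one_cell_table(self, died, n=100):
        df = pd.DataFrame({
            "Year": [2000, 2001], "Interval": [1, 1],
            "Alive_at_Start": [n, n], "Lost_to_Followup": [0, 0],
            "Died": [died, died],
        })
        return SurvivalTable(df, mode="cause_specific")

    def test_binomial_mle_at_observed_fraction(self):
        # with beta=0 both cells share pi; the likelihood over alpha peaks
        # where pi equals the observed death fraction y
        table = self._one_cell_table(died=20)
        y = 0.2

        def ll_at_pi(pi):
            alpha = np.log(-np.log(1 - pi))
            p = ModelParams(alphas=np.array([alpha]), beta=0.0,
                            year_anchor=2000)
            return log_likelihood(p, table)

        best = ll_at_pi(y)
        for pi in (0.05, 0.15, 0.25, 0.5, 0.9):
            assert ll_at_pi(pi) < best

    def test_relative_equals_cause_specific_when_e_is_one(self, one_jp_fit):
        df = simulate_table(SimulationConfig(
            year_range=(2000, 2004), n_intervals=2, cohort_size=500,
            baseline_interval_survival=0.9, beta=-0.02,
            expected_interval_survival=1.0, seed=5)).data
        p = ModelParams(alphas=np.array([-1.0, -1.5]), beta=-0.02,
                        year_anchor=2000)
        rel = log_likelihood(p, SurvivalTable(df, mode="relative"))
        cs = log_likelihood(p, SurvivalTable(df, mode="cause_specific"))
        assert rel == pytest.approx(cs, rel=1e-14)

    def test_higher_at_fit_than_at_truth(self, one_jp_config, one_jp_table,
                                         one_jp_fit):
        from joinpoint_survival import true_params
        assert one_jp_fit.loglik >= log_likelihood(
            true_params(one_jp_config), one_jp_table)


class TestFitFixedJoinpoints:
    def test_flat_truth_recovers_zero_slope(self):
        cfg = SimulationConfig(year_range=(1995, 2009), n_intervals=3,
                               cohort_size=100_000,
                               baseline_interval_survival=[0.85, 0.92, 0.95],
                               beta=0.0, seed=11)
        fit = fit_fixed_joinpoints(simulate_table(cfg))
        se = np.sqrt(fit.cov[-1, -1])
        assert abs(fit.params.beta) < 0.01
        assert abs(fit.params.beta) < 3 * se

    def test_loglik_reproducible_from_params(self, one_jp_fit, one_jp_table):
        assert log_likelihood(one_jp_fit.params, one_jp_table) == pytest.approx(
            one_jp_fit.loglik, abs=1e-8)

    def test_score_equations_satisfied(self, one_jp_fit):
        assert one_jp_fit.grad_norm < 1e-6

    def test_covariance_symmetric_psd(self, one_jp_fit):
        cov = one_jp_fit.cov
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        eigs = np.linalg.eigvalsh(cov)
        assert eigs.min() > -1e-10
        # dimensions: J alphas + beta + K deltas; taus are not in cov
        J, K = one_jp_fit.params.n_intervals, one_jp_fit.params.n_joinpoints
        assert cov.shape == (J + 1 + K, J + 1 + K)

    def test_information_criteria_consistent(self, one_jp_fit):
        bic, aic = information_criteria(one_jp_fit.loglik, one_jp_fit.p,
                                        one_jp_fit.n_cells)
        assert one_jp_fit.bic == pytest.approx(bic)
        assert one_jp_fit.aic == pytest.approx(aic)
        assert one_jp_fit.p == one_jp_fit.params.n_intervals + 1 + 2 * 1

    def test_saturated_fit_reproduces_observed_fractions(self):
        # 2 years x 1 interval with 2 free parameters: fitted pi == observed y
        df = pd.DataFrame({
            "Year": [2000, 2001], "Interval": [1, 1],
            "Alive_at_Start": [400, 500], "Lost_to_Followup": [0, 0],
            "Died": [60, 55],
        })
        table = SurvivalTable(df, mode="cause_specific")
        fit = fit_fixed_joinpoints(table)
        for x, y in [(2000, 60 / 400), (2001, 55 / 500)]:
            pi = conditional_death_prob(fit.params, x, 1)
            assert pi == pytest.approx(y, abs=1e-9)

    def test_anchor_shift_invariance(self, one_jp_table):
        f1 = fit_fixed_joinpoints(one_jp_table, taus=(2000,), year_anchor=1990)
        f2 = fit_fixed_joinpoints(one_jp_table, taus=(2000,), year_anchor=2005)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)
        assert f1.bic == pytest.approx(f2.bic, abs=1e-6)
        for x in (1991, 2000.0, 2007):
            for t in (1, 5):
                assert predict_cumulative_survival(f1.params, x, t) == \
                    pytest.approx(predict_cumulative_survival(f2.params, x, t),
                                  abs=1e-10)

    def test_fitted_survival_bounded_despite_observed_excess(self):
        # observed relative survival > 1 in the data; the model stays in (0,1]
        df = pd.DataFrame({
            "Year": np.repeat(np.arange(2000, 2010), 2),
            "Interval": np.tile([1, 2], 10),
            "Alive_at_Start": np.tile([1000, 960], 10),
            "Lost_to_Followup": 0,
            "Died": np.tile([20, 5], 10),   # interval 2 beats expected survival
            "Expected_Survival_Interval": 0.97,
        })
        fit = fit_fixed_joinpoints(SurvivalTable(df, mode="relative"))
        for x in (2000, 2009):
            for t in (1, 2):
                assert 0 < predict_cumulative_survival(fit.params, x, t) <= 1

    def test_brute_force_oracle_matches_small(self):
        from scipy.optimize import minimize
        cfg = SimulationConfig(year_range=(2000, 2009), n_intervals=3,
                               cohort_size=500,
                               baseline_interval_survival=[0.85, 0.92, 0.95],
                               beta=-0.03, seed=17)
        table = simulate_table(cfg)
        fit = fit_fixed_joinpoints(table)

        def neg_ll(theta):
            p = ModelParams(alphas=theta[:3], beta=theta[3], year_anchor=2000)
            return -log_likelihood(p, table)

        x0 = np.concatenate([fit.params.alphas + 0.3, [0.0]])
        res = minimize(neg_ll, x0, method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 500})
        assert fit.loglik >= -res.fun - 1e-6

    @pytest.mark.parametrize("taus", [(1990,), (2009,)])
    def test_joinpoint_on_range_edge_raises(self, one_jp_table, taus):
        with pytest.raises(FitError, match="inside"):
            fit_fixed_joinpoints(one_jp_table, taus=taus)

    def test_degenerate_segment_names_segment(self, one_jp_table):
        with pytest.raises(FitError, match="segment"):
            # joinpoint at the penultimate year: last segment has 2 years,
            # fine; two joinpoints 2007, 2008 leave a 1-year middle segment
            fit_fixed_joinpoints(one_jp_table, taus=(2007, 2008))

    def test_single_year_table_rejected(self):
        df = pd.DataFrame({
            "Year": [2000], "Interval": [1], "Alive_at_Start": [100],
            "Lost_to_Followup": [0], "Died": [10],
        })
        with pytest.raises(FitError, match="two diagnosis years"):
            fit_fixed_joinpoints(SurvivalTable(df, mode="cause_specific"))

    def test_observed_hessian_matches_numerical(self, one_jp_table):
        # the covariance comes from the analytic observed information; check
        # it against a finite-difference Hessian of the log-likelihood
        fit = fit_fixed_joinpoints(one_jp_table, taus=(2000,))
        p = fit.params
        theta = np.concatenate([p.alphas, [p.beta], p.deltas])
        J = p.n_intervals

        def ll(th):
            return log_likelihood(
                ModelParams(th[:J], float(th[J]), th[J + 1:], p.taus,
                            p.year_anchor), one_jp_table)

        n = len(theta)
        H = np.zeros((n, n))
        h = 1e-5
        for i in range(n):
            for k in range(i, n):
                pp = mm = pm = mp = theta.copy()
                def at(di, dk):
                    th = theta.copy()
                    th[i] += di * h
                    th[k] += dk * h
                    return ll(th)
                H[i, k] = H[k, i] = (at(1, 1) - at(1, -1) - at(-1, 1)
                                     + at(-1, -1)) / (4 * h * h)
        cov_num = np.linalg.inv(-H)
        np.testing.assert_allclose(fit.cov, cov_num, rtol=5e-3, atol=1e-10)
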