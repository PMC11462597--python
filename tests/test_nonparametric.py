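import numpy as np
import pytest
from scipy import stats

from spataft import (
    cox_ph_fit,
    km_estimate,
    logrank_test,
    mortality_table,
    schoenfeld_global_test,
)

from conftest import TABLE2_COUNTS, cohort_from_counts, make_cohort


class TestKaplanMeier:
    def test_no_censoring_equals_empirical(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_hand_product_limit_with_censoring(self):
        # {1, 2+, 3}: S(1) = 2/3, then the last subject dies: S(3) = 0
        km = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert km.evaluate(1.0) == pytest.approx(2 / 3)
        assert km.evaluate(3.0) == pytest.approx(0.0)

    def test_all_censored_is_unity(self):
        km = km_estimate([5.0, 9.0], [0, 0])
        assert km.event_times.size == 0
        assert km.evaluate(100.0) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_no_censoring_equals_empirical_property(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(size=200)
        km = km_estimate(t, np.ones(200, dtype=int))
        for q in (0.1, 0.5, 0.9):
            x = np.quantile(t, q)
            assert km.evaluate(x) == pytest.approx((t > x).mean())

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(8)
        t = rng.exponential(10, 150)
        d = rng.integers(0, 2, 150)
        if d.sum() == 0:
            d[0] = 1
        km = km_estimate(t, d)
        kmf = lifelines.KaplanMeierFitter().fit(t, d)
        for u in km.event_times:
            assert km.evaluate(u) == pytest.approx(
                float(kmf.survival_function_at_times(u).iloc[0]), abs=1e-10
            )


class TestLogRank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        d = [1, 1, 1, 1, 1, 1]
        g = ["a"] * 3 + ["b"] * 3
        stat, df, p = logrank_test(t, d, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_bruteforce_hypergeometric_oracle(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        d = np.ones(6, dtype=int)
        g = np.array([0, 0, 0, 1, 1, 1])
        stat, df, p = logrank_test(t, d, g)
        # direct O-E/V loop for two groups
        O = E = V = 0.0
        for u in np.unique(t):
            r = t >= u
            n = r.sum()
            n1 = (r & (g == 0)).sum()
            dd = ((t == u) & (d == 1)).sum()
            d1 = ((t == u) & (d == 1) & (g == 0)).sum()
            O += d1
            E += dd * n1 / n
            if n > 1:
                V += dd * (n1 / n) * (1 - n1 / n) * (n - dd) / (n - 1)
        assert stat == pytest.approx((O - E) ** 2 / V, abs=1e-10)
        assert df == 1

    def test_matches_lifelines_multigroup(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(4)
        t = rng.exponential(5, 120)
        d = rng.integers(0, 2, 120)
        g = rng.integers(0, 3, 120)
        stat, df, p = logrank_test(t, d, g)
        res = lifelines.statistics.multivariate_logrank_test(t, g, d)
        assert df == 2
        assert stat == pytest.approx(res.test_statistic, abs=1e-8)
        assert p == pytest.approx(res.p_value, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], ["a", "a"])

    def test_invariances(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(5, 60)
        d = rng.integers(0, 2, 60)
        g = rng.integers(0, 2, 60)
        s1, *_ = logrank_test(t, d, g)
        s2, *_ = logrank_test(t * 7.3, d, g)  # time rescaling
        s3, *_ = logrank_test(t, d, 1 - g)  # label permutation
        assert s1 == pytest.approx(s2, abs=1e-10)
        assert s1 == pytest.approx(s3, abs=1e-10)


def simulate_ph(n, beta, rng, censor=0.3):
    x = rng.integers(0, 2, n).astype(float)
    u = rng.uniform(size=n)
    t = -np.log(u) / np.exp(beta * x)
    c = np.quantile(t, 1 - censor)
    return np.minimum(t, c), (t <= c).astype(int), x.reshape(-1, 1)


class TestCoxPH:
    def test_null_model_loglik(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        d = np.array([1, 1, 0, 1])
        fit = cox_ph_fit(t, d, np.empty((4, 0)))
        # -sum log(risk set size) at event times: sizes 4, 3, 1
        assert fit.loglik == pytest.approx(-(np.log(4) + np.log(3) + np.log(1)))

    def test_single_covariate_matches_sksurv(self):
        sksurv = pytest.importorskip("sksurv.linear_model")
        rng = np.random.default_rng(11)
        t, d, X = simulate_ph(20, 0.8, rng)
        fit = cox_ph_fit(t, d, X)
        y = np.array(
            [(bool(e), tt) for e, tt in zip(d, t)],
            dtype=[("event", "?"), ("time", "<f8")],
        )
        oracle = sksurv.CoxPHSurvivalAnalysis(ties="breslow", tol=1e-12).fit(X, y)
        assert fit.coef[0] == pytest.approx(oracle.coef_[0], abs=1e-6)

    def test_multicovariate_matches_sksurv_with_ties(self):
        sksurv = pytest.importorskip("sksurv.linear_model")
        rng = np.random.default_rng(12)
        n = 80
        X = rng.integers(0, 2, (n, 2)).astype(float)
        t = np.ceil(rng.exponential(5, n))  # heavy ties
        d = rng.integers(0, 2, n)
        fit = cox_ph_fit(t, d, X)
        y = np.array(
            [(bool(e), tt) for e, tt in zip(d, t)],
            dtype=[("event", "?"), ("time", "<f8")],
        )
        oracle = sksurv.CoxPHSurvivalAnalysis(ties="breslow", tol=1e-12).fit(X, y)
        np.testing.assert_allclose(fit.coef, oracle.coef_, atol=1e-6)

    def test_duplicated_column_rank_error(self):
        rng = np.random.default_rng(1)
        t, d, X = simulate_ph(30, 0.5, rng)
        with pytest.raises(ValueError, match="rank"):
            cox_ph_fit(t, d, np.hstack([X, X]))

    def test_schoenfeld_residuals_sum_to_zero(self):
        rng = np.random.default_rng(13)
        t, d, X = simulate_ph(100, 0.5, rng)
        fit = cox_ph_fit(t, d, X)
        # at the MLE the score is zero, so residuals sum to ~0
        np.testing.assert_allclose(fit.schoenfeld.sum(axis=0), 0.0, atol=1e-6)


class TestSchoenfeldGlobal:
    def test_type_one_error_under_ph(self):
        rng = np.random.default_rng(21)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            t, d, X = simulate_ph(80, 0.7, rng)
            fit = cox_ph_fit(t, d, X)
            _, p = schoenfeld_global_test(fit)
            rejections += p < 0.05
        assert rejections / n_rep <= 0.10

    def test_power_under_time_varying_effect(self):
        rng = np.random.default_rng(22)
        rejections = 0
        n_rep = 20
        for _ in range(n_rep):
            n = 500
            x = rng.integers(0, 2, n).astype(float)
            # crossing hazards: effect reverses over time
            t0 = rng.exponential(1.0, n)
            t = np.where(x == 1, np.where(t0 < 0.7, t0 * 0.35, 0.7 * 0.35 + (t0 - 0.7) * 3.0), t0)
            d = np.ones(n, dtype=int)
            fit = cox_ph_fit(t, d, x.reshape(-1, 1))
            _, p = schoenfeld_global_test(fit)
            rejections += p < 0.05
        assert rejections / n_rep >= 0.8

    def test_agrees_with_lifelines_direction(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd
        from lifelines.statistics import proportional_hazard_test

        rng = np.random.default_rng(23)
        t, d, X = simulate_ph(150, 0.6, rng)
        fit = cox_ph_fit(t, d, X)
        stat, p = schoenfeld_global_test(fit)
        df = pd.DataFrame({"T": t, "E": d, "x": X[:, 0]})
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        res = proportional_hazard_test(cph, df, time_transform="identity")
        # same construction up to tie handling: statistics close, verdicts equal
        assert stat == pytest.approx(float(res.summary["test_statistic"].iloc[0]), rel=0.15)

    def test_no_covariates_rejected(self):
        t = np.array([1.0, 2.0])
        d = np.array([1, 1])
        fit = cox_ph_fit(t, d, np.empty((2, 0)))
        with pytest.raises(ValueError):
            schoenfeld_global_test(fit)


class TestMortalityTable:
    def test_overall_percentages(self):
        cohort = cohort_from_counts(TABLE2_COUNTS["overall"])
        summary = mortality_table(cohort, "factor")
        row = summary.table.loc["Overall"]
        assert row["died_pct"] == 63.83
        assert row["alive_pct"] == 36.17

    def test_sex_percentages_and_chisq(self):
        cohort = cohort_from_counts(TABLE2_COUNTS["sex"])
        summary = mortality_table(cohort, "factor")
        assert summary.table.loc["Male", "died_pct"] == 67.79
        assert summary.table.loc["Female", "died_pct"] == 58.72
        assert summary.p_value < 0.001
        # independent chi-square via scipy on the raw counts
        obs = summary.table[["alive", "died"]].to_numpy()
        chi2 = stats.chi2_contingency(obs, correction=False)[0]
        assert summary.chi2 == pytest.approx(chi2)

    def test_row_counts_sum_to_cohort(self):
        cohort = cohort_from_counts(TABLE2_COUNTS["stage"])
        summary = mortality_table(cohort, "factor")
        assert int(summary.table[["alive", "died"]].to_numpy().sum()) == len(cohort)
        assert summary.df == 4

    def test_single_level_warns(self):
        cohort = make_cohort([1, 2], [1, 0], covariates={"f": ["a", "a"]})
        with pytest.warns(UserWarning, match="single level"):
            summary = mortality_table(cohort, "f")
        assert summary.chi2 is None

    def test_percent_rounding_half_up(self):
        # 1/8 = 12.5% rounds to 12.50; 5/8 = 62.5 -> 62.50
        cohort = make_cohort(
            [1] * 8, [1, 0, 0, 0, 0, 0, 0, 0], covariates={"f": ["a"] * 8}
        )
        summary = mortality_table(cohort, "f")
        assert summary.table.loc["a", "died_pct"] == 12.5
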