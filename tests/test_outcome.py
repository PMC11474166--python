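import numpy as np
import pandas as pd
import pytest
from scipy import stats

from contrapet.outcome import (
    cox_fit,
    logrank_median_split,
    ols_regression,
    partial_correlation,
    seizure_comparison,
)


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(30)
        x, y = rng.normal(size=20), rng.normal(size=20)
        ours = partial_correlation(x, y)
        r, p = stats.pearsonr(x, y)
        assert abs(ours["r"] - r) < 1e-12
        assert abs(ours["p"] - p) < 1e-9

    def test_identity_gives_r_one(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=15)
        z = rng.normal(size=(15, 2))
        out = partial_correlation(x, x.copy(), z)
        assert np.isclose(out["r"], 1.0)

    def test_matches_recursive_formula_one_covariate(self):
        rng = np.random.default_rng(32)
        z = rng.normal(size=300)
        x = 0.6 * z + rng.normal(size=300)
        y = -0.4 * z + 0.3 * x + rng.normal(size=300)
        r_xy = stats.pearsonr(x, y)[0]
        r_xz = stats.pearsonr(x, z)[0]
        r_yz = stats.pearsonr(y, z)[0]
        oracle = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        out = partial_correlation(x, y, z.reshape(-1, 1))
        assert np.isclose(out["r"], oracle, atol=1e-10)

    def test_collinear_covariates_rejected_with_names(self):
        rng = np.random.default_rng(33)
        z = rng.normal(size=20)
        Z = np.column_stack([z, 2 * z])
        with pytest.raises(ValueError, match="cov1"):
            partial_correlation(rng.normal(size=20), rng.normal(size=20), Z)


class TestOLSRegression:
    def test_exact_linear_relation_gives_unit_r2(self):
        rng = np.random.default_rng(34)
        X = rng.normal(size=(20, 2))
        y = 2 * X[:, 0] - X[:, 1] + 3
        out = ols_regression(y, X)
        assert np.isclose(out["r_squared"], 1.0)
        assert np.isclose(out["adj_r_squared"], 1.0)

    def test_single_predictor_standardized_beta_is_pearson_r(self):
        rng = np.random.default_rng(35)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        out = ols_regression(y, x.reshape(-1, 1))
        assert np.isclose(out["beta_std"][0], stats.pearsonr(x, y)[0])

    def test_null_r2_expectation(self):
        # y independent of p predictors: E[R^2] ~ p/(n-1)
        rng = np.random.default_rng(36)
        n, p = 40, 3
        r2 = [
            ols_regression(rng.normal(size=n), rng.normal(size=(n, p)))["r_squared"]
            for _ in range(300)
        ]
        assert abs(np.mean(r2) - p / (n - 1)) < 0.02

    def test_adjusted_r2_formula(self):
        rng = np.random.default_rng(37)
        X = rng.normal(size=(25, 2))
        y = X[:, 0] + rng.normal(size=25)
        out = ols_regression(y, X)
        n, p = 25, 2
        expect = 1 - (1 - out["r_squared"]) * (n - 1) / (n - p - 1)
        assert np.isclose(out["adj_r_squared"], expect)


class TestCox:
    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(38)
        n = 2000
        t = rng.exponential(10, n)
        x = rng.normal(size=n)
        res = cox_fit(t, np.ones(n, bool), pd.DataFrame({"x": x}))
        assert abs(res.coefficients[0]) < 0.1

    def test_two_group_rate_ratio_matches_exponential_mle(self):
        rng = np.random.default_rng(39)
        n = 1000
        g = np.repeat([0, 1], n // 2)
        rate = np.where(g == 1, 2.0, 1.0)
        t = rng.exponential(1 / rate)
        res = cox_fit(t, np.ones(n, bool), pd.DataFrame({"g": g}))
        # exponential MLE oracle for the rate ratio
        d1, T1 = (g == 1).sum(), t[g == 1].sum()
        d0, T0 = (g == 0).sum(), t[g == 0].sum()
        oracle = (d1 / T1) / (d0 / T0)
        assert abs(res.hazard_ratios[0] - oracle) / oracle < 0.10

    def test_all_censored_refused(self):
        with pytest.raises(ValueError, match="events"):
            cox_fit(np.ones(10), np.zeros(10, bool), pd.DataFrame({"x": np.arange(10)}))

    def test_hr_per_sd_consistency_identity(self):
        rng = np.random.default_rng(40)
        n = 300
        x = rng.normal(2.0, 0.5, n)
        t = rng.exponential(1 / (0.1 * np.exp(0.8 * (x - 2.0))))
        cov = pd.DataFrame({"x": x})
        raw = cox_fit(t, np.ones(n, bool), cov)
        std = cox_fit(t, np.ones(n, bool), cov, z_transform_flags={"x": True})
        sd = x.std(ddof=1)
        assert np.isclose(
            std.hazard_ratios[0], np.exp(raw.coefficients[0] * sd), rtol=1e-6
        )


class TestLogrankMedianSplit:
    def test_clone_groups_give_zero_chi2(self):
        t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        e = np.ones(8, bool)
        v = np.array([0, 0, 0, 0, 1, 1, 1, 1.0])
        out = logrank_median_split(v, t, e)
        assert out["chi2"] < 1e-9

    def test_power_on_separated_exponentials(self):
        rng = np.random.default_rng(41)
        hits = 0
        for _ in range(20):
            t = np.concatenate(
                [rng.exponential(1.0, 500), rng.exponential(0.5, 500)]
            )
            v = np.concatenate([np.zeros(500), np.ones(500)])
            out = logrank_median_split(v, t, np.ones(1000, bool))
            hits += out["p"] < 0.001
        assert hits == 20

    def test_chi2_matches_hand_enumeration_toy_table(self):
        # 6 subjects, all events: O-E computed by direct enumeration
        v = np.array([1.0, 2, 3, 10, 11, 12])
        t = np.array([5.0, 6, 7, 1, 2, 3])
        e = np.ones(6, bool)
        out = logrank_median_split(v, t, e)
        # high group (v > 6.5): t = 1,2,3; low: 5,6,7
        # event times 1..6, observed-high = [1,1,1,0,0,0]
        O_E = 0.0
        V = 0.0
        n_h, n_l = 3, 3
        for k, obs_h in enumerate([1, 1, 1, 0, 0, 0]):
            n = n_h + n_l
            expect_h = n_h / n
            O_E += obs_h - expect_h
            V += n_h * n_l / n**2  # one event per time, (n-d)/(n-1) = 1
            if obs_h:
                n_h -= 1
            else:
                n_l -= 1
        assert np.isclose(out["chi2"], O_E**2 / V, rtol=1e-6)

    def test_invariant_to_monotone_transform_of_marker(self):
        rng = np.random.default_rng(42)
        v = rng.uniform(1, 2, 30)
        t = rng.exponential(1, 30)
        e = rng.random(30) < 0.8
        a = logrank_median_split(v, t, e)
        b = logrank_median_split(np.exp(v), t, e)
        assert np.isclose(a["chi2"], b["chi2"])

    def test_median_ties_go_to_low_group(self):
        v = np.array([1.0, 1.0, 1.0, 2.0])
        t = np.arange(1.0, 5.0)
        out = logrank_median_split(v, t, np.ones(4, bool))
        assert out["n_high"] == 1 and out["n_low"] == 3


class TestSeizureComparison:
    def test_reduces_to_pooled_t_without_covariates(self):
        rng = np.random.default_rng(43)
        y = rng.normal(size=24)
        g = np.repeat([0, 1], 12)
        out = seizure_comparison(y, g)
        t, p = stats.ttest_ind(y[g == 1], y[g == 0], equal_var=True)
        assert np.isclose(out["p"], p)
        assert np.isclose(out["estimate"], y[g == 1].mean() - y[g == 0].mean())

    def test_recovers_injected_effect_with_covariate(self):
        rng = np.random.default_rng(44)
        est = []
        for _ in range(100):
            g = np.repeat([0, 1], 20)
            cov = rng.normal(size=40)
            y = 0.1 * g + 0.5 * cov + rng.normal(0, 0.1, 40)
            out = seizure_comparison(y, g, pd.DataFrame({"c": cov}))
            est.append(out["estimate"])
        assert abs(np.mean(est) - 0.1) < 0.02

    def test_covariate_explaining_outcome_yields_null_estimate(self):
        rng = np.random.default_rng(45)
        g = np.repeat([0, 1], 15)
        cov = rng.normal(size=30)
        y = 2.0 * cov
        out = seizure_comparison(y, g, pd.DataFrame({"c": cov}))
        assert abs(out["estimate"]) < 1e-10

    def test_collinear_covariate_dropped_with_notice(self):
        rng = np.random.default_rng(46)
        g = np.repeat([0, 1], 10)
        y = rng.normal(size=20)
        out = seizure_comparison(y, g, pd.DataFrame({"dup": g.astype(float)}))
        assert out["covariates_dropped"] == ["dup"]
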