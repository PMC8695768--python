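"""Age-trend ANOVA, the rate+duration regression, and LMG importance,
each checked against an independent brute-force oracle."""

from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xylokin.growth_stats import age_trend_anova, fit_rate_duration, lmg_importance


def _ols_r2(y, X):
    """Normal-equations R^2 oracle, independent of the package path."""
    M = np.column_stack([np.ones_like(y), X])
    beta = np.linalg.solve(M.T @ M, M.T @ y)
    resid = y - M @ beta
    return 1.0 - float(resid @ resid) / float(np.sum((y - y.mean()) ** 2))


def _lmg_by_enumeration(y, X):
    """Average sequential R^2 increments over all predictor orderings."""
    p = X.shape[1]
    out = np.zeros(p)
    orders = list(permutations(range(p)))
    for order in orders:
        so_far = []
        prev = 0.0
        for j in order:
            so_far.append(j)
            r2 = _ols_r2(y, X[:, sorted(so_far)])
            out[j] += r2 - prev
            prev = r2
    return out / len(orders)


class TestAgeTrendAnova:
    def test_exact_linear_response(self):
        ages = {f"t{i}": a for i, a in enumerate([8, 8, 14, 20, 27, 51])}
        vals = {k: 3.0 * v + 1.0 for k, v in ages.items()}
        res = age_trend_anova(vals, ages)
        assert res.residual_sum_sq == pytest.approx(0.0, abs=1e-18)
        assert res.p_value < 1e-10
        assert res.df == 1

    def test_f_matches_hand_computed_decomposition(self):
        ages = dict(zip("abcdef", [8.0, 8.0, 14.0, 20.0, 27.0, 51.0]))
        vals = dict(zip("abcdef", [210.0, 190.0, 160.0, 120.0, 100.0, 60.0]))
        res = age_trend_anova(vals, ages)
        a = np.array(list(ages.values()))
        y = np.array(list(vals.values()))
        slope = np.sum((a - a.mean()) * (y - y.mean())) / np.sum((a - a.mean()) ** 2)
        ssr = slope ** 2 * np.sum((a - a.mean()) ** 2)
        sse = np.sum((y - y.mean()) ** 2) - ssr
        assert res.sum_sq == pytest.approx(ssr, rel=1e-10)
        assert res.f_value == pytest.approx(ssr / (sse / 4), rel=1e-10)
        assert res.mean_sq == pytest.approx(res.sum_sq / res.df)

    def test_f_is_squared_slope_t(self):
        rng = np.random.default_rng(3)
        ages = {f"t{i}": float(a) for i, a in enumerate(
            rng.choice([8, 14, 20, 27, 51], size=25))}
        vals = {k: 200.0 - 2.0 * v + rng.normal(0, 20) for k, v in ages.items()}
        res = age_trend_anova(vals, ages)
        import statsmodels.api as sm
        a = np.array([ages[k] for k in vals])
        fit = sm.OLS(np.array(list(vals.values())), sm.add_constant(a)).fit()
        assert res.f_value == pytest.approx(float(fit.tvalues[1]) ** 2, rel=1e-9)

    def test_type_i_error_calibration_under_null(self):
        rng = np.random.default_rng(7)
        ages = np.repeat([8.0, 14.0, 20.0, 27.0, 51.0], 5)
        hits = 0
        n_perm = 1000
        base = rng.normal(100, 15, ages.size)
        for _ in range(n_perm):
            y = rng.permutation(base)
            res = age_trend_anova(dict(zip(map(str, range(25)), y)),
                                  dict(zip(map(str, range(25)), ages)))
            hits += res.p_value < 0.05
        assert 0.03 <= hits / n_perm <= 0.07

    def test_factor_mode_uses_class_df(self):
        rng = np.random.default_rng(1)
        ages = np.repeat([8.0, 14.0, 20.0, 27.0, 51.0], 5)
        y = rng.normal(100, 10, ages.size)
        res = age_trend_anova(dict(zip(map(str, range(25)), y)),
                              dict(zip(map(str, range(25)), ages)),
                              mode="factor")
        assert res.df == 4 and res.residual_df == 20
        from scipy.stats import f_oneway
        groups = [y[ages == a] for a in np.unique(ages)]
        assert res.f_value == pytest.approx(f_oneway(*groups).statistic, rel=1e-9)

    def test_constant_response_errors(self):
        with pytest.raises(ValueError):
            age_trend_anova({"a": 1.0, "b": 1.0, "c": 1.0},
                            {"a": 8.0, "b": 14.0, "c": 20.0})


class TestRateDuration:
    def test_noiseless_coefficients_recovered_exactly(self):
        rng = np.random.default_rng(0)
        x1 = rng.uniform(0.15, 0.55, 25)
        x2 = rng.uniform(200.0, 250.0, 25)
        Y = -50.0 + 400.0 * x1 + 0.2 * x2
        m = fit_rate_duration(Y, x1, x2)
        assert m.alpha0 == pytest.approx(-50.0, abs=1e-8)
        assert m.alpha1 == pytest.approx(400.0, rel=1e-10)
        assert m.alpha2 == pytest.approx(0.2, rel=1e-8)
        assert m.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        x1 = rng.uniform(0.1, 0.9, 10)
        x2 = rng.uniform(180.0, 260.0, 10)
        Y = -40.0 + 350.0 * x1 + 0.3 * x2 + rng.normal(0, 10, 10)
        m = fit_rate_duration(Y, x1, x2)
        M = np.column_stack([np.ones(10), x1, x2])
        beta = np.linalg.solve(M.T @ M, M.T @ Y)
        assert [m.alpha0, m.alpha1, m.alpha2] == pytest.approx(beta.tolist(), rel=1e-9)
        # residual orthogonality to the design (normal equations)
        resid = Y - M @ beta
        assert np.max(np.abs(M.T @ resid)) < 1e-8 * np.abs(Y).sum()

    def test_constant_duration_rejected_by_name(self):
        rng = np.random.default_rng(2)
        x1 = rng.uniform(0, 1, 8)
        with pytest.raises(ValueError, match="duration"):
            fit_rate_duration(rng.normal(size=8), x1, np.full(8, 220.0))


class TestLmg:
    def test_orthogonal_predictors_get_marginal_r2(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        y = 2.0 * x1 + 1.0 * x2
        imp = lmg_importance(y, {"x1": x1, "x2": x2})
        assert imp.contributions["x1"] == pytest.approx(_ols_r2(y, x1[:, None]), rel=1e-9)
        assert imp.contributions["x2"] == pytest.approx(_ols_r2(y, x2[:, None]), rel=1e-9)

    def test_duplicated_predictor_splits_evenly(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = x + rng.normal(0, 0.4, 30)
        imp = lmg_importance(y, {"a": x, "b": x.copy() * 2.0})
        assert imp.contributions["a"] == pytest.approx(imp.contributions["b"], rel=1e-9)
        assert sum(imp.contributions.values()) == pytest.approx(imp.total_r_squared, rel=1e-9)

    @pytest.mark.parametrize("p", [2, 3, 4])
    def test_matches_factorial_enumeration(self, p):
        rng = np.random.default_rng(10 + p)
        X = rng.normal(size=(40, p)) @ (np.eye(p) + 0.4 * rng.normal(size=(p, p)))
        y = X @ rng.uniform(0.5, 2.0, p) + rng.normal(0, 1.0, 40)
        imp = lmg_importance(y, {f"x{j}": X[:, j] for j in range(p)})
        brute = _lmg_by_enumeration(y, X)
        got = np.array([imp.contributions[f"x{j}"] for j in range(p)])
        assert np.max(np.abs(got - brute)) < 1e-10

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_allocation_complete_and_order_invariant(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(25, 3))
        y = X @ np.array([1.0, 0.5, 0.2]) + rng.normal(0, 1, 25)
        imp = lmg_importance(y, {"a": X[:, 0], "b": X[:, 1], "c": X[:, 2]})
        assert sum(imp.contributions.values()) == pytest.approx(
            imp.total_r_squared, abs=1e-12)
        assert all(v >= -1e-12 for v in imp.contributions.values())
        flipped = lmg_importance(y, {"c": X[:, 2], "b": X[:, 1], "a": X[:, 0]})
        for k in "abc":
            assert imp.contributions[k] == pytest.approx(
                flipped.contributions[k], abs=1e-12)

    def test_normalized_shares_sum_to_one(self):
        rng = np.random.default_rng(9)
        x1, x2 = rng.normal(size=20), rng.normal(size=20)
        y = x1 + 0.1 * x2 + rng.normal(0, 0.5, 20)
        imp = lmg_importance(y, {"x1": x1, "x2": x2}, normalized=True)
        assert sum(imp.contributions.values()) == pytest.approx(1.0, abs=1e-10)
        assert imp.normalized

    def test_rate_dominates_under_reported_heterogeneity_pattern(self):
        # rates spread widely across stands, durations narrowly
        rng = np.random.default_rng(14)
        rate = np.repeat([0.17, 0.19, 0.21, 0.40, 0.51], 5) + rng.normal(0, 0.01, 25)
        dur = np.repeat([211.0, 239.0, 229.0, 221.0, 243.0], 5) + rng.normal(0, 8, 25)
        y = 400.0 * rate + 0.2 * dur + rng.normal(0, 12, 25)
        imp = lmg_importance(y, {"rate": rate, "duration": dur})
        assert imp.contributions["rate"] > imp.contributions["duration"]

    def test_insufficient_rows_rejected(self):
        with pytest.raises(ValueError):
            lmg_importance(np.arange(3.0), {"a": np.arange(3.0), "b": np.arange(3.0) ** 2})
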