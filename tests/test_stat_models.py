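"""Inference-layer tests: Spearman, OLS against the normal-equation
oracle, the penalized-spline mixed smoother's limits, and the
heteroscedastic mixed model against a dense multivariate-normal oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nervemorph as nm
from nervemorph.exceptions import DesignError
from nervemorph.stat_models import dispersion_age_test


class TestSpearman:
    def test_monotone_invariance(self):
        x = np.linspace(1, 10, 20)
        rho, _ = nm.spearman(x, x**2)
        assert rho == pytest.approx(1.0)

    def test_perfect_negative(self):
        rho, _ = nm.spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_ties_match_hand_ranked_formula(self):
        # average ranks computed by hand, then Pearson on the ranks
        x = np.array([1.0, 2.0, 2.0, 4.0, 5.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 7.0])
        rx = np.array([1.0, 2.5, 2.5, 4.0, 5.0])
        ry = np.array([2.0, 1.0, 3.5, 3.5, 5.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        rho, _ = nm.spearman(x, y)
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            nm.spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestOls:
    def test_noiseless_line_exact(self):
        age = np.linspace(80, 100, 30)
        fit = nm.fit_ols(2 + 3 * age, pd.DataFrame({"age": age}))
        assert fit.params["intercept"] == pytest.approx(2.0, abs=1e-8)
        assert fit.params["age"] == pytest.approx(3.0, abs=1e-10)

    def test_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((60, 3)), columns=list("abc"))
        y = rng.standard_normal(60)
        fit = nm.fit_ols(y, X)
        Xd = np.column_stack([np.ones(60), X.to_numpy()])
        beta = np.linalg.pinv(Xd) @ y
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)
        # normal equations: residuals orthogonal to design columns
        assert np.allclose(Xd.T @ fit.resid, 0.0, atol=1e-7)

    def test_collinear_columns_named(self):
        X = pd.DataFrame({"a": [1, 2, 3, 4.0], "b": [2, 4, 6, 8.0]})
        with pytest.raises(DesignError, match="a|b"):
            nm.fit_ols([1, 2, 3, 4.0], X)


class TestSplineMixed:
    def test_linear_truth_is_nearly_linear_fit(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 1500)
        y = 1.0 + 0.5 * x + 0.3 * rng.standard_normal(1500)
        fit = nm.fit_spline_mixed(y, x)
        assert fit.edf <= 2.2
        d = fit.derivative(np.linspace(0.5, 9.5, 50))
        assert np.allclose(d, 0.5, atol=0.05)

    def test_infinite_lambda_equals_ols_line(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 400)
        y = 2.0 - 0.3 * x + 0.5 * rng.standard_normal(400)
        fit = nm.fit_spline_mixed(y, x, lam=1e12)
        ols = nm.fit_ols(y, pd.DataFrame({"x": x}))
        grid = np.linspace(1, 9, 20)
        expected = ols.params["intercept"] + ols.params["x"] * grid
        assert np.allclose(fit.curve(grid), expected, atol=1e-3)
        assert fit.edf == pytest.approx(2.0, abs=1e-3)

    def test_rss_monotone_in_lambda(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 500)
        y = np.sin(x) + 0.2 * rng.standard_normal(500)
        rss = []
        for lam in [1e-4, 1e0, 1e4, 1e8]:
            fit = nm.fit_spline_mixed(y, x, lam=lam)
            rss.append(np.sum((y - fit.curve(x))**2))
        assert all(a <= b + 1e-9 for a, b in zip(rss, rss[1:]))

    def test_random_intercept_absorbs_group_shifts(self):
        rng = np.random.default_rng(4)
        G, m = 80, 50
        g = np.repeat(np.arange(G), m)
        x = rng.uniform(0, 10, G * m)
        shift = 1.5 * rng.standard_normal(G)
        y = 0.5 * x + shift[g] + 0.2 * rng.standard_normal(G * m)
        fit = nm.fit_spline_mixed(y, x, groups=g)
        assert fit.tau2 == pytest.approx(1.5**2, rel=0.4)
        d = fit.derivative(np.linspace(1, 9, 40))
        assert np.allclose(d, 0.5, atol=0.06)


def _toy_hetero(seed=0, G=8, m=6):
    rng = np.random.default_rng(seed)
    n = G * m
    grp = np.repeat(np.arange(G), m)
    X = pd.DataFrame({"intercept": np.ones(n), "x": rng.standard_normal(n)})
    Z = pd.DataFrame({"intercept": np.ones(n), "z": rng.standard_normal(n)})
    beta = np.array([1.0, 0.5])
    gamma = np.array([-0.4, 0.3])
    tau = 0.6
    y = nm.simulate_from_fitted_model(X.to_numpy(), beta, Z.to_numpy(),
                                      gamma, grp, tau, rng)
    return y, X, Z, grp


class TestHeteroMixed:
    def test_loglik_matches_dense_mvn_oracle(self):
        y, X, Z, grp = _toy_hetero()
        fit = nm.fit_hetero_mixed(y, X, Z, grp, seed=0)
        ll = 0.0
        for g in np.unique(grp):
            m = grp == g
            d = np.exp(2 * (Z[m].to_numpy() @ fit.gamma.to_numpy()))
            cov = np.diag(d) + fit.tau2
            ll += stats.multivariate_normal.logpdf(
                y[m], X[m].to_numpy() @ fit.beta.to_numpy(), cov)
        assert fit.loglik == pytest.approx(ll, abs=1e-6)

    def test_homoscedastic_truth_reduces_to_ols(self):
        rng = np.random.default_rng(5)
        n = 600
        grp = np.arange(n) % 60
        X = pd.DataFrame({"intercept": np.ones(n),
                          "x": rng.standard_normal(n)})
        Z = pd.DataFrame({"intercept": np.ones(n),
                          "z": rng.standard_normal(n)})
        y = 2.0 + 0.7 * X["x"].to_numpy() + rng.standard_normal(n)
        fit = nm.fit_hetero_mixed(y, X, Z, grp, seed=1)
        ols = nm.fit_ols(y, X[["x"]])
        for term, ref in [("intercept", ols.params["intercept"]),
                          ("x", ols.params["x"])]:
            assert abs(fit.beta[term] - ref) < 2 * ols.bse[term]
        assert abs(fit.gamma["z"]) < 0.1
        assert fit.tau2 < 0.05

    def test_pvalues_invariant_to_sign_flip(self):
        y, X, Z, grp = _toy_hetero(seed=7)
        f1 = nm.fit_hetero_mixed(y, X, Z, grp, seed=0)
        f2 = nm.fit_hetero_mixed(-y, X, Z, grp, seed=0)
        assert np.allclose(f1.p_beta.to_numpy(), f2.p_beta.to_numpy(),
                           atol=1e-4)

    def test_row_count_mismatch_raises(self):
        y, X, Z, grp = _toy_hetero()
        with pytest.raises(DesignError):
            nm.fit_hetero_mixed(y[:-1], X, Z, grp)


class TestDispersionAgeTest:
    def _frame(self, age_gamma, seed):
        rng = np.random.default_rng(seed)
        P, m = 120, 5
        grp = np.repeat(np.arange(P), m)
        age = np.repeat(rng.normal(0.0, 5.4, P), m)
        n = P * m
        X = pd.DataFrame({"intercept": np.ones(n), "age": age})
        Zb = pd.DataFrame({"intercept": np.ones(n)})
        Za = Zb.assign(age=age)
        y = nm.simulate_from_fitted_model(
            X.to_numpy(), [1.0, 0.0], Za.to_numpy(),
            [np.log(0.5), age_gamma], grp, 0.3, rng)
        return y, X, grp, Zb, Za

    def test_age_constant_variance_gives_null_gamma(self):
        y, X, grp, Zb, Za = self._frame(0.0, seed=11)
        out = dispersion_age_test(y, X, grp, {"base": Zb, "age": Za})
        fit = out.attrs["fits"]["age"]
        assert abs(fit.gamma["age"]) < 2.5 * fit.se_gamma["age"] + 0.01

    def test_recovers_log_sd_age_slope(self):
        # dispersion increasing 0.019 log-SD units per year of age
        est = []
        for s in range(5):
            y, X, grp, Zb, Za = self._frame(0.019, seed=20 + s)
            fit = nm.fit_hetero_mixed(y, X, Za, grp, seed=s)
            est.append(fit.gamma["age"])
        mcse = np.std(est) / np.sqrt(len(est))
        assert abs(np.mean(est) - 0.019) < max(2 * mcse, 0.004)

    def test_lr_statistic_nonnegative(self):
        y, X, grp, Zb, Za = self._frame(0.01, seed=33)
        out = dispersion_age_test(y, X, grp, {"base": Zb, "age": Za})
        assert out["lr_vs_previous"].iloc[1] >= -1e-6

    def test_non_nested_designs_rejected(self):
        y, X, grp, Zb, Za = self._frame(0.0, seed=1)
        other = pd.DataFrame({"something": np.ones(len(y)),
                              "else_": np.arange(len(y)) % 2})
        with pytest.raises(DesignError):
            dispersion_age_test(y, X, grp, {"base": Zb, "other": other})


class TestEffectProjection:
    def test_five_year_projection(self):
        assert nm.effect_size_projection(4.9, -0.04, 5) == pytest.approx(4.7)

    def test_zero_delta(self):
        assert nm.effect_size_projection(3.3, -0.5, 0) == 3.3
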