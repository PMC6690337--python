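"""Mixed-model likelihood, oracles, Wald reporting, fallback ladder."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit
from scipy.stats import norm

from tonetrain.glmm import BinomialMixedModel, ModelSpec, fit_glmm


def _random_intercept_data(seed=42, G=5, n=50, beta=(0.5, 0.3), sd=0.8):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, sd, G)
    g = np.repeat(np.arange(G), n)
    X = np.column_stack([np.ones(G * n), rng.normal(size=G * n)])
    eta = X @ np.array(beta) + u[g]
    y = (rng.random(G * n) < expit(eta)).astype(float)
    return y, X, g


class TestPlainLogistic:
    def test_intercept_recovers_logit_of_accuracy(self):
        # 75% correct, no random variance: intercept = logit(0.75) = 1.0986
        y = np.array([1.0] * 75 + [0.0] * 25)
        m = BinomialMixedModel(y, np.ones((100, 1)), np.zeros(100, dtype=int), None,
                               exog_names=["intercept"])
        res = m.fit()
        assert res.fe_params["intercept"] == pytest.approx(1.0986, abs=1e-3)
        assert res.fallback_level == "none"

    def test_matches_irls_oracle(self):
        y, X, _ = _random_intercept_data(sd=0.0)
        m = BinomialMixedModel(y, X, np.zeros(len(y), dtype=int), None,
                               exog_names=["intercept", "x1"])
        res = m.fit()
        oracle = sm.Logit(y, X).fit(disp=0)
        assert np.max(np.abs(res.fe_params.to_numpy() - oracle.params)) < 1e-4


class TestQuadrature:
    def test_loglike_matches_51_node_hermite_oracle(self):
        y, X, g = _random_intercept_data()
        m = BinomialMixedModel(y, X, g, np.ones((len(y), 1)),
                               exog_names=["intercept", "x1"], re_names=["intercept"])
        res = m.fit()
        beta = res.fe_params.to_numpy()
        sigma = float(np.sqrt(res.cov_re.iloc[0, 0]))
        # non-adaptive 51-node Gauss-Hermite, computed independently
        t, w = hermgauss(51)
        eta_f = X @ beta
        oracle = 0.0
        for gi in np.unique(g):
            rows = g == gi
            vals = np.array([
                np.log(w[k]) + np.sum(
                    y[rows] * (eta_f[rows] + np.sqrt(2) * sigma * t[k])
                    - np.logaddexp(0, eta_f[rows] + np.sqrt(2) * sigma * t[k])
                )
                for k in range(51)
            ])
            oracle += -0.5 * np.log(np.pi) + vals.max() + np.log(np.exp(vals - vals.max()).sum())
        assert abs(res.llf - oracle) < 1e-3

    def test_verbose_trace_is_monotone_nondecreasing(self):
        y, X, g = _random_intercept_data(G=4, n=30)
        m = BinomialMixedModel(y, X, g, np.ones((len(y), 1)))
        res = m.fit(verbose=True)
        assert len(res.optim_trace) > 1
        assert np.all(np.diff(res.optim_trace) >= -1e-6)


class TestMultivariateLaplace:
    def test_slope_model_recovers_generating_values(self):
        rng = np.random.default_rng(7)
        G, n = 40, 80
        g = np.repeat(np.arange(G), n)
        x = rng.normal(size=G * n)
        X = np.column_stack([np.ones(G * n), x])
        U = rng.multivariate_normal([0, 0], [[0.64, 0.2], [0.2, 0.25]], G)
        eta = X @ np.array([0.3, 0.5]) + U[g, 0] + U[g, 1] * x
        y = (rng.random(G * n) < expit(eta)).astype(float)
        m = BinomialMixedModel(y, X, g, X, exog_names=["intercept", "x"],
                               re_names=["intercept", "x"])
        res = m.fit()
        assert res.converged
        for name, true in (("intercept", 0.3), ("x", 0.5)):
            b, se = res.fe_params[name], res.bse[name]
            assert b - 3 * se <= true <= b + 3 * se
        w = np.linalg.eigvalsh(res.cov_re.to_numpy())
        assert np.all(w >= -1e-8)  # covariance positive semi-definite


class TestWaldReporting:
    def test_z_and_p_consistent_with_estimates(self):
        y, X, g = _random_intercept_data(G=6, n=40)
        m = BinomialMixedModel(y, X, g, np.ones((len(y), 1)),
                               exog_names=["intercept", "x1"])
        tab = m.fit().wald_table()
        assert list(tab["term"]) == sorted(tab["term"])
        np.testing.assert_allclose(tab["z"], tab["beta"] / tab["se"])
        np.testing.assert_allclose(tab["p"], 2 * norm.sf(np.abs(tab["z"])))

    def test_rank_deficient_design_names_aliased_terms(self):
        y = np.array([0.0, 1.0] * 20)
        X = np.column_stack([np.ones(40), np.arange(40.0), 2 * np.arange(40.0)])
        with pytest.raises(ValueError, match="rank deficient"):
            BinomialMixedModel(y, X, np.zeros(40, dtype=int), None,
                               exog_names=["intercept", "x", "x_copy"])

    def test_separation_is_flagged(self):
        x = np.concatenate([np.full(20, -1.0), np.full(20, 1.0)])
        y = (x > 0).astype(float)  # perfectly separated
        m = BinomialMixedModel(y, np.column_stack([np.ones(40), x]),
                               np.zeros(40, dtype=int), None,
                               exog_names=["intercept", "x"])
        with pytest.warns(RuntimeWarning, match="separation"):
            res = m.fit()
        assert res.wald_table().set_index("term").loc["x", "separation_flag"]


class TestFallbackLadder:
    def test_fallback_level_is_deterministic(self, small_battery):
        trials = small_battery["trials"]
        df = trials[trials["task"] == "oddity"].dropna(subset=["correct"]).copy()
        df["correct"] = df["correct"].astype(int)
        df["ts"] = (df["session"] == "post").astype(float) - 0.5
        spec = ModelSpec(name="oddity_small", outcome="correct",
                         fixed=["intercept", "ts"], random=["ts"])
        r1 = fit_glmm(spec, df, quad_points=8)
        r2 = fit_glmm(spec, df, quad_points=8)
        assert r1.fallback_level == r2.fallback_level
        assert r1.llf == pytest.approx(r2.llf, abs=1e-9)

    def test_uncorrelated_spec_starts_ladder_below_full(self, small_battery):
        trials = small_battery["trials"]
        df = trials[trials["task"] == "oddity"].dropna(subset=["correct"]).copy()
        df["correct"] = df["correct"].astype(int)
        df["ts"] = (df["session"] == "post").astype(float) - 0.5
        spec = ModelSpec(name="oddity_nc", outcome="correct",
                         fixed=["intercept", "ts"], random=["ts"], correlated=False)
        res = fit_glmm(spec, df, quad_points=8)
        assert res.fallback_level in ("no_correlations", "intercept_only")

    def test_summary_renders(self, small_battery):
        trials = small_battery["trials"]
        df = trials[trials["task"] == "picture_id"].dropna(subset=["correct"]).copy()
        df["correct"] = df["correct"].astype(int)
        spec = ModelSpec(name="pid", outcome="correct", fixed=["intercept"], random=[])
        res = fit_glmm(spec, df, quad_points=8)
        text = res.summary()
        assert "log-likelihood" in text and "intercept" in text


def test_model_spec_filtering_and_unknown_terms(small_battery):
    trials = small_battery["trials"]
    spec = ModelSpec(name="bad", outcome="correct",
                     fixed=["intercept", "no_such_column"], task="picture_id")
    df = trials.dropna(subset=["correct"]).copy()
    df["correct"] = df["correct"].astype(int)
    with pytest.raises(KeyError, match="no_such_column"):
        fit_glmm(spec, df)
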