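"""Offset NB2 fitting, BIC backwards selection and residual diagnostics."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import eaglersf as e
from eaglersf.covariates import ModelSpec
from eaglersf.fit import (backwards_bic, fit_nb, fit_spec, gof_deviance,
                          morans_i, _nb2_deviance_resid, _nb2_loglik)


def nb_data(n=2000, beta=(-1.0, 0.8), theta=2.0, seed=0, offset=None):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    X = pd.DataFrame({"const": np.ones(n), "x": x})
    off = np.zeros(n) if offset is None else offset
    mu = np.exp(beta[0] + beta[1] * x + off)
    y = rng.poisson(rng.gamma(theta, mu / theta))
    return X, y, off


class TestFitNB:
    def test_intercept_only_closed_form(self):
        """All counts 4 with offset 0: the intercept is exactly ln 4."""
        n = 50
        X = pd.DataFrame({"const": np.ones(n)})
        fit = fit_nb(X, np.full(n, 4), offset=np.zeros(n))
        assert fit.params["const"] == pytest.approx(math.log(4), abs=1e-5)

    def test_recovers_known_coefficients(self):
        """Large-sample ML recovery of (-1.0, 0.8) with theta 2."""
        X, y, off = nb_data(seed=7)
        fit = fit_nb(X, y, offset=off)
        assert abs(fit.params["const"] - (-1.0)) <= 3 * fit.bse["const"]
        assert abs(fit.params["x"] - 0.8) <= 3 * fit.bse["x"]
        assert 1.0 < fit.theta < 4.0

    def test_matches_joint_ml_reference(self):
        """Alternating profile fit agrees with joint-ML NB2 estimation."""
        X, y, off = nb_data(n=800, seed=3)
        fit = fit_nb(X, y, offset=off)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.NegativeBinomial(y, X, loglike_method="nb2").fit(disp=0)
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params.iloc[:2], atol=1e-4)
        assert fit.theta == pytest.approx(1.0 / ref.params.iloc[-1], rel=1e-3)
        assert fit.llf == pytest.approx(ref.llf, abs=1e-5)

    def test_offset_shift_is_exact_reparameterisation(self):
        """Adding ln 2 to every offset shifts the intercept by -ln 2 exactly."""
        X, y, off = nb_data(n=600, seed=5)
        f1 = fit_nb(X, y, offset=off)
        f2 = fit_nb(X, y, offset=off + math.log(2))
        assert f2.params["const"] == pytest.approx(f1.params["const"] - math.log(2),
                                                   abs=1e-6)
        assert f2.params["x"] == pytest.approx(f1.params["x"], abs=1e-6)
        assert f2.theta == pytest.approx(f1.theta, rel=1e-4)

    def test_offset_equivariance_on_scaled_counts(self):
        """Counts scaled 5x with offset ln 5 give statistically identical slopes.

        Exact for the Poisson score; for NB2 the dispersion reweighting makes
        it hold to well within one standard error.
        """
        X, y, off = nb_data(n=1500, seed=9)
        f1 = fit_nb(X, y, offset=off)
        f2 = fit_nb(X, y * 5, offset=off + math.log(5))
        assert abs(f2.params["x"] - f1.params["x"]) <= 3 * f1.bse["x"]

    def test_all_zero_response_rejected(self):
        X = pd.DataFrame({"const": np.ones(30)})
        with pytest.raises(ValueError, match="zero"):
            fit_nb(X, np.zeros(30), offset=np.zeros(30))

    def test_non_integer_response_rejected(self):
        X = pd.DataFrame({"const": np.ones(30)})
        with pytest.raises(ValueError, match="integer"):
            fit_nb(X, np.full(30, 1.5))

    def test_bic_convention(self):
        """BIC = -2 ll + (p + 2) ln n with the dispersion counted."""
        X, y, off = nb_data(n=400, seed=2)
        fit = fit_nb(X, y, offset=off)
        k = X.shape[1] + 1
        assert fit.bic == pytest.approx(-2 * fit.llf + k * math.log(400), abs=1e-9)
        assert fit.aic == pytest.approx(-2 * fit.llf + 2 * k, abs=1e-9)
        assert fit.df_resid == 400 - X.shape[1]


class TestDeviance:
    def test_saturated_limit_is_zero(self):
        """Deviance residuals vanish when fitted means equal the counts."""
        y = np.array([1.0, 2.0, 5.0, 3.0])
        r = _nb2_deviance_resid(y, y.copy(), theta=2.0)
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_statistic_matches_termwise_oracle(self):
        """GOF statistic equals the direct term-by-term deviance sum."""
        X, y, off = nb_data(n=300, seed=4)
        fit = fit_nb(X, y, offset=off)
        th, mu = fit.theta, fit.mu
        total = 0.0
        for yi, mi in zip(y, mu):
            t1 = yi * math.log(yi / mi) if yi > 0 else 0.0
            t2 = (yi + th) * math.log((yi + th) / (mi + th))
            total += 2 * (t1 - t2)
        stat, df, p = gof_deviance(fit)
        assert stat == pytest.approx(total, rel=1e-10)
        assert df == fit.df_resid
        assert 0.0 <= p <= 1.0


class TestBackwardsBIC:
    def test_zero_likelihood_change_deletion_costs_ln_n(self):
        """Removing a parameter at unchanged likelihood drops BIC by ln n."""
        n = 1845
        llf = -1500.0
        bic_full = -2 * llf + (8 + 1) * math.log(n)
        bic_red = -2 * llf + (7 + 1) * math.log(n)
        assert bic_full - bic_red == pytest.approx(math.log(1845), rel=1e-12)

    def test_hierarchy_never_violated_and_trace_monotone(self):
        """Quadratics cannot orphan their parents; BIC trace non-increasing."""
        rng = np.random.default_rng(21)
        n = 1200
        cov = pd.DataFrame({
            "a": rng.standard_normal(n), "b": rng.standard_normal(n),
            "noise1": rng.standard_normal(n), "noise2": rng.standard_normal(n),
        })
        mu = np.exp(-0.5 + 0.7 * cov["a"] - 0.3 * cov["a"] ** 2 + 0.6 * cov["b"]) * 3
        y = rng.poisson(rng.gamma(1.5, mu / 1.5))
        off = np.log(np.full(n, 3.0))
        spec = ModelSpec(("a", "a^2", "b", "b^2", "noise1", "noise2"))
        final, trace = backwards_bic(cov, y, off, spec)
        assert (np.diff(trace["bic"].to_numpy()) <= 1e-9).all()
        # reconstruct the surviving term set at each step; check hierarchy
        terms = set(spec.terms)
        for removed in trace["removed"].dropna():
            terms.discard(removed)
            for t in terms:
                if t.endswith("^2"):
                    assert t[:-2] in terms
        assert set(final.spec.terms) == terms

    def test_strong_effects_survive_noise_removed(self):
        rng = np.random.default_rng(22)
        n = 1500
        cov = pd.DataFrame({"s": rng.standard_normal(n),
                            "junk": rng.standard_normal(n)})
        mu = np.exp(-0.3 + 0.9 * cov["s"]) * 2
        y = rng.poisson(rng.gamma(1.5, mu / 1.5))
        final, trace = backwards_bic(cov, y, np.zeros(n), ModelSpec(("s", "junk")))
        assert "s" in final.spec.terms
        assert "junk" not in final.spec.terms

    def test_coefficient_stability_monitor_reported(self):
        rng = np.random.default_rng(23)
        n = 600
        cov = pd.DataFrame({"s": rng.standard_normal(n),
                            "junk": rng.standard_normal(n)})
        y = rng.poisson(np.exp(0.2 + 0.8 * cov["s"]))
        y[0] = max(y[0], 1)
        _, trace = backwards_bic(cov, y, np.zeros(n), ModelSpec(("s", "junk")))
        removed_steps = trace[trace["removed"].notna()]
        assert (removed_steps["max_rel_coef_change"] >= 0).all()


class TestMoransI:
    def test_antisymmetric_pair_gives_minus_one(self):
        I, flagged = morans_i([1.5, -1.5], [(0.0, 0.0), (10.0, 0.0)], radius_km=200)
        assert I == pytest.approx(-1.0)
        assert not flagged

    def test_matches_bruteforce_double_sum(self):
        """Five fixed units: I equals the direct double-sum formula."""
        resid = np.array([0.5, -1.2, 0.3, 2.0, -0.7])
        pts = np.array([(0, 0), (50, 0), (120, 0), (400, 0), (130, 90)], float)
        I, _ = morans_i(resid, pts, radius_km=200)
        z = resid - resid.mean()
        num = 0.0
        wsum = 0.0
        for i in range(5):
            for j in range(5):
                d = math.dist(pts[i], pts[j])
                w = 1.0 if 0 < d <= 200 else 0.0
                num += w * z[i] * z[j]
                wsum += w
        oracle = (5 / wsum) * num / (z @ z)
        assert I == pytest.approx(oracle, rel=1e-12)

    def test_permutation_expectation(self):
        """Mean I over residual permutations approaches -1/(n-1)."""
        rng = np.random.default_rng(30)
        n = 40
        pts = rng.uniform(0, 500, size=(n, 2))
        resid = rng.standard_normal(n)
        vals = []
        for _ in range(300):
            I, _ = morans_i(rng.permutation(resid), pts, radius_km=200)
            vals.append(I)
        vals = np.asarray(vals)
        mc_se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean() - (-1 / (n - 1))) <= 3 * mc_se

    def test_row_standardized_bounded(self):
        rng = np.random.default_rng(31)
        pts = rng.uniform(0, 300, size=(30, 2))
        I, _ = morans_i(rng.standard_normal(30), pts, radius_km=200,
                        row_standardize=True)
        assert -1.0 - 1e-9 <= I <= 1.0 + 1e-9

    def test_no_neighbours_rejected(self):
        with pytest.raises(ValueError, match="no neighbour"):
            morans_i([1.0, -1.0], [(0, 0), (500, 0)], radius_km=200)

    def test_flag_threshold(self):
        """Strong positive clustering of residuals trips the 0.20 flag."""
        pts = np.array([[i * 10.0, 0.0] for i in range(20)])
        resid = np.where(np.arange(20) < 10, 2.0, -2.0) + 0.01 * np.arange(20)
        I, flagged = morans_i(resid, pts, radius_km=50)
        assert I > 0.20 and flagged


class TestFitOnPipelineData:
    def test_pipeline_fit_converges(self, demo_study, demo_fit):
        assert demo_fit.converged
        assert np.isfinite(demo_fit.params).all()
        assert demo_fit.nobs == len(demo_study.counts)

    def test_gof_on_pipeline_fit(self, demo_fit):
        stat, df, p = gof_deviance(demo_fit)
        assert df == demo_fit.nobs - 5
        assert 0 <= p <= 1
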