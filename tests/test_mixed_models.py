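"""Tests for aggregation, the Poisson GLMM, bootstrap and linear models."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from rootpatch import mixed_models as mm
from rootpatch.spatial_stats import MoranResult


def sim_blocks(rng, beta=0.3, site_sd=0.3, n_sites=12, n_blocks=10,
               regions=("R1",), beta0=0.0):
    """Block-level data drawn exactly from the fitted model's assumptions."""
    rows = []
    reg = np.resize(list(regions), n_sites)
    for s in range(n_sites):
        x = rng.normal(0, 1, n_blocks)
        b = rng.normal(0, site_sd)
        mu = np.exp(beta0 + b + beta * x)
        rows.append(pd.DataFrame({
            "site_id": f"S{s:02d}", "region_id": reg[s],
            "count": rng.poisson(mu), "x": x}))
    return pd.concat(rows, ignore_index=True)


class TestAggregateBlocks:
    def test_sums_and_shape(self):
        counts = np.zeros(30, dtype=int)
        counts[:3] = [1, 0, 2]
        preds = pd.DataFrame({"p": np.ones(30)})
        agg = mm.aggregate_blocks(counts, preds, "S1", "R1")
        assert len(agg.blocks) == 10
        assert agg.blocks["count"].iloc[0] == 3
        assert (agg.blocks["count"].iloc[1:] == 0).all()
        assert (agg.blocks["p"] == 1.0).all()

    def test_conserves_total(self, rng):
        counts = rng.poisson(1.0, 30)
        preds = pd.DataFrame({"p": rng.normal(size=30)})
        agg = mm.aggregate_blocks(counts, preds)
        assert agg.blocks["count"].sum() == counts.sum()

    def test_nan_poisons_block(self, rng):
        counts = rng.poisson(1.0, 30)
        p = rng.normal(size=30)
        p[4] = np.nan                      # second block (plots 3-5)
        agg = mm.aggregate_blocks(counts, pd.DataFrame({"p": p}))
        assert np.isnan(agg.blocks["p"].iloc[1])
        assert agg.blocks["p"].iloc[0] == pytest.approx(p[:3].mean())

    def test_trailing_block_dropped_with_warning(self, rng):
        counts = rng.poisson(1.0, 31)
        preds = pd.DataFrame({"p": rng.normal(size=31)})
        with pytest.warns(UserWarning, match="incomplete block"):
            agg = mm.aggregate_blocks(counts, preds)
        assert len(agg.blocks) == 10
        assert agg.blocks["count"].sum() == counts[:30].sum()


class TestExcludeSites:
    def test_identity_when_none_significant(self):
        res = {f"S{i}": MoranResult(0.0, -0.1, 0.5) for i in range(4)}
        kept, report = mm.exclude_autocorrelated_sites(res)
        assert len(kept) == 4 and not report["excluded"].any()

    def test_all_significant(self):
        res = {f"S{i}": MoranResult(0.5, -0.1, 0.001) for i in range(4)}
        kept, report = mm.exclude_autocorrelated_sites(res)
        assert kept == [] and report["excluded"].all()


class TestPoissonGLMM:
    def test_glm_oracle_equivalence(self, rng):
        """With the random-effect variance pinned at 0 the fit matches IRLS."""
        df = sim_blocks(rng, beta=0.25, site_sd=0.0, regions=("R1", "R2"))
        fit = mm.fit_poisson_glmm(df, "x", standardize=False, var_site=0)
        X = np.column_stack([(df["region_id"] == "R1").astype(float),
                             (df["region_id"] == "R2").astype(float),
                             df["x"]])
        oracle = sm.GLM(df["count"].to_numpy(), X,
                        family=sm.families.Poisson()).fit()
        ours = np.array([fit.region_intercepts["R1"],
                         fit.region_intercepts["R2"], fit.slope])
        np.testing.assert_allclose(ours, oracle.params, rtol=1e-6)
        assert fit.mean_intercept == pytest.approx(
            np.mean(list(fit.region_intercepts.values())))

    def test_laplace_close_to_agq(self, rng):
        df = sim_blocks(rng, beta=0.3, site_sd=0.4, n_sites=16)
        f_lap = mm.fit_poisson_glmm(df, "x", standardize=False)
        f_agq = mm.fit_poisson_glmm(df, "x", standardize=False, method="agq")
        assert f_lap.slope == pytest.approx(f_agq.slope, abs=5e-3)
        assert f_lap.loglik == pytest.approx(f_agq.loglik, abs=0.05)

    def test_chi2_positive_for_real_effect(self, rng):
        df = sim_blocks(rng, beta=0.8, site_sd=0.2, n_sites=16)
        fit = mm.fit_poisson_glmm(df, "x", standardize=False)
        assert fit.chi2 > 10

    def test_all_zero_counts_rejected(self):
        df = pd.DataFrame({"site_id": ["a"] * 5 + ["b"] * 5,
                           "region_id": "R1", "count": 0,
                           "x": np.arange(10.0)})
        with pytest.raises(ValueError):
            mm.fit_poisson_glmm(df, "x")

    def test_single_site_rejected(self, rng):
        df = sim_blocks(rng, n_sites=1)
        with pytest.raises(ValueError):
            mm.fit_poisson_glmm(df, "x")


class TestConditionalR2:
    def test_zero_when_no_effect_no_variance(self):
        rng = np.random.default_rng(0)
        df = sim_blocks(rng, beta=0.0, site_sd=0.0, n_sites=10)
        fit = mm.fit_poisson_glmm(df, None, var_site=0)
        # single region, intercept only: no fixed or random variance
        assert mm.conditional_r2(fit) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_site_variance(self, rng):
        df = sim_blocks(rng, beta=0.2, site_sd=0.3, n_sites=12)
        fit = mm.fit_poisson_glmm(df, "x", standardize=False)
        r2 = []
        for v in (0.0, 0.2, 0.5, 1.0):
            fit.var_site = v
            r2.append(mm.conditional_r2(fit))
        assert all(np.diff(r2) > 0)
        assert all(0 <= r <= 1 for r in r2)

    def test_matches_hand_computation(self, rng):
        df = sim_blocks(rng, beta=0.4, site_sd=0.2, n_sites=12)
        fit = mm.fit_poisson_glmm(df, "x", standardize=False)
        eta = fit._X @ fit._params[:-1]
        vf = np.var(eta)
        lam = np.mean(np.exp(eta + fit.var_site / 2))
        ve = np.log1p(1 / lam)
        expected = (vf + fit.var_site) / (vf + fit.var_site + ve)
        assert fit.r2 == pytest.approx(expected, rel=1e-12)
        # trigamma variant is close but not identical
        alt = mm.conditional_r2(fit, resid_variance="trigamma")
        assert 0 <= alt <= 1


class TestParametricBootstrap:
    def test_identical_models_give_p_one(self, rng):
        df = sim_blocks(rng, beta=0.0, site_sd=0.2)
        fit = mm.fit_poisson_glmm(df, "x", standardize=False)
        p, _ = mm.parametric_bootstrap_p(fit, fit, n_boot=49, seed=1)
        assert p == pytest.approx(1.0, abs=0.03)

    def test_strong_effect_hits_floor(self, rng):
        df = sim_blocks(rng, beta=1.0, site_sd=0.2, n_sites=12)
        full = mm.fit_poisson_glmm(df, "x", standardize=False)
        red = mm.fit_poisson_glmm(df, None)
        p, failed = mm.parametric_bootstrap_p(full, red, n_boot=99, seed=2)
        assert p == pytest.approx(1 / (100 - failed), abs=1e-9)


class TestRankPredictors:
    def test_headline_order(self):
        fits = []
        for name, slope in (("sla", 0.283), ("leaf_cn", -0.260),
                            ("rh", 0.193)):
            fits.append(mm.GLMMFit(predictor=name, region_intercepts={},
                                   mean_intercept=0.37, slope=slope,
                                   var_site=0.1, loglik=0.0))
        table = mm.rank_predictors(fits)
        assert list(table["predictor"]) == ["sla", "leaf_cn", "rh"]

    def test_tie_break_stable_by_name(self):
        fits = [mm.GLMMFit(predictor=n, region_intercepts={},
                           mean_intercept=0, slope=s, var_site=0, loglik=0)
                for n, s in (("b", 0.2), ("a", -0.2), ("c", 0.1))]
        table = mm.rank_predictors(fits)
        assert list(table["predictor"]) == ["a", "b", "c"]


def sim_mcc(rng, n_sites=14, n_classes=10, dist_effect=0.0, noise=0.05):
    rows = []
    lui = rng.uniform(0.5, 3.5, n_sites)
    whc = rng.uniform(30, 90, n_sites)
    d = np.linspace(0.36, 7.86, n_classes)
    for s in range(n_sites):
        r = dist_effect * (d - d.mean()) + rng.normal(0, noise, n_classes) \
            + rng.normal(0, noise / 2)
        for k in range(n_classes):
            rows.append({"site_id": f"S{s:02d}", "distance": d[k], "r": r[k]})
    mcc = pd.DataFrame(rows)
    cov = pd.DataFrame({"site_id": [f"S{s:02d}" for s in range(n_sites)],
                        "lui": lui, "whc": whc})
    return mcc, cov


class TestMccLmm:
    def test_distance_effect_retained(self):
        """A real distance trend survives backward selection; the inert
        covariates are usually (not always) cleared out."""
        kept, clean = 0, 0
        for rep in range(6):
            rng = np.random.default_rng(300 + rep)
            mcc, cov = sim_mcc(rng, dist_effect=-0.04)
            fit = mm.fit_mcc_lmm(mcc, cov, p_method="lrt")
            kept += "distance" in fit.retained
            clean += ("distance" in fit.retained
                      and "lui" not in fit.retained
                      and "whc" not in fit.retained)
        assert kept >= 5
        assert clean >= 2

    def test_null_mostly_empties_the_model(self):
        """Without any covariate effect backward selection usually removes
        every fixed term; asymptotic LRT p-values keep an occasional
        spurious term, so the bound is a majority-style one."""
        clean, n_terms = 0, []
        for rep in range(12):
            rng = np.random.default_rng(400 + rep)
            mcc, cov = sim_mcc(rng, dist_effect=0.0)
            fit = mm.fit_mcc_lmm(mcc, cov, p_method="lrt")
            clean += not fit.retained
            n_terms.append(len(fit.retained))
        assert clean >= 4
        assert np.mean(n_terms) <= 1.5

    def test_bootstrap_term_test_calibrated(self):
        """Parametric-bootstrap p for one Gaussian LMM term: rejection
        rate under the null stays near the nominal 5%."""
        rejections = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(500 + rep)
            mcc, cov = sim_mcc(rng, n_sites=8, n_classes=6, dist_effect=0.0)
            df = mcc.merge(cov, on="site_id")
            for col in ("lui", "whc", "distance"):
                x = df[col].to_numpy(float)
                df[col] = (x - x.mean()) / x.std(ddof=1)
            p = mm._lmm_term_p(df, ["distance"], "distance", "bootstrap",
                               n_boot=99, rng=rng)
            rejections += p <= 0.05
        assert rejections <= 4   # 95% binomial envelope around 0.05

    def test_single_site_rejected(self):
        rng = np.random.default_rng(1)
        mcc, cov = sim_mcc(rng, n_sites=1)
        with pytest.raises(ValueError):
            mm.fit_mcc_lmm(mcc, cov, p_method="lrt")

    def test_empty_input_gives_empty_result(self):
        fit = mm.fit_mcc_lmm(pd.DataFrame(columns=["site_id", "distance", "r"]),
                             pd.DataFrame(columns=["site_id", "lui", "whc"]))
        assert fit.empty and fit.retained == []


class TestSiteLevelLm:
    def test_exact_relationship(self):
        df = pd.DataFrame({"lui": np.linspace(0.5, 3.5, 10)})
        df["y"] = 2 * df["lui"]
        r2, p = mm.fit_site_level_lm(df, "y")
        assert r2 == pytest.approx(1.0)
        assert p < 1e-10

    def test_null_r2_expectation(self):
        """Under independence E[R2] = 1/(n-1) for simple regression."""
        rng = np.random.default_rng(8)
        n = 28
        lui = rng.uniform(0.5, 3.5, n)
        r2s = []
        for _ in range(500):
            df = pd.DataFrame({"lui": lui, "y": rng.normal(size=n)})
            r2s.append(mm.fit_site_level_lm(df, "y")[0])
        assert np.mean(r2s) == pytest.approx(1 / (n - 1), abs=0.012)

    def test_constant_lui_rejected(self):
        df = pd.DataFrame({"lui": [1.0] * 5, "y": np.arange(5.0)})
        with pytest.raises(ValueError):
            mm.fit_site_level_lm(df, "y")
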