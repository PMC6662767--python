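"""Statistical battery: AR(1) z-test, SMA, mixed model, slopes, day-wise."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest

import vocalshift as vs
from vocalshift.stats import (ar1_ztest, bonferroni_alpha, daywise_matrix,
                              lag1_autocorr, mixed_ar1_fit, naive_ztest_p,
                              parameter_slopes, simulate_ar1, slope_rcb_anova,
                              sma_test, variance_inflation)


class TestLag1:
    def test_alternating_series(self):
        x = np.tile([1.0, -1.0], 50)
        assert lag1_autocorr(x) == pytest.approx(-1.0, abs=0.02)

    def test_iid_near_zero(self):
        x = np.random.default_rng(8).standard_normal(10000)
        assert abs(lag1_autocorr(x)) < 0.03

    def test_ar1_recovered(self):
        x = simulate_ar1(1, 10000, 0.4, 1.0, np.random.default_rng(9))[0]
        assert lag1_autocorr(x) == pytest.approx(0.4, abs=0.03)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            lag1_autocorr(np.ones(10))
        with pytest.raises(ValueError):
            lag1_autocorr(np.array([1.0, 2.0]))


class TestAR1ZTest:
    def test_identical_series(self):
        a = np.sin(np.arange(20.0))      # same series twice: no difference
        r = ar1_ztest(a, a)
        assert r.mean_diff == 0.0
        assert r.z == 0.0
        assert r.p == 1.0

    def test_se_formula_contract(self, rng):
        a = rng.normal(size=50)
        b = rng.normal(size=60)
        r = ar1_ztest(a, b)
        expected = r.pooled_sd * np.sqrt(1 / 50 + 1 / 60) * \
            variance_inflation(r.r1)
        assert r.corrected_se == pytest.approx(expected)

    def test_reduces_to_classical_at_zero_r1(self, rng):
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        r = ar1_ztest(a, b)
        # with the correction factor divided out, the naive p is recovered
        z_naive = r.mean_diff / (r.pooled_sd * np.sqrt(2 / 200))
        from scipy.stats import norm
        assert naive_ztest_p(a, b) == pytest.approx(
            2 * norm.sf(abs(z_naive)))
        assert variance_inflation(0.0) == 1.0

    def test_inflation_strictly_increasing(self):
        grid = np.linspace(0.0, 0.9, 10)
        vals = [variance_inflation(r) for r in grid]
        assert np.all(np.diff(vals) > 0)

    def test_null_calibration_beats_naive(self):
        rng = np.random.default_rng(21)
        n_rep = 400
        a = simulate_ar1(n_rep, 90, 0.4, 1.0, rng)
        b = simulate_ar1(n_rep, 90, 0.4, 1.0, rng)
        rej = np.mean([ar1_ztest(a[i], b[i]).p < 0.05 for i in range(n_rep)])
        rej_naive = np.mean([naive_ztest_p(a[i], b[i]) < 0.05
                             for i in range(n_rep)])
        assert 0.02 <= rej <= 0.09
        assert rej_naive > 0.10

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            ar1_ztest(np.array([1.0, 2.0]), np.arange(5.0))


class TestSMA:
    def test_extreme_separation(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(10, 1, 30)       # 10 pooled sd apart
        r = sma_test(a, b, iterations=2000, seed=4)
        assert r.p_empirical <= 1.0 / 1000
        assert r.mean_diff == pytest.approx(10.0, abs=1.0)
        assert r.R > 0.9

    def test_seed_reproducibility(self, rng):
        a = rng.normal(size=25)
        b = rng.normal(size=25)
        r1 = sma_test(a, b, iterations=2000, seed=11)
        r2 = sma_test(a, b, iterations=2000, seed=11)
        assert r1 == r2

    def test_agrees_with_ztest_asymptotically(self):
        rng = np.random.default_rng(31)
        a = simulate_ar1(1, 500, 0.4, 1.0, rng)[0]
        b = simulate_ar1(1, 500, 0.4, 1.0, rng)[0] + 0.1
        p_sma = sma_test(a, b, iterations=20000, seed=2).p_empirical
        p_z = ar1_ztest(a, b).p
        assert abs(p_sma - p_z) < 0.03

    def test_validation(self):
        with pytest.raises(ValueError):
            sma_test(np.array([]), np.arange(5.0))
        with pytest.raises(ValueError):
            sma_test(np.arange(5.0), np.arange(5.0), iterations=0)


def _mixed_fixture(nbins=40, shift=3.0, seed=1, rho=0.4):
    rng = np.random.default_rng(seed)
    rows = []
    for g in ("g1", "g2", "g3", "g4"):
        off = rng.normal(0, 0.5)
        for cond, mu in (("baseline", 10.0), ("post", 10.0 + shift)):
            y = mu + off + simulate_ar1(1, nbins, rho, 1.0, rng)[0]
            rows += [{"group": g, "condition": cond, "bin_index": i,
                      "centroid_hz": v} for i, v in enumerate(y)]
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_matches_nlme_oracle(self, tmp_path):
        # independent oracle: R nlme::lme with corAR1 residuals on the
        # identical data set, REML
        df = _mixed_fixture()
        csv = tmp_path / "fixture.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "check.R"
        script.write_text(textwrap.dedent(f"""
            library(nlme)
            d <- read.csv("{csv}")
            d$post <- as.integer(d$condition != "baseline")
            d$series <- paste(d$group, d$condition)
            m <- lme(centroid_hz ~ post, random = ~1 | group,
                     correlation = corAR1(form = ~ bin_index | group/series),
                     data = d, method = "REML")
            cat(fixef(m)["post"], sqrt(vcov(m)["post","post"]),
                coef(m$modelStruct$corStruct, unconstrained=FALSE), "\\n")
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        eff_r, se_r, rho_r = map(float, out.stdout.split()[-3:])
        res = mixed_ar1_fit(df)
        assert res.effect == pytest.approx(eff_r, rel=1e-3)
        assert res.se == pytest.approx(se_r, rel=1e-2)
        assert res.rho == pytest.approx(rho_r, abs=0.02)

    def test_single_group_rejected(self):
        df = _mixed_fixture()
        with pytest.raises(ValueError):
            mixed_ar1_fit(df[df.group == "g1"])

    def test_missing_condition_rejected(self):
        df = _mixed_fixture()
        df = df[~((df.group == "g2") & (df.condition == "post"))]
        with pytest.raises(ValueError):
            mixed_ar1_fit(df)

    def test_translation_equivariance(self):
        df = _mixed_fixture(nbins=20)
        base = mixed_ar1_fit(df)
        shifted = df.copy()
        shifted.loc[shifted.condition == "post", "centroid_hz"] += 5.0
        res = mixed_ar1_fit(shifted)
        assert res.effect == pytest.approx(base.effect + 5.0, abs=1e-3)

    def test_coverage_of_true_effect(self):
        from scipy.stats import t as tdist
        cover = 0
        n_rep = 60
        for i in range(n_rep):
            res = mixed_ar1_fit(_mixed_fixture(nbins=20, seed=300 + i))
            tc = tdist.ppf(0.975, res.df)
            cover += (res.effect - tc * res.se <= 3.0
                      <= res.effect + tc * res.se)
        # nominal 95%: binomial(60, .95) puts ~99.9% of mass at >= 51
        assert cover >= 51


class TestSlopes:
    def test_constant_series_zero_slope(self):
        bins = pd.DataFrame({"bin_index": np.arange(10),
                             "centroid_hz": np.full(10, 4.0)})
        s = parameter_slopes(bins, ["centroid_hz"])
        assert s["centroid_hz"] == pytest.approx(0.0, abs=1e-12)

    def test_linear_series_exact_slope(self):
        bins = pd.DataFrame({"bin_index": np.arange(10),
                             "centroid_hz": 2.0 * np.arange(10)})
        s = parameter_slopes(bins, ["centroid_hz"])
        assert s["centroid_hz"] == pytest.approx(2.0)

    def test_stationary_slope_near_zero(self):
        hits = 0
        n_rep = 100
        for i in range(n_rep):
            rng = np.random.default_rng(500 + i)
            n = 40
            y = simulate_ar1(1, n, 0.2, 1.0, rng)[0]
            bins = pd.DataFrame({"bin_index": np.arange(n), "v": y})
            slope = parameter_slopes(bins, ["v"])["v"]
            # OLS slope SE for AR(1) data, first-order corrected
            x = np.arange(n) - (n - 1) / 2
            se = np.sqrt(1.0 / np.sum(x ** 2)) * variance_inflation(0.2)
            hits += abs(slope) <= 2 * se
        assert hits >= 85                 # ≈95% nominal

    def test_too_few_bins(self):
        with pytest.raises(ValueError):
            parameter_slopes(pd.DataFrame({"bin_index": [0, 1],
                                           "v": [1.0, 2.0]}), ["v"])


class TestSlopeAnova:
    def test_zero_table(self):
        tbl = pd.DataFrame(np.zeros((4, 11)),
                           columns=[f"p{i}" for i in range(11)])
        res = slope_rcb_anova(tbl)
        assert res.F == 0.0
        np.testing.assert_allclose(res.table.mean_diff, 0.0)
        assert np.allclose(res.table.ci_low, -res.table.ci_high)

    def test_bonferroni_ci_level(self):
        tbl = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 11)),
                           columns=[f"p{i}" for i in range(11)])
        res = slope_rcb_anova(tbl, alpha=0.05)
        assert res.ci_level == pytest.approx(1 - 0.05 / 11)
        assert round(res.ci_level, 4) == 0.9955   # the reported 99.55%

    def test_null_p_uniformity(self):
        from scipy.stats import kstest
        ps = []
        for i in range(200):
            rng = np.random.default_rng(700 + i)
            tbl = pd.DataFrame(rng.normal(size=(4, 11)),
                               columns=[f"p{i}" for i in range(11)])
            ps.append(slope_rcb_anova(tbl).p)
        assert kstest(ps, "uniform").statistic < 0.1

    def test_missing_cells_rejected(self):
        tbl = pd.DataFrame(np.zeros((4, 3)), columns=list("abc"))
        tbl.iloc[1, 2] = np.nan
        with pytest.raises(ValueError):
            slope_rcb_anova(tbl)


class TestBonferroni:
    @pytest.mark.parametrize("alpha,k,expected", [
        (0.05, 11, 0.0045),
        (0.05, 1, 0.05),
        (0.05, 2, 0.025),
    ])
    def test_values(self, alpha, k, expected):
        assert bonferroni_alpha(alpha, k) == expected

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestDaywise:
    def _frame(self, shift, rng, n_days=4, bins_per_day=10):
        rows = []
        for cond, mu in (("baseline", 0.0), ("post", shift)):
            for d in range(n_days):
                for v in rng.normal(mu, 1.0, bins_per_day):
                    rows.append({"condition": cond, "day": d,
                                 "centroid_hz": v})
        return pd.DataFrame(rows)

    def test_identical_days_not_significant(self, rng):
        df = self._frame(0.0, rng)
        m = daywise_matrix(df, alpha=0.0045)
        assert (m.n_sig_vs_other == 0).all()

    def test_large_shift_significant_everywhere(self, rng):
        df = self._frame(10.0, rng)
        m = daywise_matrix(df, alpha=0.0045)
        assert (m.n_sig_vs_other == m.n_days_other).all()
        assert (m.n_sig_vs_same == 0).all()

    def test_sparse_day_excluded(self, rng):
        df = self._frame(10.0, rng)
        df = pd.concat([df, pd.DataFrame([{"condition": "post", "day": 99,
                                           "centroid_hz": 1.0}])])
        m = daywise_matrix(df, alpha=0.0045)
        assert 99 not in set(m.day)
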