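import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, special, stats

from cotwin.datamodel import ConfigError, PipelineError
from cotwin.paired import (
    bh_adjust,
    moderated_t_test,
    paired_t_test,
    percent_significant,
    round_half_up,
    signflip_permutation_test,
    volcano_table,
)

from conftest import make_diffs


def closed_form_t_pvalue_df2(t: float) -> float:
    """Two-sided p for Student's t with 2 df: CDF(x) = 1/2 + x / (2*sqrt(2)*sqrt(1+x^2/2))."""
    cdf = 0.5 + t / (2.0 * math.sqrt(2.0) * math.sqrt(1.0 + t * t / 2.0))
    return 2.0 * (1.0 - cdf)


class TestPairedT:
    def test_example_1_2_3(self):
        res = paired_t_test(make_diffs([1.0, 2.0, 3.0]))
        assert res["t"].iloc[0] == pytest.approx(3.4641016, abs=1e-6)
        assert res["df"].iloc[0] == 2
        expected_p = closed_form_t_pvalue_df2(3.4641016151377544)
        assert expected_p == pytest.approx(0.0742, abs=5e-5)
        assert res["p_raw"].iloc[0] == pytest.approx(expected_p, abs=1e-10)

    def test_symmetric_diffs_give_t_zero(self):
        res = paired_t_test(make_diffs([-1.0, 1.0]))
        assert res["t"].iloc[0] == 0.0
        assert res["p_raw"].iloc[0] == 1.0

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0, 1, (20, 8))
        res = paired_t_test(make_diffs(d))
        ref = stats.ttest_1samp(d, 0.0, axis=1)
        np.testing.assert_allclose(res["t"], ref.statistic, rtol=1e-12)
        np.testing.assert_allclose(res["p_raw"], ref.pvalue, rtol=1e-12)

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_negation_symmetry(self, d):
        res = paired_t_test(make_diffs(d))
        neg = paired_t_test(make_diffs([-x for x in d]))
        t0, t1 = res["t"].iloc[0], neg["t"].iloc[0]
        if np.isnan(t0):
            assert np.isnan(t1)
        else:
            assert t1 == pytest.approx(-t0, rel=1e-12, abs=1e-12)
            assert neg["p_raw"].iloc[0] == pytest.approx(res["p_raw"].iloc[0], rel=1e-12)

    def test_zero_variance_gives_na(self):
        res = paired_t_test(make_diffs([[0.5, 0.5, 0.5], [1.0, 2.0, 3.0]]))
        assert np.isnan(res["t"].iloc[0]) and np.isnan(res["p_raw"].iloc[0])
        assert np.isfinite(res["t"].iloc[1])

    def test_single_pair_rejected(self):
        with pytest.raises(ConfigError, match=">= 2"):
            paired_t_test(make_diffs([[1.0]]))


def bh_reference(p):
    """Quadratic-time BH: adj_i = min over j with p_j >= p_i of m*p_(j)/rank(j)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    for rank_pos, i in enumerate(order, start=1):
        candidates = []
        for rank_j in range(rank_pos, m + 1):
            j = order[rank_j - 1]
            candidates.append(m * p[j] / rank_j)
        adj[i] = min(1.0, min(candidates))
    return adj


class TestBhAdjust:
    def test_stepup_hand_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out["p_adj"], [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        out = bh_adjust([1.0, 1.0, 1.0])
        np.testing.assert_allclose(out["p_adj"], 1.0)

    def test_single_p_unchanged(self):
        out = bh_adjust([0.123])
        assert out["p_adj"].iloc[0] == pytest.approx(0.123)

    def test_monotone_in_raw_order(self):
        out = bh_adjust([0.001, 0.5, 0.04])
        assert out["p_adj"].iloc[0] <= out["p_adj"].iloc[2] <= out["p_adj"].iloc[1]

    def test_invalid_p_rejected(self):
        with pytest.raises(ConfigError, match=r"\[0, 1\]"):
            bh_adjust([0.5, 1.5])

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(out["p_adj"].iloc[1])
        # m counts only the finite entries
        np.testing.assert_allclose(out["p_adj"].dropna(), [0.02, 0.02])

    def test_matches_quadratic_reference_1000_draws(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            m = int(rng.integers(1, 12))
            p = rng.uniform(0, 1, m).round(3).tolist()
            out = bh_adjust(p)
            np.testing.assert_allclose(out["p_adj"], bh_reference(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 200)
        out = bh_adjust(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(out["p_adj"], ref, atol=1e-12)


def brute_force_signflip_p(d):
    n = len(d)

    def tstat(v):
        m = sum(v) / n
        var = sum((x - m) ** 2 for x in v) / (n - 1)
        if var == 0.0:
            return 0.0 if m == 0 else math.copysign(math.inf, m)
        return m / math.sqrt(var / n)

    t_obs = abs(tstat(d))
    count = 0
    for signs in itertools.product((1.0, -1.0), repeat=n):
        if abs(tstat([s * x for s, x in zip(signs, d)])) >= t_obs * (1 - 1e-12):
            count += 1
    return count / 2**n


class TestSignflip:
    def test_example_1_2_3(self):
        res = signflip_permutation_test(make_diffs([1.0, 2.0, 3.0]))
        assert res["p_perm"].iloc[0] == 0.25
        assert res["n_arrangements"].iloc[0] == 8

    def test_global_flip_lower_bound(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0, 1, (20, 6))
        res = signflip_permutation_test(make_diffs(d))
        assert (res["p_perm"] >= 2 / 2**6).all()

    def test_exhaustive_cap(self):
        d = np.zeros((1, 21))
        with pytest.raises(ConfigError, match="montecarlo"):
            signflip_permutation_test(make_diffs(d), cap=20)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        for n in range(2, 9):
            d = rng.normal(0, 1, n)
            res = signflip_permutation_test(make_diffs(d))
            assert res["p_perm"].iloc[0] == brute_force_signflip_p(d.tolist())

    def test_montecarlo_seeded_and_consistent(self):
        rng = np.random.default_rng(4)
        d = rng.normal(0.5, 1, 12)
        a = signflip_permutation_test(make_diffs(d), mode="montecarlo", B=2000, seed=9)
        b = signflip_permutation_test(make_diffs(d), mode="montecarlo", B=2000, seed=9)
        assert a["p_perm"].iloc[0] == b["p_perm"].iloc[0]
        exact = signflip_permutation_test(make_diffs(d))
        assert a["p_perm"].iloc[0] == pytest.approx(exact["p_perm"].iloc[0], abs=0.03)

    def test_rank_concordant_with_t_pvalues(self):
        rng = np.random.default_rng(21)
        d = rng.normal(0.0, 1.0, (200, 17)) + rng.normal(0, 0.3, (200, 1))
        diffs = make_diffs(d)
        perm = signflip_permutation_test(diffs)
        tres = paired_t_test(diffs)
        rho = stats.spearmanr(perm["p_perm"], tres["p_raw"]).statistic
        assert rho > 0.99


class TestModeratedT:
    def test_prior_df_zero_equals_ordinary_t(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0, 1, (50, 7))
        diffs = make_diffs(d)
        res, hyper = moderated_t_test(diffs, prior_df=0.0)
        ref = paired_t_test(diffs)
        np.testing.assert_allclose(res["t_moderated"], ref["t"], rtol=1e-12)
        np.testing.assert_allclose(res["p_raw"], ref["p_raw"], rtol=1e-12)

    def test_constant_variances_give_infinite_prior_df(self):
        rng = np.random.default_rng(7)
        base = rng.normal(0, 1, 6)
        base = (base - base.mean()) / base.std(ddof=1)  # unit variance exactly
        d = np.array([base * 1.0 + mu for mu in np.linspace(-1, 1, 30)])
        res, hyper = moderated_t_test(make_diffs(d))
        assert math.isinf(hyper["d0"])
        # moment estimator applies the log-variance bias correction:
        # s0^2 = s_g^2 * exp(log(df/2) - digamma(df/2)) for df = n - 1
        s0_expected = math.exp(math.log(2.5) - special.digamma(2.5))
        assert hyper["s0_sq"] == pytest.approx(s0_expected, rel=1e-9)
        # t~ = mean/(s0/sqrt(n)) with normal p-values
        expected_t = d.mean(axis=1) / math.sqrt(s0_expected / 6)
        np.testing.assert_allclose(res["t_moderated"], expected_t, rtol=1e-9)
        np.testing.assert_allclose(
            res["p_raw"], 2 * stats.norm.sf(np.abs(expected_t)), rtol=1e-9
        )

    def test_hyperparameters_match_independent_moment_solve(self):
        rng = np.random.default_rng(8)
        n, G = 9, 200
        scale = np.exp(rng.normal(-1, 0.8, G))
        d = rng.normal(0, 1, (G, n)) * scale[:, None]
        diffs = make_diffs(d)
        _, hyper = moderated_t_test(diffs)

        # independent oracle: solve the digamma/trigamma moment equations
        s2 = d.var(axis=1, ddof=1)
        df = n - 1
        z = np.log(s2)
        e = z - special.digamma(df / 2) + math.log(df / 2)
        emean = e.mean()
        evar = np.mean((e - emean) ** 2) * G / (G - 1) - special.polygamma(1, df / 2)
        d0_oracle = 2.0 * optimize.brentq(
            lambda y: special.polygamma(1, y) - evar, 1e-6, 1e8
        )
        s0_oracle = math.exp(
            emean + special.digamma(d0_oracle / 2) - math.log(d0_oracle / 2)
        )
        assert hyper["d0"] == pytest.approx(d0_oracle, abs=1e-6)
        assert hyper["s0_sq"] == pytest.approx(s0_oracle, rel=1e-6)

        # and the shrunk t follows the posterior-variance formula
        res, _ = moderated_t_test(diffs)
        s2_post = (hyper["d0"] * hyper["s0_sq"] + df * s2) / (hyper["d0"] + df)
        np.testing.assert_allclose(
            res["t_moderated"], d.mean(axis=1) / np.sqrt(s2_post / n), rtol=1e-9
        )

    def test_all_zero_variance_rejected(self):
        d = np.tile([[0.3, 0.3, 0.3]], (5, 1))
        with pytest.raises(PipelineError, match="zero variance"):
            moderated_t_test(make_diffs(d))

    def test_log_odds_finite_and_monotone_in_t(self):
        rng = np.random.default_rng(9)
        d = rng.normal(0, 1, (300, 9))
        d[:10] += 2.0
        res, _ = moderated_t_test(make_diffs(d))
        assert np.isfinite(res["log_odds"]).all()
        order = np.argsort(np.abs(res["t_moderated"]))
        assert (np.diff(res["log_odds"].to_numpy()[order]) >= -1e-9).all()


class TestVolcano:
    def test_neg_log10_axis(self):
        res = paired_t_test(make_diffs([[0.1, 0.3, 0.2]]))
        res["p_adj"] = [0.05]
        v = volcano_table(res)
        assert v["y"].iloc[0] == pytest.approx(1.3010, abs=1e-4)
        assert v["threshold"].iloc[0] == pytest.approx(-math.log10(0.05))

    def test_p_one_maps_to_zero(self):
        res = paired_t_test(make_diffs([[0.1, 0.3, 0.2]]))
        res["p_adj"] = [1.0]
        assert volcano_table(res)["y"].iloc[0] == 0.0

    def test_log_odds_axis(self):
        rng = np.random.default_rng(10)
        res, _ = moderated_t_test(make_diffs(rng.normal(0, 1, (20, 5))))
        v = volcano_table(res, significance="log_odds")
        np.testing.assert_allclose(v["y"], res["log_odds"])
        np.testing.assert_allclose(v["effect"], res["mean_diff"])


class TestSummaryFraction:
    def test_celltype_methylation_fraction(self):
        assert percent_significant(1288, 26690) == 4.8

    def test_celltype_expression_fraction(self):
        assert percent_significant(2126, 37846) == 5.6

    def test_round_half_up(self):
        assert round_half_up(12.45, 1) == 12.5
        assert round_half_up(-12.45, 1) == -12.5

    def test_bounds_checked(self):
        with pytest.raises(ConfigError):
            percent_significant(5, 0)
        with pytest.raises(ConfigError):
            percent_significant(7, 5)
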