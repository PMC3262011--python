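"""Paired differential statistics.

Per-feature paired t-tests, Benjamini-Hochberg step-up FDR, exhaustive
and Monte Carlo sign-flip permutation nulls, an empirical-Bayes
moderated t with variance shrinkage, and volcano-table export.  All
tests are two-sided.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import special, stats

from .datamodel import ConfigError, PairedDifferences, PipelineError

log = logging.getLogger(__name__)

__all__ = [
    "paired_t_test",
    "bh_adjust",
    "signflip_permutation_test",
    "moderated_t_test",
    "volcano_table",
    "percent_significant",
    "round_half_up",
]

EXHAUSTIVE_CAP = 20
_REL_TOL = 1e-12  # relative tolerance when counting |t_perm| >= |t_obs|


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding with ties away from zero (reporting convention)."""
    if not math.isfinite(x):
        return x
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def percent_significant(n_significant: int, n_tested: int, ndigits: int = 1) -> float:
    """Summary percentage of significant features, rounded for reporting."""
    if n_tested <= 0:
        raise ConfigError("n_tested must be positive")
    if not 0 <= n_significant <= n_tested:
        raise ConfigError("n_significant must lie in [0, n_tested]")
    return round_half_up(100.0 * n_significant / n_tested, ndigits)


def _diff_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    n = values.shape[1]
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    return mean, sd, n


def paired_t_test(diffs: PairedDifferences) -> pd.DataFrame:
    """Per-feature paired t-test on precomputed differences.

    Returns a frame with ``feature_id, mean_diff, t, df, p_raw``.
    Zero-variance features get ``t = p_raw = NaN`` and are meant to be
    excluded from FDR adjustment (they are logged).
    """
    n = diffs.n_pairs
    if n < 2:
        raise ConfigError(f"paired t-test needs >= 2 pairs, got {n}")
    mean, sd, _ = _diff_stats(diffs.values)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    t = np.where(sd == 0.0, np.nan, t)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    n_degenerate = int(np.isnan(t).sum())
    if n_degenerate:
        log.info("paired t-test: %d zero-variance features set to NA", n_degenerate)
    return pd.DataFrame(
        {
            "feature_id": diffs.feature_ids,
            "mean_diff": mean,
            "t": t,
            "df": n - 1,
            "p_raw": p,
        }
    )


def bh_adjust(p_values, q: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up adjustment.

    ``adj_i = min_{j >= rank(i)} m * p_(j) / j`` capped at 1.  NaN
    entries are excluded from the adjustment (and from ``m``) and stay
    NaN.  Returns a frame with ``p_raw, p_adj, significant`` where
    ``significant`` means ``p_adj < q``.
    """
    p = np.asarray(p_values, dtype=float)
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ConfigError("p-values must lie in [0, 1]")
    adj = np.full(p.shape, np.nan)
    m = int(finite.sum())
    if m:
        pf = p[finite]
        order = np.argsort(pf, kind="mergesort")
        ranked = pf[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        adj[finite] = out
    significant = adj < q
    return pd.DataFrame({"p_raw": p, "p_adj": adj, "significant": significant})


def _sign_matrix(n: int) -> np.ndarray:
    codes = np.arange(2**n, dtype=np.int64)
    bits = (codes[:, None] >> np.arange(n)) & 1
    return (2 * bits - 1).astype(np.int8)


def _t_from_sums(sums: np.ndarray, ss: np.ndarray, n: int) -> np.ndarray:
    """t-statistics from sign-flipped sums; Sum d_i^2 is flip-invariant."""
    mean = sums / n
    var = (ss - n * mean**2) / (n - 1)
    var = np.clip(var, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
        degenerate = np.where(mean == 0.0, 0.0, np.inf * np.sign(mean))
    return np.where(var == 0.0, degenerate, t)


def signflip_permutation_test(
    diffs: PairedDifferences,
    mode: str = "exhaustive",
    B: int = 10000,
    seed: int | None = None,
    cap: int = EXHAUSTIVE_CAP,
) -> pd.DataFrame:
    """Sign-flip permutation test of the paired t-statistic.

    Exhaustive mode enumerates all ``2**n`` flips of the affection
    status (the observed arrangement included), so ``p >= 2 / 2**n``.
    Monte Carlo mode draws ``B`` seeded flips and reports
    ``(1 + #exceed) / (1 + B)``.

    Returns a frame with ``feature_id, t, p_perm, n_arrangements``.
    """
    d = diffs.values
    n = diffs.n_pairs
    if n < 2:
        raise ConfigError(f"sign-flip test needs >= 2 pairs, got {n}")
    ss = (d**2).sum(axis=1)
    t_obs = _t_from_sums(d.sum(axis=1), ss, n)
    abs_obs = np.abs(t_obs)
    threshold = abs_obs * (1.0 - _REL_TOL)

    if mode == "exhaustive":
        if n > cap:
            raise ConfigError(
                f"exhaustive enumeration over 2^{n} arrangements exceeds the cap "
                f"of 2^{cap}; use mode='montecarlo'"
            )
        n_arr = 2**n
        exceed = np.zeros(d.shape[0], dtype=np.int64)
        chunk = max(1, min(n_arr, 2**22 // max(d.shape[0], 1), 8192))
        signs = _sign_matrix(n)
        for start in range(0, n_arr, chunk):
            s = signs[start : start + chunk].astype(float)
            sums = d @ s.T  # features x chunk
            t_b = _t_from_sums(sums, ss[:, None], n)
            exceed += (np.abs(t_b) >= threshold[:, None]).sum(axis=1)
        p = exceed / n_arr
    elif mode == "montecarlo":
        rng = np.random.default_rng(seed)
        n_arr = B
        exceed = np.zeros(d.shape[0], dtype=np.int64)
        chunk = 4096
        for start in range(0, B, chunk):
            size = min(chunk, B - start)
            s = rng.choice([-1.0, 1.0], size=(size, n))
            sums = d @ s.T
            t_b = _t_from_sums(sums, ss[:, None], n)
            exceed += (np.abs(t_b) >= threshold[:, None]).sum(axis=1)
        p = (1 + exceed) / (1 + B)
    else:
        raise ConfigError(f"unknown permutation mode {mode!r}")
    return pd.DataFrame(
        {
            "feature_id": diffs.feature_ids,
            "t": t_obs,
            "p_perm": p,
            "n_arrangements": n_arr,
        }
    )


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ConfigError("trigamma_inverse needs a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if -dif / y < 1e-10:
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to observed variances.

    Matches mean and variance of ``log(s2)`` against the theoretical
    moments of log scaled-F variates; returns ``(d0, s0_sq)``, with
    ``d0 = inf`` when the observed variances are underdispersed.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ConfigError("variance prior estimation needs >= 2 positive variances")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    n = e.size
    evar = float(np.mean((e - emean) ** 2) * n / (n - 1) - special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return d0, s0_sq


def _tmixture(tstat: np.ndarray, v1: np.ndarray, df: float, proportion: float) -> float:
    """Estimate the prior variance of nonzero effects from the top |t| values."""
    ngenes = tstat.size
    ntarget = math.ceil(proportion / 2.0 * ngenes)
    if ntarget < 1:
        return 0.0
    p = max(ntarget / ngenes, proportion)
    t_abs = np.abs(tstat)
    order = np.argsort(t_abs)[::-1][:ntarget]
    ttop = t_abs[order]
    vtop = v1[order]
    if math.isinf(df):
        p0 = 2.0 * stats.norm.sf(ttop)
    else:
        p0 = 2.0 * stats.t.sf(ttop, df)
    r = np.arange(1, ntarget + 1)
    ptarget = ((r - 0.5) / ngenes - (1.0 - p) * p0) / p
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if pos.any():
        if math.isinf(df):
            qtarget = stats.norm.isf(ptarget[pos] / 2.0)
        else:
            qtarget = stats.t.isf(ptarget[pos] / 2.0, df)
        v0[pos] = vtop[pos] * ((ttop[pos] / qtarget) ** 2 - 1.0)
    return float(np.clip(v0, 0.0, None).mean())


def moderated_t_test(
    diffs: PairedDifferences,
    proportion: float = 0.01,
    prior_df: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Empirical-Bayes moderated paired t-test with variance shrinkage.

    Per-feature variances ``s_g^2`` (df ``n - 1``) are shrunk toward a
    moment-matched prior: ``s~^2 = (d0 s0^2 + d s^2) / (d0 + d)``;
    ``t~ = mean / (s~ / sqrt(n))`` with ``d0 + d`` degrees of freedom.
    ``log_odds`` is the posterior log-odds of a nonzero effect at the
    given prior ``proportion``.

    ``prior_df`` overrides the estimated ``d0`` (0 reproduces the
    ordinary paired t-test).  Returns ``(results, hyperparameters)``.
    """
    n = diffs.n_pairs
    if n < 2:
        raise ConfigError(f"moderated t-test needs >= 2 pairs, got {n}")
    mean, sd, _ = _diff_stats(diffs.values)
    s2 = sd**2
    df_resid = n - 1
    positive = s2 > 0
    if not positive.any():
        raise PipelineError("all features have zero variance; cannot fit the prior")
    if prior_df is None:
        d0, s0_sq = fit_variance_prior(s2[positive], df_resid)
    else:
        d0 = float(prior_df)
        s0_sq = float(np.exp(np.mean(np.log(s2[positive])))) if d0 > 0 else 0.0
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = math.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = mean / np.sqrt(s2_post / n)
    t_mod = np.where(s2_post == 0.0, np.nan, t_mod)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    v_unscaled = np.full_like(s2, 1.0 / n)  # variance of the mean per unit s^2
    ok = np.isfinite(t_mod)
    var_prior = _tmixture(t_mod[ok], v_unscaled[ok], df_total, proportion)
    var_prior = max(var_prior, 1e-12)
    r = (v_unscaled + var_prior) / v_unscaled
    t2 = t_mod**2
    if math.isinf(df_total):
        kernel = t2 * (1.0 - 1.0 / r) / 2.0
    else:
        kernel = (1.0 + df_total) / 2.0 * np.log((t2 + df_total) / (t2 / r + df_total))
    log_odds = math.log(proportion / (1.0 - proportion)) - np.log(r) / 2.0 + kernel

    log.info(
        "moderated t: d0=%s, s0^2=%.6g, var_prior=%.6g", d0, s0_sq, var_prior
    )
    results = pd.DataFrame(
        {
            "feature_id": diffs.feature_ids,
            "mean_diff": mean,
            "t_moderated": t_mod,
            "df_total": df_total,
            "p_raw": p,
            "log_odds": log_odds,
        }
    )
    hyper = {"d0": d0, "s0_sq": s0_sq, "var_prior": var_prior, "proportion": proportion}
    return results, hyper


def volcano_table(
    results: pd.DataFrame,
    effect_col: str = "mean_diff",
    significance: str = "p_adj",
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Volcano-plot export: effect vs -log10(adjusted p) or log-odds.

    The ``threshold`` column carries the y-value of the FDR line
    (``-log10(fdr)``) when the significance axis is a p-value.
    """
    if results.empty:
        raise ConfigError("volcano table needs nonempty results")
    if significance == "log_odds":
        y = results["log_odds"].to_numpy(dtype=float)
        threshold = np.nan
    else:
        p = results[significance].to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            y = -np.log10(p)
        threshold = -math.log10(fdr)
    return pd.DataFrame(
        {
            "feature_id": results["feature_id"],
            "effect": results[effect_col].to_numpy(dtype=float),
            "y": y,
            "threshold": threshold,
        }
    )
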