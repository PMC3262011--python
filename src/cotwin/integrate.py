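"""Per-gene correlation of co-twin methylation differences against
expression fold changes, with significance ranking and top-fraction
selection.

For each gene shared by both assays, Spearman's rho is computed between
the per-pair gene-level deltaBeta vector and the per-pair logFC vector
(average ranks for ties).  Genes are ranked by the significance of the
correlation.
"""

from __future__ import annotations

import logging
import math
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .datamodel import ConfigError, DesignError, PairedDifferences
from .paired import round_half_up

log = logging.getLogger(__name__)

__all__ = [
    "combined_correlation",
    "rank_genes",
    "select_top_fraction",
    "spearman_pvalue",
    "exact_spearman_pvalue",
    "format_correlation_table",
]

_EXACT_MAX_N = 9
_ONE = 1.0 - 1e-12


def spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided p for Spearman's rho via the t-approximation.

    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` with ``n - 2`` degrees of
    freedom; the standard approximation for moderate n.
    """
    if n < 3:
        return float("nan")
    if abs(rho) >= _ONE:
        return 2.0 / math.factorial(n)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def exact_spearman_pvalue(x, y) -> float:
    """Exact permutation p: enumerate all n! orderings of one vector.

    Feasible for ``n <= 9``; respects ties through average ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > _EXACT_MAX_N:
        raise ConfigError(f"exact enumeration limited to n <= {_EXACT_MAX_N}, got {n}")
    if n < 3:
        return float("nan")
    rx = rankdata(x) - (n + 1) / 2.0
    ry = rankdata(y) - (n + 1) / 2.0
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0.0:
        return float("nan")
    rho_obs = float(rx @ ry) / denom
    perms = np.array(list(permutations(range(n))), dtype=np.intp)
    rho_all = (ry[perms] @ rx) / denom
    return float(np.mean(np.abs(rho_all) >= abs(rho_obs) - 1e-12))


def _rowwise_spearman(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ra = rankdata(a, axis=1).astype(float)
    rb = rankdata(b, axis=1).astype(float)
    ra -= ra.mean(axis=1, keepdims=True)
    rb -= rb.mean(axis=1, keepdims=True)
    num = (ra * rb).sum(axis=1)
    den = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = num / den
    return np.where(den == 0.0, np.nan, rho)


def combined_correlation(
    meth_diffs: PairedDifferences,
    expr_diffs: PairedDifferences,
    p_method: str = "tapprox",
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Correlate per-pair deltaBeta against logFC for every shared gene.

    The gene universe is the intersection of the two feature sets and
    the pair set is the intersection of the two pair sets (the platform
    overlap).  Genes with fewer than ``min_pairs`` complete pairs are
    skipped with a log entry.  ``p_method`` is ``tapprox`` (default) or
    ``exact`` (full enumeration, n <= 9); |rho| = 1 always uses the
    exact value.

    Returns one row per gene: ``gene_id, rho, p_value, mean_deltaBeta,
    mean_logFC, n_pairs_used``.
    """
    if p_method not in ("tapprox", "exact"):
        raise ConfigError(f"unknown p-value method {p_method!r}")
    genes = [g for g in meth_diffs.feature_ids if g in set(expr_diffs.feature_ids)]
    pairs = [p for p in meth_diffs.pair_ids if p in set(expr_diffs.pair_ids)]
    if not genes:
        raise DesignError("no genes shared between the methylation and expression inputs")
    if len(pairs) < min_pairs:
        raise DesignError(
            f"only {len(pairs)} pairs shared between assays; need >= {min_pairs}"
        )
    if p_method == "exact" and len(pairs) > _EXACT_MAX_N:
        raise ConfigError(
            f"exact p-values require n <= {_EXACT_MAX_N} pairs, got {len(pairs)}"
        )
    a = meth_diffs.to_frame().loc[genes, pairs].to_numpy()
    b = expr_diffs.to_frame().loc[genes, pairs].to_numpy()

    ok = ~(np.isnan(a) | np.isnan(b))
    complete = ok.all(axis=1)
    n_full = len(pairs)

    rho = np.full(len(genes), np.nan)
    n_used = np.full(len(genes), 0)
    mean_db = np.full(len(genes), np.nan)
    mean_fc = np.full(len(genes), np.nan)

    if complete.any():
        rho[complete] = _rowwise_spearman(a[complete], b[complete])
        n_used[complete] = n_full
        mean_db[complete] = a[complete].mean(axis=1)
        mean_fc[complete] = b[complete].mean(axis=1)
    for i in np.flatnonzero(~complete):
        mask = ok[i]
        if mask.sum() < min_pairs:
            log.info("gene %s skipped: only %d complete pairs", genes[i], mask.sum())
            continue
        rho[i] = _rowwise_spearman(a[i, mask][None, :], b[i, mask][None, :])[0]
        n_used[i] = int(mask.sum())
        mean_db[i] = a[i, mask].mean()
        mean_fc[i] = b[i, mask].mean()

    p = np.full(len(genes), np.nan)
    for i in range(len(genes)):
        if n_used[i] < min_pairs or np.isnan(rho[i]):
            continue
        n_i = int(n_used[i])
        if abs(rho[i]) >= _ONE and n_i <= _EXACT_MAX_N:
            mask = ok[i]
            p[i] = exact_spearman_pvalue(a[i, mask], b[i, mask])
        elif p_method == "exact":
            mask = ok[i]
            p[i] = exact_spearman_pvalue(a[i, mask], b[i, mask])
        else:
            p[i] = spearman_pvalue(float(rho[i]), n_i)

    records = pd.DataFrame(
        {
            "gene_id": genes,
            "rho": rho,
            "p_value": p,
            "mean_deltaBeta": mean_db,
            "mean_logFC": mean_fc,
            "n_pairs_used": n_used,
        }
    )
    return records[records["n_pairs_used"] >= min_pairs].reset_index(drop=True)


def rank_genes(records: pd.DataFrame) -> pd.DataFrame:
    """Order by ascending p, ties broken by descending |rho|, then gene id."""
    if records.empty:
        raise ConfigError("cannot rank an empty record list")
    key = records.assign(_abs_rho=-records["rho"].abs())
    ranked = key.sort_values(
        ["p_value", "_abs_rho", "gene_id"], kind="mergesort", na_position="last"
    ).drop(columns="_abs_rho")
    return ranked.reset_index(drop=True)


def select_top_fraction(ranked: pd.DataFrame, fraction: float) -> list[str]:
    """First ``ceil(fraction * G)`` gene ids of the ranked list."""
    if not (0.0 < fraction <= 1.0):
        raise ConfigError(f"fraction must lie in (0, 1], got {fraction}")
    k = math.ceil(fraction * len(ranked))
    return ranked["gene_id"].head(k).tolist()


def format_correlation_table(records: pd.DataFrame) -> pd.DataFrame:
    """Reporting view: rho to 2 decimals, p to 5, effects to 4."""
    out = records.copy()
    out["rho"] = out["rho"].map(lambda v: round_half_up(v, 2))
    out["p_value"] = out["p_value"].map(lambda v: round_half_up(v, 5))
    out["mean_deltaBeta"] = out["mean_deltaBeta"].map(lambda v: round_half_up(v, 4))
    out["mean_logFC"] = out["mean_logFC"].map(lambda v: round_half_up(v, 4))
    return out
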