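"""Gene-set overrepresentation: Fisher/hypergeometric test of a disease
set in a top-ranked list, and term enrichment with BH correction."""

from __future__ import annotations

import logging

import pandas as pd
from scipy.stats import hypergeom

from .datamodel import ConfigError, GeneSet, GeneSetCollection
from .paired import bh_adjust, round_half_up

log = logging.getLogger(__name__)

__all__ = ["fisher_overrepresentation", "term_enrichment"]


def _hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(population N, successes K, draws n)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def fisher_overrepresentation(
    top_list, gene_set, background
) -> tuple[tuple[tuple[int, int], tuple[int, int]], float]:
    """One-sided Fisher test of gene-set overrepresentation in a top list.

    Returns ``((in_list_hit, in_list_miss), (out_list_hit,
    out_list_miss)), p`` with ``p = P(X >= overlap)`` under the
    hypergeometric null.  The gene set is intersected with the
    background first.
    """
    background = {str(g) for g in background}
    if not background:
        raise ConfigError("background gene universe is empty")
    top = {str(g) for g in top_list}
    outside = sorted(top - background)
    if outside:
        raise ConfigError(f"top-list gene {outside[0]!r} is not in the background")
    members = gene_set.members if isinstance(gene_set, GeneSet) else gene_set
    in_bg = {str(g) for g in members} & background
    N = len(background)
    K = len(in_bg)
    n = len(top)
    k = len(top & in_bg)
    p = _hypergeom_upper_tail(k, N, K, n)
    table = ((k, n - k), (K - k, N - K - n + k))
    log.info("Fisher overrepresentation: table=%s p=%.4g", table, p)
    return table, p


def term_enrichment(
    input_list,
    terms: GeneSetCollection,
    background,
    ease: bool = False,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-term overrepresentation of the input list, BH-corrected.

    ``frequency_pct`` is ``100 * count / input_size`` rounded to one
    decimal (the reporting convention).  With ``ease=True`` the hit
    count is decremented by one before the hypergeometric tail (DAVID's
    conservative EASE variant).  Terms with zero hits are excluded
    before adjustment.

    Returns one row per term: ``term_id, term_name, count, input_size,
    frequency_pct, background_hits, background_size, p_raw, p_adj``.
    """
    background = {str(g) for g in background}
    if not background:
        raise ConfigError("background gene universe is empty")
    if len(terms) == 0:
        raise ConfigError("no terms to test")
    input_genes = []
    seen = set()
    for g in input_list:
        g = str(g)
        if g not in background:
            raise ConfigError(f"input gene {g!r} is not in the background universe")
        if g not in seen:
            seen.add(g)
            input_genes.append(g)
    if not input_genes:
        raise ConfigError("input gene list is empty")
    input_set = set(input_genes)
    N = len(background)
    n = len(input_genes)
    rows = []
    for gs in terms:
        members = {str(g) for g in gs.members} & background
        K = len(members)
        k = len(input_set & members)
        if k == 0:
            continue
        k_test = max(k - 1, 0) if ease else k
        p = _hypergeom_upper_tail(k_test, N, K, n)
        rows.append(
            {
                "term_id": gs.name,
                "term_name": gs.description,
                "count": k,
                "input_size": n,
                "frequency_pct": round_half_up(100.0 * k / n, 1),
                "background_hits": K,
                "background_size": N,
                "p_raw": p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "term_id",
                "term_name",
                "count",
                "input_size",
                "frequency_pct",
                "background_hits",
                "background_size",
                "p_raw",
                "p_adj",
            ]
        )
    out = pd.DataFrame(rows)
    adj = bh_adjust(out["p_raw"].to_numpy(), q=q)
    out["p_adj"] = adj["p_adj"].to_numpy()
    return out.sort_values(["p_raw", "term_id"], kind="mergesort").reset_index(drop=True)
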