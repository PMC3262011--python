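"""Co-twin similarity diagnostics and the technical-vs-biological
difference contrast."""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    ConfigError,
    DesignError,
    FeatureMatrix,
    TwinDesign,
)
from .paired import round_half_up

__all__ = [
    "cotwin_correlation",
    "technical_vs_biological",
    "ks_two_sample",
]


def cotwin_correlation(
    matrix: FeatureMatrix,
    design: TwinDesign,
    cell_type: str,
    method: str = "spearman",
) -> tuple[pd.DataFrame, dict]:
    """Per-pair correlation of the two co-twin columns across features.

    Returns ``(per_pair, summary)``; the summary carries the mean, min
    and max rounded to 2 decimals for reporting (plus unrounded values).
    Constant columns yield NaN for that pair with a warning.
    """
    if method not in ("spearman", "pearson"):
        raise ConfigError(f"unknown correlation method {method!r}")
    if len(matrix.feature_ids) < 3:
        raise ConfigError("co-twin correlation needs >= 3 features")
    pairs = design.complete_pairs(cell_type)
    available = set(matrix.sample_ids)
    pairs = pairs[
        pairs["unaffected"].isin(available) & pairs["affected"].isin(available)
    ]
    if pairs.empty:
        raise DesignError(f"no complete pairs for cell type {cell_type!r}")
    rows = []
    for _, row in pairs.iterrows():
        x = matrix.column(row["unaffected"])
        y = matrix.column(row["affected"])
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            warnings.warn(
                f"constant column for pair {row['pair_id']!r}; correlation is NA",
                stacklevel=2,
            )
            r = np.nan
        elif method == "spearman":
            r = float(stats.spearmanr(x, y).statistic)
        else:
            r = float(stats.pearsonr(x, y).statistic)
        rows.append((row["pair_id"], r))
    per_pair = pd.DataFrame(rows, columns=["pair_id", "correlation"])
    vals = per_pair["correlation"].dropna()
    summary = {
        "method": method,
        "n_pairs": len(per_pair),
        "mean": round_half_up(float(vals.mean()), 2),
        "min": round_half_up(float(vals.min()), 2),
        "max": round_half_up(float(vals.max()), 2),
        "mean_raw": float(vals.mean()),
    }
    return per_pair, summary


def technical_vs_biological(
    beta: FeatureMatrix, design: TwinDesign, cell_type: str | None = None
) -> tuple[pd.Series, pd.Series]:
    """Per-CpG technical (self-self) vs biological (co-twin) differences.

    Technical: |value - replicate value| per CpG averaged over
    replicated samples.  Biological: |unaffected - affected| per CpG
    averaged over complete pairs.  Returned as two Series aligned on the
    matrix feature order.
    """
    reps = design.replicate_table(cell_type)
    available = set(beta.sample_ids)
    reps = reps[
        reps["sample_id"].isin(available) & reps["replicate_of"].isin(available)
    ]
    if reps.empty:
        raise DesignError("no replicated samples available for the technical contrast")
    tech = np.zeros(len(beta.feature_ids))
    for _, row in reps.iterrows():
        tech += np.abs(beta.column(row["sample_id"]) - beta.column(row["replicate_of"]))
    tech /= len(reps)

    cell_types = [cell_type] if cell_type is not None else design.cell_types
    diffs = []
    for ct in cell_types:
        pairs = design.complete_pairs(ct)
        pairs = pairs[
            pairs["unaffected"].isin(available) & pairs["affected"].isin(available)
        ]
        for _, row in pairs.iterrows():
            diffs.append(
                np.abs(beta.column(row["unaffected"]) - beta.column(row["affected"]))
            )
    if not diffs:
        raise DesignError("no complete pairs available for the biological contrast")
    bio = np.mean(diffs, axis=0)
    index = pd.Index(beta.feature_ids)
    return pd.Series(tech, index=index, name="technical"), pd.Series(
        bio, index=index, name="biological"
    )


def ks_two_sample(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    ``D = sup |F_x - F_y|``; the p-value uses the asymptotic Kolmogorov
    distribution with the effective-n scaling
    ``sqrt(n*m/(n+m)) * D``, or the exact method when both samples are
    small (n < 50) and ``method='auto'``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConfigError("KS test needs two nonempty samples")
    if method == "auto":
        method = "exact" if (x.size < 50 and y.size < 50) else "asymp"
    if method == "exact":
        res = stats.ks_2samp(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    d = float(stats.ks_2samp(x, y, alternative="two-sided", method="asymp").statistic)
    en = math.sqrt(x.size * y.size / (x.size + y.size))
    p = float(np.clip(stats.kstwobign.sf(en * d), 0.0, 1.0))
    return d, p
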