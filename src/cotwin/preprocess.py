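"""Probe filtering, normalization, log transform, gene-level aggregation,
and paired-difference computation.

Orientation of all paired differences is fixed as unaffected minus
affected; the cell-type contrast is oriented first minus second cell
type.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import (
    ConfigError,
    DesignError,
    FeatureMatrix,
    PairedDifferences,
    ParseError,
    ProbeGeneMap,
    TwinDesign,
    UNAFFECTED,
)

log = logging.getLogger(__name__)

__all__ = [
    "filter_probes",
    "quantile_normalize",
    "log2_transform",
    "aggregate_cpgs_to_gene",
    "compute_pair_differences",
    "compute_celltype_differences",
]


def filter_probes(beta: FeatureMatrix, whitelist) -> FeatureMatrix:
    """Restrict rows to the whitelist, preserving the original order."""
    whitelist = set(whitelist)
    if not whitelist:
        raise ConfigError("probe whitelist is empty")
    keep = [f for f in beta.feature_ids if f in whitelist]
    if not keep:
        raise ParseError("probe whitelist has empty intersection with the matrix")
    log.info("probe filter kept %d of %d probes", len(keep), len(beta.feature_ids))
    return beta.subset_features(keep)


def quantile_normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Quantile-normalize columns to the mean-of-order-statistics reference.

    After normalization every column's sorted values equal the
    across-column mean of sorted values; within-column ranks are
    preserved and ties receive the mean of the reference values they
    span.
    """
    values = matrix.values
    if values.shape[1] < 2:
        raise ConfigError("quantile normalization needs >= 2 samples")
    if np.isnan(values).any():
        raise ParseError("quantile normalization input contains NA values")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = reference
        # average the reference values across tie groups
        sorted_vals = col[order]
        tie_starts = np.flatnonzero(np.r_[True, sorted_vals[1:] != sorted_vals[:-1]])
        group = np.repeat(np.arange(len(tie_starts)), np.diff(np.r_[tie_starts, n]))
        sums = np.bincount(group, weights=reference)
        counts = np.bincount(group)
        averaged = (sums / counts)[group]
        assigned[order] = averaged
        out[:, j] = assigned
    return FeatureMatrix(matrix.feature_ids, matrix.sample_ids, out, matrix.kind)


def log2_transform(expr: FeatureMatrix, offset: float = 1.0) -> FeatureMatrix:
    """log2(value + offset); the result is tagged ``expression-log2``."""
    shifted = expr.values + offset
    if (shifted <= 0).any():
        bad = np.argwhere(shifted <= 0)[0]
        raise ParseError(
            f"non-positive value after offset {offset} at feature "
            f"{expr.feature_ids[bad[0]]!r}, sample {expr.sample_ids[bad[1]]!r}"
        )
    return FeatureMatrix(
        expr.feature_ids, expr.sample_ids, np.log2(shifted), "expression-log2"
    )


def aggregate_cpgs_to_gene(beta: FeatureMatrix, pmap: ProbeGeneMap) -> FeatureMatrix:
    """Unweighted mean beta over each gene's probes present in the matrix.

    Genes with zero present probes are omitted; output kind is
    ``gene-beta`` with genes in sorted order.
    """
    present = beta.feature_ids.intersection(pmap.probe_ids)
    if len(present) == 0:
        raise ParseError("no probe in the matrix is covered by the probe map")
    sub = beta.subset_features(list(present))
    genes = pmap.mapping.loc[list(present)]
    frame = sub.to_frame()
    frame.index = pd.Index(genes.values)
    agg = frame.groupby(level=0, sort=True).mean()
    return FeatureMatrix.from_frame(agg, "gene-beta")


_DIFF_KIND_BY_INPUT = {
    "methylation-beta": "deltaBeta",
    "gene-beta": "deltaBeta",
    "expression-log2": "logFC",
}


def compute_pair_differences(
    matrix: FeatureMatrix, design: TwinDesign, cell_type: str
) -> PairedDifferences:
    """Per-feature, per-pair unaffected-minus-affected differences.

    Replicate and excluded samples are ignored; pairs lacking either
    co-twin in the matrix are dropped.
    """
    if matrix.kind not in _DIFF_KIND_BY_INPUT:
        raise ConfigError(
            f"cannot compute paired differences from kind {matrix.kind!r}; "
            "expression intensities must be log2-transformed first"
        )
    pairs = design.complete_pairs(cell_type)
    available = set(matrix.sample_ids)
    usable = pairs[
        pairs["unaffected"].isin(available) & pairs["affected"].isin(available)
    ]
    if usable.empty:
        raise DesignError(f"no complete pairs for cell type {cell_type!r} in the matrix")
    un = matrix.subset_samples(usable["unaffected"].tolist()).values
    af = matrix.subset_samples(usable["affected"].tolist()).values
    return PairedDifferences(
        matrix.feature_ids,
        pd.Index(usable["pair_id"].tolist()),
        un - af,
        _DIFF_KIND_BY_INPUT[matrix.kind],
    )


def compute_celltype_differences(
    matrix: FeatureMatrix,
    design: TwinDesign,
    cell_types: tuple[str, str] = ("CD4", "CD8"),
    status: str = UNAFFECTED,
) -> PairedDifferences:
    """Within-individual differences between two cell types.

    Pairing unit is the individual (pair_id x status); by default only
    unaffected twins measured in both cell types enter.  Oriented
    ``cell_types[0]`` minus ``cell_types[1]``.
    """
    if matrix.kind not in _DIFF_KIND_BY_INPUT:
        raise ConfigError(
            f"cannot compute paired differences from kind {matrix.kind!r}"
        )
    ct_a, ct_b = cell_types
    t = design.table
    keep = (t["replicate_of"] == "") & (~t["excluded"]) & (t["status"] == status)
    t = t.loc[keep]
    available = set(matrix.sample_ids)
    by_ct = {
        ct: t.loc[t["cell_type"] == ct].set_index("pair_id")["sample_id"]
        for ct in (ct_a, ct_b)
    }
    individuals = sorted(
        pid
        for pid in set(by_ct[ct_a].index) & set(by_ct[ct_b].index)
        if by_ct[ct_a][pid] in available and by_ct[ct_b][pid] in available
    )
    if not individuals:
        raise DesignError(
            f"no {status} individual measured in both {ct_a!r} and {ct_b!r}"
        )
    a = matrix.subset_samples([by_ct[ct_a][p] for p in individuals]).values
    b = matrix.subset_samples([by_ct[ct_b][p] for p in individuals]).values
    return PairedDifferences(
        matrix.feature_ids,
        pd.Index(individuals),
        a - b,
        _DIFF_KIND_BY_INPUT[matrix.kind],
    )
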