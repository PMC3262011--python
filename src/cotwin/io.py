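"""Readers and writers for the pipeline's plain-text formats.

Canonical dialect: tab-separated, UTF-8, '.' decimal point, missing
values encoded as ``NA``.  Matrices are features x samples with the
sample ids in the header row and feature ids in the first column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    BETA_KINDS,
    FeatureMatrix,
    GeneSetCollection,
    ParseError,
    ProbeGeneMap,
    TwinDesign,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_design",
    "write_design",
    "read_probe_map",
    "write_probe_map",
    "read_gmt",
    "write_gmt",
    "validate",
    "ValidationReport",
]

_NA = "NA"


def read_matrix(path: str | Path, kind: str) -> FeatureMatrix:
    """Read a features x samples TSV matrix.

    Raises :class:`ParseError` with the offending row/column location for
    duplicate ids, non-numeric cells, and out-of-range beta values.
    """
    path = Path(path)
    raw = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[_NA], keep_default_na=False,
        dtype=str,
    )
    raw.index = raw.index.astype(str)
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        try:
            values[:, j] = pd.to_numeric(raw[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(raw[col], errors="coerce")
        else:
            continue
        i = int(np.argmax(bad.isna().to_numpy() & raw[col].notna().to_numpy()))
        raise ParseError(
            f"{path}: non-numeric value {raw[col].iloc[i]!r} at "
            f"feature {raw.index[i]!r}, sample {col!r}"
        )
    if kind in BETA_KINDS:
        finite = np.isfinite(values)
        bad = finite & ((values < 0.0) | (values > 1.0))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ParseError(
                f"{path}: {kind} value {values[i, j]} out of [0, 1] at "
                f"feature {raw.index[i]!r}, sample {raw.columns[j]!r}"
            )
    matrix = FeatureMatrix(raw.index, raw.columns, values, kind)
    log.info("read %s matrix %s: %d features x %d samples", kind, path, *matrix.shape)
    return matrix


def write_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a matrix TSV; floats keep >= 12 significant digits."""
    frame = matrix.to_frame()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t", float_format="%.12g", na_rep=_NA)


def read_design(path: str | Path) -> TwinDesign:
    table = pd.read_csv(
        path, sep="\t", dtype=str, na_values=[_NA], keep_default_na=False
    )
    return TwinDesign(table)


def write_design(design: TwinDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_probe_map(path: str | Path) -> ProbeGeneMap:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ParseError(f"{path}: probe map needs two columns (probe_id, gene_id)")
    return ProbeGeneMap(pd.Series(table.iloc[:, 1].values, index=table.iloc[:, 0]))


def write_probe_map(pmap: ProbeGeneMap, path: str | Path) -> None:
    frame = pd.DataFrame(
        {"probe_id": pmap.mapping.index, "gene_id": pmap.mapping.values}
    )
    frame.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format: name, description, members."""
    coll = GeneSetCollection()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            coll.add(parts[0], parts[1], [p for p in parts[2:] if p])
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


@dataclass
class ValidationReport:
    """Consistency report for a design against one or more matrices."""

    n_pairs: dict[str, int] = field(default_factory=dict)
    incomplete_pairs: dict[str, list[str]] = field(default_factory=dict)
    missing_samples: dict[str, list[str]] = field(default_factory=dict)
    shared_pairs: dict[str, list[str]] = field(default_factory=dict)
    excluded_samples: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate(
    design: TwinDesign, matrices: Mapping[str, FeatureMatrix] | None = None
) -> ValidationReport:
    """Check pair completeness and design/matrix sample agreement.

    ``matrices`` maps an assay label (e.g. ``"beta"``, ``"expression"``)
    to its matrix.  Side-effect free; call twice, get the same report.
    """
    report = ValidationReport()
    matrices = dict(matrices or {})
    for ct in design.cell_types:
        report.n_pairs[ct] = design.n_pairs(ct)
        bad = design.incomplete_pairs(ct)
        report.incomplete_pairs[ct] = bad
        for pair_id in bad:
            report.errors.append(
                f"pair {pair_id!r} in cell type {ct!r} lacks exactly one "
                "affected and one unaffected sample"
            )
    report.excluded_samples = design.table.loc[
        design.table["excluded"], "sample_id"
    ].tolist()
    for label, matrix in matrices.items():
        present = set(matrix.sample_ids)
        missing = [s for s in design.sample_ids if s not in present]
        report.missing_samples[label] = missing
    if len(matrices) >= 2:
        labels = list(matrices)
        for ct in design.cell_types:
            pairs = design.complete_pairs(ct)
            shared = []
            for _, row in pairs.iterrows():
                if all(
                    row["unaffected"] in set(m.sample_ids)
                    and row["affected"] in set(m.sample_ids)
                    for m in matrices.values()
                ):
                    shared.append(row["pair_id"])
            report.shared_pairs[ct] = shared
    return report
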