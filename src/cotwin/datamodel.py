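"""Shared data model for the co-twin methylation/expression pipeline.

All tabular structures are thin wrappers around :mod:`pandas` /
:mod:`numpy` containers with the pipeline's invariants enforced at
construction time.  Feature matrices carry a ``kind`` tag so that
kind-specific invariants (beta values in [0, 1], positive intensities)
travel with the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PipelineError",
    "ParseError",
    "ConfigError",
    "DesignError",
    "FeatureMatrix",
    "TwinDesign",
    "ProbeGeneMap",
    "GeneSet",
    "GeneSetCollection",
    "PairedDifferences",
    "BETA_KINDS",
    "MATRIX_KINDS",
    "DIFF_KINDS",
    "AFFECTED",
    "UNAFFECTED",
]

BETA_KINDS = frozenset({"methylation-beta", "gene-beta"})
MATRIX_KINDS = BETA_KINDS | {"expression-intensity", "expression-log2"}
DIFF_KINDS = frozenset({"deltaBeta", "logFC"})

AFFECTED = "affected"
UNAFFECTED = "unaffected"


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(PipelineError):
    """A file could not be parsed or violated a format invariant."""


class ConfigError(PipelineError):
    """An invalid configuration value, named after the violated invariant."""


class DesignError(PipelineError):
    """The sample sheet is inconsistent with the requested analysis."""


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise ParseError(f"duplicate {what}: {dup[:5]}")


@dataclass
class FeatureMatrix:
    """A features x samples matrix of real values with a kind tag.

    Parameters
    ----------
    feature_ids : ordered feature identifiers (rows).
    sample_ids : ordered sample identifiers (columns).
    values : float array of shape ``(n_features, n_samples)``.
    kind : one of ``methylation-beta``, ``gene-beta``,
        ``expression-intensity``, ``expression-log2``.
    """

    feature_ids: pd.Index
    sample_ids: pd.Index
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise ConfigError(
                f"unknown matrix kind {self.kind!r}; expected one of {sorted(MATRIX_KINDS)}"
            )
        self.feature_ids = pd.Index(self.feature_ids, dtype=object)
        self.sample_ids = pd.Index(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ParseError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature ids")
        _check_unique(self.sample_ids, "sample ids")
        if self.kind in BETA_KINDS:
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                r, c = self._first_out_of_range()
                raise ParseError(
                    f"{self.kind} value {self.values[r, c]!r} out of [0, 1] at "
                    f"feature {self.feature_ids[r]!r}, sample {self.sample_ids[c]!r}"
                )

    def _first_out_of_range(self) -> tuple[int, int]:
        bad = np.argwhere((self.values < 0.0) | (self.values > 1.0))
        r, c = bad[0]
        return int(r), int(c)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, kind: str) -> "FeatureMatrix":
        return cls(frame.index, frame.columns, frame.to_numpy(dtype=float), kind)

    def subset_features(self, ids: Sequence[str]) -> "FeatureMatrix":
        idx = self.feature_ids.get_indexer(pd.Index(ids))
        if (idx < 0).any():
            missing = [i for i, j in zip(ids, idx) if j < 0]
            raise ParseError(f"features not in matrix: {missing[:5]}")
        return FeatureMatrix(
            pd.Index(ids), self.sample_ids, self.values[idx, :], self.kind
        )

    def subset_samples(self, ids: Sequence[str]) -> "FeatureMatrix":
        idx = self.sample_ids.get_indexer(pd.Index(ids))
        if (idx < 0).any():
            missing = [i for i, j in zip(ids, idx) if j < 0]
            raise ParseError(f"samples not in matrix: {missing[:5]}")
        return FeatureMatrix(
            self.feature_ids, pd.Index(ids), self.values[:, idx], self.kind
        )

    def column(self, sample_id: str) -> np.ndarray:
        j = self.sample_ids.get_loc(sample_id)
        return self.values[:, j]


DESIGN_COLUMNS = ["sample_id", "pair_id", "status", "cell_type"]
OPTIONAL_DESIGN_COLUMNS = ["replicate_of", "excluded", "exclude_reason"]


@dataclass
class TwinDesign:
    """Sample sheet: twin pairing, affection status, cell type, replicates.

    The underlying table has one row per array sample.  ``replicate_of``
    marks technical replicate columns (empty for primary samples) and
    ``excluded`` flags samples that must never enter any statistic.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        missing = [c for c in DESIGN_COLUMNS if c not in t.columns]
        if missing:
            raise ParseError(f"sample sheet missing required columns: {missing}")
        if "replicate_of" not in t.columns:
            t["replicate_of"] = ""
        if "excluded" not in t.columns:
            t["excluded"] = False
        if "exclude_reason" not in t.columns:
            t["exclude_reason"] = ""
        t["replicate_of"] = t["replicate_of"].fillna("").astype(str)
        t["exclude_reason"] = t["exclude_reason"].fillna("").astype(str)
        t["excluded"] = t["excluded"].map(_as_bool)
        for col in ("sample_id", "pair_id", "status", "cell_type"):
            t[col] = t[col].astype(str)
        _check_unique(pd.Index(t["sample_id"]), "sample ids in design")
        bad_status = sorted(set(t["status"]) - {AFFECTED, UNAFFECTED})
        if bad_status:
            raise ParseError(
                f"unknown affection status values {bad_status}; "
                f"expected {AFFECTED!r} or {UNAFFECTED!r}"
            )
        known = set(t["sample_id"])
        dangling = sorted(set(t.loc[t["replicate_of"] != "", "replicate_of"]) - known)
        if dangling:
            raise ParseError(f"replicate_of references unknown samples: {dangling}")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.table["cell_type"].unique())

    def analysis_table(self, cell_type: str | None = None) -> pd.DataFrame:
        """Non-replicate, non-excluded rows (optionally one cell type)."""
        t = self.table
        keep = (t["replicate_of"] == "") & (~t["excluded"])
        if cell_type is not None:
            keep &= t["cell_type"] == cell_type
        return t.loc[keep]

    def replicate_table(self, cell_type: str | None = None) -> pd.DataFrame:
        t = self.table
        keep = (t["replicate_of"] != "") & (~t["excluded"])
        if cell_type is not None:
            keep &= t["cell_type"] == cell_type
        return t.loc[keep]

    def complete_pairs(self, cell_type: str) -> pd.DataFrame:
        """Pairs with exactly one affected and one unaffected usable sample.

        Returns a frame with columns ``pair_id``, ``unaffected``,
        ``affected`` (sample ids), sorted by pair id.
        """
        t = self.analysis_table(cell_type)
        rows = []
        for pair_id, grp in t.groupby("pair_id", sort=True):
            un = grp.loc[grp["status"] == UNAFFECTED, "sample_id"].tolist()
            af = grp.loc[grp["status"] == AFFECTED, "sample_id"].tolist()
            if len(un) == 1 and len(af) == 1:
                rows.append((pair_id, un[0], af[0]))
        return pd.DataFrame(rows, columns=["pair_id", "unaffected", "affected"])

    def incomplete_pairs(self, cell_type: str) -> list[str]:
        t = self.analysis_table(cell_type)
        bad = []
        for pair_id, grp in t.groupby("pair_id", sort=True):
            n_un = (grp["status"] == UNAFFECTED).sum()
            n_af = (grp["status"] == AFFECTED).sum()
            if (n_un, n_af) != (1, 1):
                bad.append(str(pair_id))
        return bad

    def n_pairs(self, cell_type: str) -> int:
        return len(self.complete_pairs(cell_type))


def _as_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no", "", "nan", "na"}:
        return False
    raise ParseError(f"cannot interpret {x!r} as a boolean excluded flag")


@dataclass
class ProbeGeneMap:
    """Many-to-one probe -> gene mapping."""

    mapping: pd.Series  # index: probe_id, values: gene_id

    def __post_init__(self) -> None:
        s = pd.Series(self.mapping)
        s.index = s.index.astype(str)
        _check_unique(s.index, "probe ids in map")
        self.mapping = s.astype(str)

    @property
    def probe_ids(self) -> pd.Index:
        return self.mapping.index

    @property
    def gene_ids(self) -> list[str]:
        return sorted(set(self.mapping.values))

    def gene_of(self, probe_id: str) -> str:
        return self.mapping[probe_id]

    def probes_of(self, gene_id: str) -> list[str]:
        return self.mapping.index[self.mapping.values == gene_id].tolist()

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for m in self.members:
            seen.setdefault(str(m))
        self.members = tuple(seen)
        if not self.members:
            raise ParseError(f"gene set {self.name!r} has no members")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-serializable)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, name: str, description: str, members: Iterable[str]) -> None:
        if name in self.sets:
            raise ParseError(f"duplicate gene set name {name!r}")
        self.sets[name] = GeneSet(name, description, tuple(members))

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class PairedDifferences:
    """Per-feature, per-pair differences, oriented unaffected minus affected.

    ``kind`` is ``deltaBeta`` for (gene-)beta inputs and ``logFC`` for
    log2 expression inputs.
    """

    feature_ids: pd.Index
    pair_ids: pd.Index
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in DIFF_KINDS:
            raise ConfigError(
                f"unknown difference kind {self.kind!r}; expected one of {sorted(DIFF_KINDS)}"
            )
        self.feature_ids = pd.Index(self.feature_ids, dtype=object)
        self.pair_ids = pd.Index(self.pair_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.pair_ids)):
            raise ParseError("paired difference shape inconsistent with ids")
        _check_unique(self.feature_ids, "feature ids")
        _check_unique(self.pair_ids, "pair ids")
        if self.kind == "deltaBeta":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (np.abs(finite) > 1.0 + 1e-12).any():
                raise ParseError("deltaBeta values must lie in [-1, 1]")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.pair_ids)
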