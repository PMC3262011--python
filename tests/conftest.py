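import numpy as np
import pandas as pd
import pytest

from cotwin.datamodel import FeatureMatrix, PairedDifferences, TwinDesign
from cotwin.simulate import SimulationConfig, simulate_cohort


def make_design(n_pairs: int = 4, cell_types=("CD4",), excluded=(), replicates=()):
    """Build a simple sample sheet: pairNN_{U,A}_{ct} columns."""
    rows = []
    for ct in cell_types:
        for p in range(n_pairs):
            pair = f"pair{p + 1:02d}"
            for status, tag in (("unaffected", "U"), ("affected", "A")):
                sid = f"{pair}_{tag}_{ct}"
                rows.append(
                    {
                        "sample_id": sid,
                        "pair_id": pair,
                        "status": status,
                        "cell_type": ct,
                        "replicate_of": "",
                        "excluded": sid in excluded,
                        "exclude_reason": "qc" if sid in excluded else "",
                    }
                )
    for orig in replicates:
        src = next(r for r in rows if r["sample_id"] == orig)
        rows.append({**src, "sample_id": orig + "_rep", "replicate_of": orig})
    return TwinDesign(pd.DataFrame(rows))


def make_matrix(values, kind="methylation-beta", features=None, samples=None):
    values = np.asarray(values, dtype=float)
    if features is None:
        features = [f"f{i}" for i in range(values.shape[0])]
    if samples is None:
        samples = [f"s{j}" for j in range(values.shape[1])]
    return FeatureMatrix(pd.Index(features), pd.Index(samples), values, kind)


def make_diffs(values, kind="logFC", features=None, pairs=None):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    if features is None:
        features = [f"f{i}" for i in range(values.shape[0])]
    if pairs is None:
        pairs = [f"p{j}" for j in range(values.shape[1])]
    return PairedDifferences(pd.Index(features), pd.Index(pairs), values, kind)


@pytest.fixture(scope="session")
def small_cohort():
    """A planted-signal cohort shared by several test modules."""
    config = SimulationConfig(
        n_pairs_per_celltype=8,
        n_genes=200,
        cpgs_per_gene=(1, 3),
        n_planted_genes=30,
        target_planted_rho=0.85,
        n_replicated_pairs=3,
        n_celltype_specific_features=10,
        seed=7,
    )
    beta, expr, design, pmap, truth = simulate_cohort(config)
    return {
        "config": config,
        "beta": beta,
        "expr": expr,
        "design": design,
        "probe_map": pmap,
        "truth": truth,
    }
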