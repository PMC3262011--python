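"""Synthetic discordant-twin cohorts with known ground truth.

The generative model, per CpG probe, works on the logit (log-odds) scale
so that beta values concentrate near 0 and 1 as they do on 27K-style
arrays:

* a gene-level baseline drawn from a 3-component mixture
  (low / intermediate / high methylation) plus a per-probe offset;
* a pair-level shared effect implementing MZ genetic identity — shared
  between co-twins and across cell types;
* individual-level noise whose variance is calibrated so that the
  co-twin rank correlation of the beta columns approximates
  ``cotwin_correlation_target``;
* for planted genes, a latent per-pair discordance score ``z_p`` feeds
  both the methylation co-twin difference and the expression log fold
  change, so that their per-gene correlation across pairs has a known
  population magnitude and sign.

Betas additionally receive individual beta-scale noise
(``biological_noise_beta``) and are clipped to [0, 1]; expression is
generated on the log2 scale and emitted as positive intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .datamodel import (
    AFFECTED,
    UNAFFECTED,
    ConfigError,
    FeatureMatrix,
    GeneSetCollection,
    ProbeGeneMap,
    TwinDesign,
)

__all__ = [
    "SimulationConfig",
    "TruthLabels",
    "simulate_cohort",
    "simulate_replicates",
    "simulate_gene_annotations",
]

# Mixture of logit-scale baselines: mostly hypo- or hyper-methylated
# probes, a thin intermediate component.
_MIX_WEIGHTS = (0.45, 0.10, 0.45)
_MIX_MEANS = (-3.0, 0.0, 3.0)
_MIX_SDS = (0.8, 1.0, 0.8)
_PROBE_OFFSET_SD = 0.5
_PAIR_EFFECT_SD = 0.3
_EXPR_BASELINE_MEAN = 8.0
_EXPR_BASELINE_SD = 2.5
_EXPR_PAIR_EFFECT_SD = 0.4


@dataclass
class SimulationConfig:
    """Parameters of the synthetic twin cohort.

    ``latent_effect_meth`` (logit scale) and ``latent_effect_expr``
    (log2 scale) size the planted per-pair discordance signal directly;
    if ``target_planted_rho`` is set, per-gene effect sizes are instead
    calibrated so the population |rho| of the combined analysis equals
    that target.
    """

    n_pairs_per_celltype: int = 17
    n_genes: int = 11933
    cpgs_per_gene: tuple[int, int] = (1, 3)
    n_planted_genes: int = 0
    latent_effect_meth: float = 0.0
    latent_effect_expr: float = 0.0
    biological_noise_beta: float = 0.01
    technical_noise_beta: float = 0.005
    biological_noise_log2expr: float = 0.25
    cotwin_correlation_target: float = 0.98
    n_replicated_pairs: int = 0
    n_celltype_specific_features: int = 0
    target_planted_rho: float | None = None
    cell_types: tuple[str, str] = ("CD4", "CD8")
    disease_set_size: int = 60
    n_terms: int = 20
    term_size: tuple[int, int] = (20, 200)
    enrichment_bias: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_pairs_per_celltype": self.n_pairs_per_celltype,
            "n_genes": self.n_genes,
            "n_planted_genes": self.n_planted_genes,
            "n_replicated_pairs": self.n_replicated_pairs,
            "n_celltype_specific_features": self.n_celltype_specific_features,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigError(f"invariant violated: {name} must be >= 0, got {value}")
        if self.n_pairs_per_celltype < 1:
            raise ConfigError("invariant violated: n_pairs_per_celltype must be >= 1")
        if self.n_genes < 1:
            raise ConfigError("invariant violated: n_genes must be >= 1")
        lo, hi = self.cpgs_per_gene
        if not (1 <= lo <= hi):
            raise ConfigError(
                f"invariant violated: cpgs_per_gene must satisfy 1 <= min <= max, got {self.cpgs_per_gene}"
            )
        if self.n_planted_genes > self.n_genes:
            raise ConfigError(
                "invariant violated: n_planted_genes must be <= n_genes "
                f"({self.n_planted_genes} > {self.n_genes})"
            )
        if self.technical_noise_beta > 0 and not (
            self.technical_noise_beta < self.biological_noise_beta
        ):
            raise ConfigError(
                "invariant violated: technical_noise_beta must be smaller than "
                f"biological_noise_beta ({self.technical_noise_beta} >= {self.biological_noise_beta})"
            )
        for name in ("biological_noise_beta", "technical_noise_beta", "biological_noise_log2expr"):
            if getattr(self, name) < 0:
                raise ConfigError(f"invariant violated: {name} must be >= 0")
        if not (0.0 < self.cotwin_correlation_target < 1.0):
            raise ConfigError(
                "invariant violated: cotwin_correlation_target must lie in (0, 1), "
                f"got {self.cotwin_correlation_target}"
            )
        if self.target_planted_rho is not None and not (0.0 < self.target_planted_rho < 1.0):
            raise ConfigError("invariant violated: target_planted_rho must lie in (0, 1)")
        if not (0.0 <= self.enrichment_bias <= 1.0):
            raise ConfigError("invariant violated: enrichment_bias must lie in [0, 1]")
        if self.n_replicated_pairs > self.n_pairs_per_celltype:
            raise ConfigError(
                "invariant violated: n_replicated_pairs must be <= n_pairs_per_celltype"
            )


@dataclass
class TruthLabels:
    """Ground truth of a simulated cohort."""

    planted_gene_ids: set[str] = field(default_factory=set)
    planted_sign: dict[str, int] = field(default_factory=dict)
    celltype_specific_feature_ids: set[str] = field(default_factory=set)


def _calibrate_logit_noise(
    m_probe: np.ndarray,
    biological_noise_beta: float,
    target: float,
    rng: np.random.Generator,
) -> float:
    """Find the individual logit-noise SD matching the co-twin rank correlation.

    Simulates one co-twin column pair under common random numbers and
    bisects on the noise SD; the rank correlation is monotone decreasing
    in it.  Returns 0 when even the beta-scale noise alone already
    undershoots the target.
    """
    from scipy.stats import spearmanr

    n = m_probe.size
    u = rng.normal(0.0, _PAIR_EFFECT_SD, size=n)
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    b1 = rng.normal(0.0, biological_noise_beta, size=n)
    b2 = rng.normal(0.0, biological_noise_beta, size=n)

    def measured(s: float) -> float:
        x1 = np.clip(expit(m_probe + u + s * e1) + b1, 0.0, 1.0)
        x2 = np.clip(expit(m_probe + u + s * e2) + b2, 0.0, 1.0)
        return float(spearmanr(x1, x2).statistic)

    if measured(0.0) <= target:
        return 0.0
    lo, hi = 0.0, 0.25
    while measured(hi) > target and hi < 8.0:
        lo, hi = hi, hi * 2.0
    for _ in range(25):
        mid = 0.5 * (lo + hi)
        if measured(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sample_columns(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    width = max(2, len(str(config.n_pairs_per_celltype)))
    for ct in config.cell_types:
        for p in range(config.n_pairs_per_celltype):
            pair_id = f"pair{p + 1:0{width}d}"
            for status, tag in ((UNAFFECTED, "U"), (AFFECTED, "A")):
                rows.append(
                    {
                        "sample_id": f"{pair_id}_{tag}_{ct}",
                        "pair_id": pair_id,
                        "status": status,
                        "cell_type": ct,
                        "replicate_of": "",
                        "excluded": False,
                        "exclude_reason": "",
                        "pair_index": p,
                    }
                )
    return pd.DataFrame(rows)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[FeatureMatrix, FeatureMatrix, TwinDesign, ProbeGeneMap, TruthLabels]:
    """Generate a full twin cohort; bit-reproducible for a fixed seed.

    Returns ``(beta, expression, design, probe_map, truth)``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (
        ss_struct,
        ss_meth,
        ss_expr,
        ss_latent,
        ss_ct,
        ss_rep,
        _ss_annot,
    ) = ss.spawn(7)
    rng_struct = np.random.default_rng(ss_struct)
    rng_meth = np.random.default_rng(ss_meth)
    rng_expr = np.random.default_rng(ss_expr)
    rng_latent = np.random.default_rng(ss_latent)
    rng_ct = np.random.default_rng(ss_ct)

    G = config.n_genes
    P = config.n_pairs_per_celltype
    gene_ids = np.array([f"g{i + 1:06d}" for i in range(G)], dtype=object)
    lo, hi = config.cpgs_per_gene
    k_per_gene = rng_struct.integers(lo, hi + 1, size=G)
    n_probes = int(k_per_gene.sum())
    probe_ids = np.array([f"cg{i + 1:08d}" for i in range(n_probes)], dtype=object)
    probe_gene_idx = np.repeat(np.arange(G), k_per_gene)
    probe_map = ProbeGeneMap(pd.Series(gene_ids[probe_gene_idx], index=probe_ids))

    # --- baselines -------------------------------------------------------
    comp = rng_struct.choice(3, size=G, p=_MIX_WEIGHTS)
    gene_logit = np.take(_MIX_MEANS, comp) + rng_struct.normal(
        0.0, np.take(_MIX_SDS, comp), size=G
    )
    m_probe = gene_logit[probe_gene_idx] + rng_struct.normal(
        0.0, _PROBE_OFFSET_SD, size=n_probes
    )
    beta0 = expit(m_probe)
    w_probe = beta0 * (1.0 - beta0)  # d(beta)/d(logit) at the baseline

    expr_baseline = rng_struct.normal(_EXPR_BASELINE_MEAN, _EXPR_BASELINE_SD, size=G)

    # --- noise calibration ----------------------------------------------
    if config.biological_noise_beta == 0.0:
        s_meth = 0.0
    else:
        s_meth = _calibrate_logit_noise(
            m_probe,
            config.biological_noise_beta,
            config.cotwin_correlation_target,
            np.random.default_rng(np.random.SeedSequence((config.seed, 97))),
        )

    # --- planted cross-assay signal -------------------------------------
    truth = TruthLabels()
    alpha_probe = np.zeros(n_probes)  # logit-scale effect per unit z
    b_gene = np.zeros(G)  # signed log2-scale effect per unit z
    z_pair = rng_latent.standard_normal(P)
    if config.n_planted_genes > 0:
        planted_idx = rng_latent.choice(G, size=config.n_planted_genes, replace=False)
        signs = rng_latent.choice([-1, 1], size=config.n_planted_genes)
        truth.planted_gene_ids = set(gene_ids[planted_idx])
        truth.planted_sign = {
            str(gene_ids[i]): int(s) for i, s in zip(planted_idx, signs)
        }
        if config.target_planted_rho is not None:
            eta = math.sqrt(config.target_planted_rho / (1.0 - config.target_planted_rho))
            # per-gene noise variance of the gene-level deltaBeta (delta method)
            per_probe_var = 2.0 * (s_meth * w_probe) ** 2 + 2.0 * config.biological_noise_beta**2
            var_sum = np.bincount(probe_gene_idx, weights=per_probe_var, minlength=G)
            vm_gene = var_sum / k_per_gene.astype(float) ** 2
            w_sum = np.bincount(probe_gene_idx, weights=w_probe, minlength=G)
            w_mean = np.clip(w_sum / k_per_gene, 0.02, None)
            a_gene = eta * np.sqrt(vm_gene) / w_mean  # logit units
            ve = 2.0 * config.biological_noise_log2expr**2
            b_mag = eta * math.sqrt(ve)
        else:
            a_gene = np.full(G, config.latent_effect_meth)
            b_mag = config.latent_effect_expr
        alpha_by_gene = np.zeros(G)
        alpha_by_gene[planted_idx] = a_gene[planted_idx]
        alpha_probe = alpha_by_gene[probe_gene_idx]
        b_gene[planted_idx] = signs * b_mag

    # --- cell-type specific features ------------------------------------
    ct_shift_probe = np.zeros(n_probes)
    ct_shift_gene = np.zeros(G)
    if config.n_celltype_specific_features > 0:
        n_ct = min(config.n_celltype_specific_features, n_probes)
        sel_probes = rng_ct.choice(n_probes, size=n_ct, replace=False)
        ct_shift_probe[sel_probes] = rng_ct.choice([-1.0, 1.0], size=n_ct) * rng_ct.uniform(
            0.8, 1.6, size=n_ct
        )
        n_ctg = min(config.n_celltype_specific_features, G)
        sel_genes = rng_ct.choice(G, size=n_ctg, replace=False)
        ct_shift_gene[sel_genes] = rng_ct.choice([-1.0, 1.0], size=n_ctg) * rng_ct.uniform(
            0.8, 1.6, size=n_ctg
        )
        truth.celltype_specific_feature_ids = set(probe_ids[sel_probes]) | set(
            gene_ids[sel_genes]
        )

    # --- assemble columns ------------------------------------------------
    columns = _sample_columns(config)
    n_cols = len(columns)
    col_pair = columns["pair_index"].to_numpy()
    col_status_sign = np.where(columns["status"] == UNAFFECTED, 1.0, -1.0)
    col_is_ct2 = (columns["cell_type"] == config.cell_types[1]).to_numpy()
    col_is_ct1 = ~col_is_ct2

    pair_effect_meth = rng_meth.normal(0.0, _PAIR_EFFECT_SD, size=(n_probes, P))
    x = m_probe[:, None] + pair_effect_meth[:, col_pair]
    if col_is_ct2.any():
        x[:, col_is_ct2] += ct_shift_probe[:, None]
    # planted discordance acts in the first cell type only
    plant = 0.5 * alpha_probe[:, None] * (
        z_pair[col_pair] * col_status_sign * col_is_ct1
    )[None, :]
    x += plant
    if s_meth > 0.0:
        x += rng_meth.normal(0.0, s_meth, size=(n_probes, n_cols))
    beta_vals = expit(x)
    if config.biological_noise_beta > 0.0:
        beta_vals = beta_vals + rng_meth.normal(
            0.0, config.biological_noise_beta, size=(n_probes, n_cols)
        )
    np.clip(beta_vals, 0.0, 1.0, out=beta_vals)

    pair_effect_expr = rng_expr.normal(0.0, _EXPR_PAIR_EFFECT_SD, size=(G, P))
    y = expr_baseline[:, None] + pair_effect_expr[:, col_pair]
    if col_is_ct2.any():
        y[:, col_is_ct2] += ct_shift_gene[:, None]
    y += 0.5 * b_gene[:, None] * (z_pair[col_pair] * col_status_sign * col_is_ct1)[None, :]
    if config.biological_noise_log2expr > 0.0:
        y += rng_expr.normal(0.0, config.biological_noise_log2expr, size=(G, n_cols))
    expr_vals = np.exp2(y)

    sample_ids = columns["sample_id"].tolist()
    beta = FeatureMatrix(probe_ids, pd.Index(sample_ids), beta_vals, "methylation-beta")
    expr = FeatureMatrix(gene_ids, pd.Index(sample_ids), expr_vals, "expression-intensity")
    design = TwinDesign(columns.drop(columns=["pair_index"]))

    if config.n_replicated_pairs > 0:
        beta, design = simulate_replicates(beta, design, config)
    return beta, expr, design, probe_map, truth


def simulate_replicates(
    beta: FeatureMatrix,
    design: TwinDesign,
    config: SimulationConfig,
    cell_type: str | None = None,
) -> tuple[FeatureMatrix, TwinDesign]:
    """Append one technical replicate column per sample of the selected pairs.

    Replicate values are the original beta plus noise with SD
    ``technical_noise_beta``, clipped to [0, 1]; ``replicate_of`` marks
    provenance.
    """
    config.validate()
    if cell_type is None:
        cell_type = config.cell_types[0]
    pairs = design.complete_pairs(cell_type)
    if config.n_replicated_pairs > len(pairs):
        raise ConfigError(
            f"requested {config.n_replicated_pairs} replicated pairs but only "
            f"{len(pairs)} complete pairs exist in cell type {cell_type!r}"
        )
    if config.n_replicated_pairs == 0:
        return beta, design
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 211)))
    sel = rng.choice(len(pairs), size=config.n_replicated_pairs, replace=False)
    sel_pairs = pairs.iloc[np.sort(sel)]

    new_cols = []
    new_rows = []
    for _, row in sel_pairs.iterrows():
        for status_col in ("unaffected", "affected"):
            orig = row[status_col]
            rep_id = f"{orig}_rep"
            values = beta.column(orig).copy()
            if config.technical_noise_beta > 0.0:
                values = values + rng.normal(
                    0.0, config.technical_noise_beta, size=values.shape
                )
                np.clip(values, 0.0, 1.0, out=values)
            new_cols.append((rep_id, values))
            src = design.table.loc[design.table["sample_id"] == orig].iloc[0]
            new_rows.append(
                {
                    "sample_id": rep_id,
                    "pair_id": src["pair_id"],
                    "status": src["status"],
                    "cell_type": src["cell_type"],
                    "replicate_of": orig,
                    "excluded": False,
                    "exclude_reason": "",
                }
            )
    all_values = np.column_stack([beta.values] + [v for _, v in new_cols])
    all_ids = list(beta.sample_ids) + [rid for rid, _ in new_cols]
    new_beta = FeatureMatrix(beta.feature_ids, pd.Index(all_ids), all_values, beta.kind)
    new_table = pd.concat(
        [design.table, pd.DataFrame(new_rows)], ignore_index=True
    )
    return new_beta, TwinDesign(new_table)


def simulate_gene_annotations(
    genes: Sequence[str],
    truth: TruthLabels,
    config: SimulationConfig,
) -> tuple[GeneSetCollection, GeneSetCollection]:
    """Generate a disease gene set and a collection of annotation terms.

    Planted genes are preferentially assigned (with probability
    ``enrichment_bias``) to the disease set and to the first few terms,
    so enrichment stages have recoverable signal; with bias 0 the sets
    are uniform random draws.
    """
    config.validate()
    genes = [str(g) for g in genes]
    if not genes:
        raise ConfigError("invariant violated: gene universe must be nonempty")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 409)))
    universe = np.array(genes, dtype=object)
    planted = sorted(truth.planted_gene_ids & set(genes))

    def _biased_draw(size: int, bias: float) -> list[str]:
        size = min(size, len(universe))
        take_planted = [g for g in planted if rng.random() < bias][:size]
        remaining = [g for g in universe if g not in set(take_planted)]
        n_fill = size - len(take_planted)
        fill = rng.choice(len(remaining), size=n_fill, replace=False) if n_fill else []
        return sorted(take_planted + [remaining[i] for i in fill])

    disease = GeneSetCollection()
    disease.add(
        "disease_associated",
        "simulated disease-associated gene set",
        _biased_draw(config.disease_set_size, config.enrichment_bias),
    )
    terms = GeneSetCollection()
    t_lo, t_hi = config.term_size
    for t in range(config.n_terms):
        size = int(rng.integers(t_lo, t_hi + 1))
        bias = config.enrichment_bias if t < 3 else 0.0
        terms.add(
            f"TERM{t + 1:04d}",
            f"simulated annotation term {t + 1}",
            _biased_draw(size, bias),
        )
    return disease, terms
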