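"""End-to-end workflow: simulate -> preprocess -> diff -> similarity ->
integrate -> enrich, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .datamodel import ConfigError, PipelineError
from . import enrich as enrich_mod
from . import integrate as integrate_mod
from . import io as io_mod
from . import paired as paired_mod
from . import preprocess as pre_mod
from . import similarity as sim_mod
from .simulate import SimulationConfig, simulate_cohort, simulate_gene_annotations

log = logging.getLogger(__name__)

__all__ = ["run_all", "load_config"]


def load_config(path: str | Path) -> dict:
    """Load a JSON/YAML keyed configuration file."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g", na_rep="NA")


class _Stage:
    """Context manager that prefixes stage name and context onto errors."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, PipelineError):
            raise PipelineError(f"stage {self.name!r} failed: {exc}") from exc
        if isinstance(exc, PipelineError) and not str(exc).startswith("stage"):
            raise PipelineError(f"stage {self.name!r} failed: {exc}") from exc
        log.info("stage %s: done", self.name)
        return False


def run_all(config: dict, outdir: str | Path, seed: int | None = None) -> Path:
    """Run the whole study workflow into ``outdir``; returns the run dir.

    The configuration has a ``simulate`` section (synthetic cohort
    parameters) or an ``inputs`` section (paths to beta/expression/design
    files), plus an ``analysis`` section.  Deterministic given the seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs_dir = outdir / "inputs"
    inputs_dir.mkdir(exist_ok=True)
    analysis = dict(config.get("analysis", {}))
    if seed is None:
        seed = int(config.get("seed", 0))
    manifest: dict = {
        "versions": {
            "cotwin": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "seed": seed,
        "config": config,
        "input_hashes": {},
        "n": {},
    }

    disease_sets = terms = None
    with _Stage("inputs"):
        if "simulate" in config:
            sim_kwargs = dict(config["simulate"])
            sim_kwargs.setdefault("seed", seed)
            for key in ("cpgs_per_gene", "cell_types", "term_size"):
                if key in sim_kwargs:
                    sim_kwargs[key] = tuple(sim_kwargs[key])
            sim_config = SimulationConfig(**sim_kwargs)
            beta, expr, design, probe_map, truth = simulate_cohort(sim_config)
            disease_sets, terms = simulate_gene_annotations(
                list(expr.feature_ids), truth, sim_config
            )
            io_mod.write_matrix(beta, inputs_dir / "beta.tsv")
            io_mod.write_matrix(expr, inputs_dir / "expression.tsv")
            io_mod.write_design(design, inputs_dir / "design.tsv")
            io_mod.write_probe_map(probe_map, inputs_dir / "probe_map.tsv")
            io_mod.write_gmt(disease_sets, inputs_dir / "disease_sets.gmt")
            io_mod.write_gmt(terms, inputs_dir / "terms.gmt")
            truth_frame = pd.DataFrame(
                {
                    "gene_id": sorted(truth.planted_gene_ids),
                    "planted_sign": [
                        truth.planted_sign[g] for g in sorted(truth.planted_gene_ids)
                    ],
                }
            )
            _write_tsv(truth_frame, inputs_dir / "truth_planted.tsv")
        elif "inputs" in config:
            paths = config["inputs"]
            if "beta" not in paths or "design" not in paths:
                raise ConfigError("inputs section needs at least 'beta' and 'design'")
            beta = io_mod.read_matrix(paths["beta"], "methylation-beta")
            design = io_mod.read_design(paths["design"])
            expr = (
                io_mod.read_matrix(paths["expression"], "expression-intensity")
                if "expression" in paths
                else None
            )
            probe_map = (
                io_mod.read_probe_map(paths["probe_map"])
                if "probe_map" in paths
                else None
            )
            disease_sets = (
                io_mod.read_gmt(paths["disease_sets"]) if "disease_sets" in paths else None
            )
            terms = io_mod.read_gmt(paths["terms"]) if "terms" in paths else None
        else:
            raise ConfigError("config needs a 'simulate' or an 'inputs' section")
        for f in sorted(inputs_dir.glob("*")):
            manifest["input_hashes"][f.name] = _sha256(f)

    cell_type = analysis.get("cell_type", design.cell_types[0])
    fdr = float(analysis.get("fdr", 0.05))
    log2_offset = float(analysis.get("log2_offset", 1.0))
    qn = analysis.get("quantile_normalize", "expr")
    top_fraction = float(analysis.get("top_fraction", 0.01))
    disease_top_k = int(analysis.get("disease_top_k", 50))

    with _Stage("preprocess"):
        if "probe_whitelist" in analysis:
            whitelist = set(
                pd.read_csv(analysis["probe_whitelist"], sep="\t", header=None)[0]
            )
            beta = pre_mod.filter_probes(beta, whitelist)
        if qn in ("beta", "both"):
            beta = pre_mod.quantile_normalize(beta)
        if probe_map is not None:
            gene_beta = pre_mod.aggregate_cpgs_to_gene(beta, probe_map)
        else:
            gene_beta = None
        if expr is not None:
            if qn in ("expr", "both"):
                expr = pre_mod.quantile_normalize(expr)
            expr_log2 = pre_mod.log2_transform(expr, offset=log2_offset)
        else:
            expr_log2 = None
        manifest["n"]["probes"] = len(beta.feature_ids)
        manifest["n"]["genes_beta"] = (
            len(gene_beta.feature_ids) if gene_beta is not None else 0
        )
        manifest["n"]["pairs"] = {ct: design.n_pairs(ct) for ct in design.cell_types}

    with _Stage("similarity"):
        per_pair, summary = sim_mod.cotwin_correlation(
            beta, design, cell_type, method="spearman"
        )
        _write_tsv(per_pair, outdir / "cotwin_correlation_beta.tsv")
        manifest["cotwin_correlation_beta"] = summary
        if expr_log2 is not None:
            per_pair_e, summary_e = sim_mod.cotwin_correlation(
                expr_log2, design, cell_type, method="pearson"
            )
            _write_tsv(per_pair_e, outdir / "cotwin_correlation_expr.tsv")
            manifest["cotwin_correlation_expr"] = summary_e
        if not design.replicate_table().empty:
            tech, bio = sim_mod.technical_vs_biological(beta, design)
            d_stat, p_ks = sim_mod.ks_two_sample(tech.values, bio.values)
            ecdf = pd.DataFrame(
                {"feature_id": tech.index, "technical": tech.values, "biological": bio.values}
            )
            _write_tsv(ecdf, outdir / "technical_vs_biological.tsv")
            manifest["ks_technical_vs_biological"] = {"D": d_stat, "p": p_ks}

    with _Stage("diff"):
        cpg_diffs = pre_mod.compute_pair_differences(beta, design, cell_type)
        cpg_res = paired_mod.paired_t_test(cpg_diffs)
        adj = paired_mod.bh_adjust(cpg_res["p_raw"].to_numpy(), q=fdr)
        cpg_res["p_adj"] = adj["p_adj"].to_numpy()
        cpg_res["significant"] = adj["significant"].to_numpy()
        _write_tsv(cpg_res, outdir / "cotwin_diff_cpg.tsv")
        _write_tsv(
            paired_mod.volcano_table(cpg_res, fdr=fdr), outdir / "volcano_cotwin_cpg.tsv"
        )
        n_sig = int(cpg_res["significant"].sum())
        manifest["n"]["cotwin_significant_cpgs"] = n_sig
        manifest["n"]["cotwin_tested_cpgs"] = int(cpg_res["p_raw"].notna().sum())

        meth_gene_diffs = None
        if gene_beta is not None:
            meth_gene_diffs = pre_mod.compute_pair_differences(gene_beta, design, cell_type)
            gene_res = paired_mod.paired_t_test(meth_gene_diffs)
            adj = paired_mod.bh_adjust(gene_res["p_raw"].to_numpy(), q=fdr)
            gene_res["p_adj"] = adj["p_adj"].to_numpy()
            gene_res["significant"] = adj["significant"].to_numpy()
            _write_tsv(gene_res, outdir / "cotwin_diff_gene.tsv")

        expr_diffs = None
        if expr_log2 is not None:
            expr_diffs = pre_mod.compute_pair_differences(expr_log2, design, cell_type)
            mod_res, hyper = paired_mod.moderated_t_test(expr_diffs)
            adj = paired_mod.bh_adjust(mod_res["p_raw"].to_numpy(), q=fdr)
            mod_res["p_adj"] = adj["p_adj"].to_numpy()
            mod_res["significant"] = adj["significant"].to_numpy()
            _write_tsv(mod_res, outdir / "cotwin_diff_expression.tsv")
            _write_tsv(
                paired_mod.volcano_table(mod_res, significance="log_odds"),
                outdir / "volcano_cotwin_expression.tsv",
            )
            manifest["moderated_t_hyperparameters"] = {
                k: (v if np.isfinite(v) else "inf") for k, v in hyper.items()
            }

        permutation = analysis.get("permutation", "off")
        if permutation != "off":
            perm = paired_mod.signflip_permutation_test(
                cpg_diffs,
                mode=permutation,
                B=int(analysis.get("permutation_B", 10000)),
                seed=seed + 7,
            )
            _write_tsv(perm, outdir / "cotwin_permutation_cpg.tsv")
            manifest["n"]["permutation_arrangements"] = int(perm["n_arrangements"].iloc[0])

        cts = design.cell_types
        if len(cts) >= 2:
            try:
                ct_diffs = pre_mod.compute_celltype_differences(
                    beta, design, (cts[0], cts[1])
                )
            except PipelineError:
                ct_diffs = None
            if ct_diffs is not None:
                ct_res = paired_mod.paired_t_test(ct_diffs)
                adj = paired_mod.bh_adjust(ct_res["p_raw"].to_numpy(), q=fdr)
                ct_res["p_adj"] = adj["p_adj"].to_numpy()
                ct_res["significant"] = adj["significant"].to_numpy()
                _write_tsv(ct_res, outdir / "celltype_diff_cpg.tsv")
                _write_tsv(
                    paired_mod.volcano_table(ct_res, fdr=fdr),
                    outdir / "volcano_celltype_cpg.tsv",
                )
                n_sig_ct = int(ct_res["significant"].sum())
                n_tested_ct = int(ct_res["p_raw"].notna().sum())
                manifest["celltype_contrast"] = {
                    "n_significant": n_sig_ct,
                    "n_tested": n_tested_ct,
                    "percent_significant": paired_mod.percent_significant(
                        n_sig_ct, n_tested_ct
                    ),
                }

    top_genes = None
    ranked = None
    with _Stage("integrate"):
        if expr_diffs is None or meth_gene_diffs is None:
            raise ConfigError(
                "integration requires both a gene-level methylation input "
                "(beta + probe map) and an expression input"
            )
        records = integrate_mod.combined_correlation(meth_gene_diffs, expr_diffs)
        ranked = integrate_mod.rank_genes(records)
        _write_tsv(ranked, outdir / "combined_correlation_full.tsv")
        top_genes = integrate_mod.select_top_fraction(ranked, top_fraction)
        table1 = integrate_mod.format_correlation_table(ranked.head(disease_top_k))
        _write_tsv(table1, outdir / "combined_correlation_top.tsv")
        manifest["n"]["genes_integrated"] = len(ranked)
        manifest["n"]["top_fraction_genes"] = len(top_genes)

    with _Stage("enrich"):
        background = ranked["gene_id"].tolist()
        if disease_sets is not None and len(disease_sets) > 0:
            top_k = ranked["gene_id"].head(disease_top_k).tolist()
            gs = next(iter(disease_sets))
            table, p_fisher = enrich_mod.fisher_overrepresentation(
                top_k, gs, background
            )
            manifest["disease_overrepresentation"] = {
                "set": gs.name,
                "table": table,
                "p": p_fisher,
                "top_k": disease_top_k,
            }
        if terms is not None and len(terms) > 0:
            enr = enrich_mod.term_enrichment(
                top_genes, terms, background, ease=bool(analysis.get("ease", False)), q=fdr
            )
            _write_tsv(enr, outdir / "term_enrichment.tsv")
            manifest["n"]["terms_tested"] = len(enr)

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return outdir
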