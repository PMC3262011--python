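import numpy as np
import pytest

from cotwin.datamodel import ConfigError
from cotwin.preprocess import (
    aggregate_cpgs_to_gene,
    compute_pair_differences,
    log2_transform,
)
from cotwin.integrate import combined_correlation
from cotwin.similarity import cotwin_correlation, ks_two_sample
from cotwin.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_gene_annotations,
    simulate_replicates,
)


class TestConfigValidation:
    def test_negative_count_rejected(self):
        with pytest.raises(ConfigError, match="n_planted_genes"):
            SimulationConfig(n_planted_genes=-1).validate()

    def test_technical_noise_must_be_smaller(self):
        with pytest.raises(ConfigError, match="technical_noise_beta"):
            SimulationConfig(technical_noise_beta=0.02, biological_noise_beta=0.01).validate()

    def test_planted_exceeding_genes_rejected(self):
        with pytest.raises(ConfigError, match="n_planted_genes"):
            SimulationConfig(n_genes=10, n_planted_genes=11).validate()

    def test_bad_cpg_range_rejected(self):
        with pytest.raises(ConfigError, match="cpgs_per_gene"):
            SimulationConfig(cpgs_per_gene=(3, 1)).validate()

    def test_noiseless_config_is_valid(self):
        SimulationConfig(
            biological_noise_beta=0.0,
            technical_noise_beta=0.0,
            biological_noise_log2expr=0.0,
        ).validate()


class TestCohortStructure:
    def test_dimensions_and_ranges(self, small_cohort):
        beta = small_cohort["beta"]
        expr = small_cohort["expr"]
        config = small_cohort["config"]
        pmap = small_cohort["probe_map"]
        assert len(beta.feature_ids) == len(pmap)
        assert len(expr.feature_ids) == config.n_genes
        n_primary = 2 * config.n_pairs_per_celltype * 2
        assert len(expr.sample_ids) == n_primary
        assert len(beta.sample_ids) == n_primary + 2 * config.n_replicated_pairs
        assert beta.values.min() >= 0.0 and beta.values.max() <= 1.0
        assert (expr.values > 0).all()

    def test_truth_labels_consistent(self, small_cohort):
        truth = small_cohort["truth"]
        config = small_cohort["config"]
        genes = set(small_cohort["expr"].feature_ids)
        assert len(truth.planted_gene_ids) == config.n_planted_genes
        assert truth.planted_gene_ids <= genes
        assert set(truth.planted_sign) == truth.planted_gene_ids
        assert set(truth.planted_sign.values()) <= {-1, 1}

    def test_bit_reproducible(self):
        config = SimulationConfig(n_pairs_per_celltype=3, n_genes=40, seed=11)
        a = simulate_cohort(config)
        b = simulate_cohort(config)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[1].values, b[1].values)
        assert a[4].planted_gene_ids == b[4].planted_gene_ids

    def test_noiseless_twins_identical(self):
        config = SimulationConfig(
            n_pairs_per_celltype=4,
            n_genes=50,
            biological_noise_beta=0.0,
            technical_noise_beta=0.0,
            biological_noise_log2expr=0.0,
            seed=3,
        )
        beta, expr, design, _, _ = simulate_cohort(config)
        for matrix in (beta, expr):
            for _, row in design.complete_pairs("CD4").iterrows():
                np.testing.assert_array_equal(
                    matrix.column(row["unaffected"]), matrix.column(row["affected"])
                )
        diffs = compute_pair_differences(beta, design, "CD4")
        assert (diffs.values == 0).all()

    def test_cotwin_correlation_matches_target(self):
        config = SimulationConfig(n_genes=2500, seed=5)
        beta, _, design, _, _ = simulate_cohort(config)
        _, summary = cotwin_correlation(beta, design, "CD4", method="spearman")
        assert abs(summary["mean_raw"] - config.cotwin_correlation_target) < 0.02


class TestReplicates:
    def test_zero_noise_replicates_equal_originals(self):
        config = SimulationConfig(
            n_pairs_per_celltype=4,
            n_genes=30,
            n_replicated_pairs=2,
            biological_noise_beta=0.01,
            technical_noise_beta=0.0,
            seed=2,
        )
        beta, _, design, _, _ = simulate_cohort(config)
        reps = design.replicate_table()
        assert len(reps) == 4
        for _, row in reps.iterrows():
            np.testing.assert_array_equal(
                beta.column(row["sample_id"]), beta.column(row["replicate_of"])
            )

    def test_seven_replicated_pairs_on_13_pair_design(self):
        config = SimulationConfig(
            n_pairs_per_celltype=13, n_genes=30, n_replicated_pairs=7, seed=2
        )
        beta, _, design, _, _ = simulate_cohort(config)
        reps = design.replicate_table()
        assert reps["pair_id"].nunique() == 7
        assert len(reps) == 14  # both co-twins of each replicated pair

    def test_more_replicates_than_pairs_rejected(self):
        config = SimulationConfig(n_pairs_per_celltype=3, n_genes=20, seed=2)
        beta, _, design, _, _ = simulate_cohort(config)
        bad = SimulationConfig(n_pairs_per_celltype=3, n_genes=20, n_replicated_pairs=3, seed=2)
        # design excludes one pair -> only 2 complete pairs remain
        table = design.table.copy()
        table.loc[table["pair_id"] == "pair01", "excluded"] = True
        from cotwin.datamodel import TwinDesign

        with pytest.raises(ConfigError, match="replicated pairs"):
            simulate_replicates(beta, TwinDesign(table), bad)

    def test_self_self_smaller_than_cotwin(self):
        config = SimulationConfig(
            n_pairs_per_celltype=8,
            n_genes=3000,
            n_replicated_pairs=4,
            biological_noise_beta=0.02,
            technical_noise_beta=0.01,
            seed=9,
        )
        beta, _, design, _, _ = simulate_cohort(config)
        from cotwin.similarity import technical_vs_biological

        tech, bio = technical_vs_biological(beta, design)
        assert np.median(tech) < np.median(bio)
        _, p = ks_two_sample(tech.values, bio.values)
        assert p < 1e-6


class TestAnnotations:
    def test_empty_universe_rejected(self, small_cohort):
        with pytest.raises(ConfigError, match="nonempty"):
            simulate_gene_annotations([], small_cohort["truth"], small_cohort["config"])

    def test_planted_term_ranks_first(self, small_cohort):
        from cotwin.datamodel import GeneSetCollection
        from cotwin.enrich import term_enrichment
        from cotwin.integrate import (
            combined_correlation,
            rank_genes,
            select_top_fraction,
        )
        from cotwin.preprocess import quantile_normalize

        cohort = small_cohort
        gene_beta = aggregate_cpgs_to_gene(cohort["beta"], cohort["probe_map"])
        mdiff = compute_pair_differences(gene_beta, cohort["design"], "CD4")
        ediff = compute_pair_differences(
            log2_transform(quantile_normalize(cohort["expr"])), cohort["design"], "CD4"
        )
        ranked = rank_genes(combined_correlation(mdiff, ediff))
        top = select_top_fraction(ranked, 0.2)
        planted = sorted(cohort["truth"].planted_gene_ids)
        terms = GeneSetCollection()
        terms.add("planted", "exactly the planted genes", planted)
        terms.add("random", "unrelated", sorted(set(ranked["gene_id"]) - set(planted))[:40])
        result = term_enrichment(top, terms, ranked["gene_id"].tolist())
        assert result.iloc[0]["term_id"] == "planted"

    def test_bias_zero_is_uniform_draw(self, small_cohort):
        from dataclasses import replace

        config = replace(small_cohort["config"], enrichment_bias=0.0, seed=5)
        genes = list(small_cohort["expr"].feature_ids)
        disease, _ = simulate_gene_annotations(genes, small_cohort["truth"], config)
        members = set(next(iter(disease)).members)
        planted = small_cohort["truth"].planted_gene_ids
        # under a uniform draw the planted fraction matches the universe fraction
        expected = len(members) * len(planted) / len(genes)
        assert abs(len(members & planted) - expected) < 4 * np.sqrt(expected + 1)

    def test_gmt_serializable(self, small_cohort, tmp_path):
        from cotwin import io as io_mod

        genes = list(small_cohort["expr"].feature_ids)
        disease, terms = simulate_gene_annotations(
            genes, small_cohort["truth"], small_cohort["config"]
        )
        io_mod.write_gmt(terms, tmp_path / "terms.gmt")
        back = io_mod.read_gmt(tmp_path / "terms.gmt")
        assert back.names() == terms.names()


class TestNullCalibration:
    def test_null_combined_pvalues_uniform(self):
        """With no planted genes the combined-analysis p-values are ~U(0,1)."""
        from cotwin.preprocess import quantile_normalize

        fracs = []
        pooled = []
        for seed in range(50):
            config = SimulationConfig(
                n_pairs_per_celltype=17, n_genes=100, cpgs_per_gene=(1, 2), seed=seed
            )
            beta, expr, design, pmap, _ = simulate_cohort(config)
            gene_beta = aggregate_cpgs_to_gene(beta, pmap)
            mdiff = compute_pair_differences(gene_beta, design, "CD4")
            ediff = compute_pair_differences(
                log2_transform(quantile_normalize(expr)), design, "CD4"
            )
            records = combined_correlation(mdiff, ediff)
            pooled.append(records["p_value"].to_numpy())
        p = np.concatenate(pooled)
        frac = float(np.mean(p < 0.05))
        # 5000 pooled draws: binomial 3-sigma ~ 0.009, allow a small margin
        assert abs(frac - 0.05) < 0.012
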