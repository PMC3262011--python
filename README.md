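# cotwin

Integrative analysis of DNA methylation and gene expression in
monozygotic twin pairs discordant for a disease phenotype.

The package implements, as a tested and reusable pipeline:

* **synthetic cohorts** (`cotwin.simulate`) — twin cohorts with
  27K-array-like bimodal beta values, MZ pair-shared baselines, tunable
  co-twin correlation, technical replicates, cell-type specific
  features, and a planted set of genes whose co-twin methylation
  differences (deltaBeta) and expression log fold changes (logFC) are
  correlated across pairs with a known population rho and sign;
* **data model and IO** (`cotwin.datamodel`, `cotwin.io`) — feature
  matrices, sample sheets with pairing/status/replicate/exclusion
  metadata, probe-to-gene maps, GMT gene sets; TSV/GMT readers and
  writers with validation;
* **preprocessing** (`cotwin.preprocess`) — probe whitelisting,
  quantile normalization, log2 transform, mean-beta aggregation of CpGs
  per gene, and paired differences oriented unaffected minus affected;
* **paired statistics** (`cotwin.paired`) — per-feature paired t-tests,
  Benjamini-Hochberg step-up FDR, exhaustive (all 2^n sign flips) and
  Monte Carlo permutation nulls, a limma-style empirical-Bayes
  moderated t with log-odds, and volcano-table export;
* **similarity diagnostics** (`cotwin.similarity`) — per-pair co-twin
  correlations (Spearman/Pearson) and the technical (self-self) versus
  biological (co-twin) difference contrast with a two-sample
  Kolmogorov-Smirnov test;
* **integration** (`cotwin.integrate`) — per-gene Spearman correlation
  of deltaBeta against logFC across pairs, significance ranking, and
  top-fraction selection;
* **enrichment** (`cotwin.enrich`) — hypergeometric (Fisher)
  overrepresentation of a disease gene set in the top-ranked list, and
  per-term enrichment with frequency percentages and BH correction
  (optional EASE variant);
* **orchestration** (`cotwin.pipeline`, `cotwin.cli`) — a `run-all`
  workflow with per-stage outputs and a reproducibility manifest.

## Command line

All stages are exposed as subcommands of `cotwin`:

```sh
# generate a synthetic cohort
cotwin simulate --seed 1 --outdir out/cohort

# full workflow from a config file
cotwin run-all --config config.yaml --outdir out/run
```

A minimal `config.yaml`:

```yaml
seed: 1
simulate:
  n_pairs_per_celltype: 17
  n_genes: 11933
  n_planted_genes: 100
  target_planted_rho: 0.8
  n_replicated_pairs: 7
analysis:
  cell_type: CD4
  fdr: 0.05
  top_fraction: 0.01
```

`run-all` writes per-pair correlation tables, per-CpG/per-gene paired
test results with volcano exports, the ranked gene-correlation table
(full and top-50 reporting view), the term-enrichment table, and
`manifest.json` recording versions, seeds, parameters, input hashes and
per-stage sample counts. Other subcommands (`preprocess`, `diff`,
`similarity`, `integrate`, `enrich`) operate on TSV/GMT files directly;
see `cotwin <cmd> --help`.

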