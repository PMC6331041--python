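# ledkit

Quantifying **lineage-specific expression divergence (LED)** from tissue
expression profiles of three related species.

Comparative transcriptomics often asks not just *whether* a gene's
expression diverged between species, but *along which lineage* the change
happened. Given per-tissue expression (TPM) for 1:1:1 orthologs in three
species X, Y, Z, ledkit treats the three pairwise distances between
expression profiles as an unrooted three-taxon tree and assigns each
lineage its branch length:

```
LED_X = ½ (E_XY + E_XZ − E_YZ)
```

where `E_AB = √ Σ_t (A_t − B_t)²` is the Euclidean distance between the
species' relative-abundance profiles over the T tissues (profiles are
`log2(TPM+1)` vectors normalized to sum to one). A gene that shifted
expression along one lineage shows one disproportionately long branch.
The package was built around the wild grass *Brachypodium distachyon* and
its domesticated relatives rice (*Oryza sativa japonica*) and sorghum
(*Sorghum bicolor*), profiled in nine tissues, but runs on any
three-species TPM tables.

Around the core statistic the pipeline provides:

- **Per-generation scaling** — each lineage's LED divided by the total
  generations along its branch, `(365 / days-to-anthesis) × My × 10⁶`,
  so species with different generation times become comparable.
- **Distribution comparisons** — two-sample permutation tests (1,000
  permutations, difference of medians) between species' LED distributions.
- **Genic correlates** — tissue specificity τ = Σ(1 − x_i/x_max)/(T−1),
  primary (highest-expressed) tissue, and correlations of LED with
  externally supplied sequence divergence (gene-tree branch length, Ka,
  Ka/Ks); Poisson regression of interaction-partner counts on LED.
- **Primary-tissue enrichment** of the top 1% most divergent genes:
  χ² goodness of fit plus per-tissue exact binomial tests,
  Bonferroni-corrected over the nine tissues.
- **GO enrichment** of LED ranks: one-sided two-sample KS tests over a
  true-path-propagated is_a DAG, with the topology-aware `elim` algorithm
  (default) or `classic`, nodeSize ≥ 10, significance at P < 0.01.
- **A synthetic-data generator** that plants known expression shifts,
  correlated divergence tables and an enriched GO term, so the whole
  pipeline is testable end to end without any downloads.

## Worked example

Simulate a study (10,000 ortholog triples, nine tissues, 1% of genes given
a 16-fold single-tissue shift in anther on a random lineage) and run the
full pipeline:

```bash
ledkit simulate --outdir demo --seed 42 --n-genes 2000
ledkit run --config demo/run_config.yaml
```

This writes `demo/results/` with `led.tsv`, `led_per_generation.tsv`,
`distribution_tests.tsv`, `correlations.tsv`, `poisson.tsv`,
`tissue_enrichment.tsv`, `go_enrichment.tsv` and a `manifest.json`.
A few numbers from that run and what they mean:

- `tissue_enrichment.tsv`, anther row for *B. distachyon*:
  `observed 51  expected 11.9  chi_component 11.3  binom_p_adj 1.5e-20`
  — the planted anther shifts put far more anther-primary genes in the
  top 1% of LED than the genome-wide frequency predicts.
- `poisson.tsv`: `beta1 ≈ −1.02` for *B. distachyon* — the generator
  plants interaction counts with log-mean slope −1.0 on rank-normalized
  LED, and the regression recovers it.
- `go_enrichment.tsv`: the term named "planted divergence module"
  (annotating the 20 top-LED genes) ranks first with P ≈ 10⁻⁴⁸.

Stages can also be run in isolation (`ledkit led | correlates | enrich |
report`); `report` renders LED violin plots and the hanging chi-gram.

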