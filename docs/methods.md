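# Methods

## The branch statistic

For each 1:1:1 ortholog triple in species X, Y, Z the pipeline builds
relative-abundance expression profiles per species, computes the three
pairwise Euclidean distances `E_XY, E_XZ, E_YZ`, and decomposes them into
per-lineage branch lengths by the three-point formula
`LED_X = ½(E_XY + E_XZ − E_YZ)` (cyclically for Y, Z). The decomposition
is exact: `LED_X + LED_Y = E_XY` etc., and for distances computed from
actual vectors (hence metric) every branch is non-negative. Negative values
with magnitude ≤ 1e-12 are floating-point artifacts and are clamped to
zero; anything more negative means the input distances were not metric and
raises an error rather than being silently repaired.

The model's key assumption is the standard additive one: expression
divergence accumulates independently along each lineage, so pairwise
distances decompose into branch contributions. With three taxa a change on
the internal branch ancestral to two species is indistinguishable from
lineage-specific change — a four-taxon extension that subtracts the
internal branch would resolve this, but is out of scope here.

## Profiles and filtering

TPM tables are log-transformed and genes with `log2(TPM) > 2` (i.e.
TPM > 4) in at least one tissue are retained. The filter is applied on raw
TPM against `2^threshold`, so zeros are excluded automatically and the
pseudocount never affects filtering. A triple enters the analysis only if
all three members pass the filter in their own species — all three
profiles are needed, and no partial rule is obviously better.

Profiles are `v_t = log2(TPM_t + 1)` normalized to `Σ_t v_t = 1`. The
pseudocount (default 1) keeps zeros finite and is configurable. Distances
are taken on these log-scale shares by default; raw-TPM shares are
available as a config switch (`profile_scale: linear`) since either reading
is defensible. The log scale is the default because the transform precedes
profile construction in the procedure this implements, and because drift
in log space makes squared distances grow linearly with time (below).

## Generation scaling

Each lineage's LED is divided by the total generations along its branch:
`(365 / days_to_anthesis) × divergence_My × 10⁶`. Defaults are the grass
constants (35 d / 50 My for *B. distachyon*, 65 d / 50 My for
*O. sativa japonica*, 75 d / 60 My for *S. bicolor*), giving divisors of
≈ 5.21×10⁸, 2.81×10⁸ and 2.92×10⁸ generations. Scaling is applied per
gene (every point divided by the lineage's constant), which is the only
per-gene operation that rescales the whole distribution.

## Correlates

- τ = Σ_i (1 − x_i/x_max)/(T−1), computed on the same `log2(TPM+1)`
  values as the profiles; 0 for uniform expression, 1 for single-tissue.
- Primary tissue is the raw-TPM argmax (identical to the log-scale argmax;
  ties go to the first tissue in the run's canonical order).
- Sequence divergence (gene-tree branch length, Ka, Ka/Ks) and
  interaction counts are consumed as externally computed TSVs. Ka/Ks may
  be missing (undefined when Ks = 0 upstream) and is then excluded from
  that correlation only; every statistic reports its complete-case n.
- The top fraction (default 1%) is the ⌈fN⌉ largest-LED genes, ties
  broken by score then gene id, so the selection is deterministic.
- For regressions on LED the score is quantile-rank normalized
  (x = rank/N ∈ (0,1]). LED is strongly right-skewed, so max-normalization
  would concentrate the predictor near zero and make slopes poorly
  identified; ranks are scale-free and keep coefficients comparable
  across species.

## Inference

- Distribution comparisons use two-sample permutation tests with
  |median(a) − median(b)| as statistic and the add-one estimator
  p = (1+b)/(1+B) (B = 1,000 by default), so p is never exactly zero.
  The absolute difference makes the test two-sided. For tiny samples
  (≤ 5,000 distinct label assignments) the test switches to exhaustive
  enumeration and reports the exact tail fraction.
- Correlation tests report Pearson's r or Spearman's ρ (mid-ranks, then
  Pearson on ranks) with two-sided p from t = r√((n−2)/(1−r²)) at n−2 df.
- The interaction-count model is a Poisson regression with log link, fit
  by IRLS (tolerance 1e-8, ≤ 100 iterations) via statsmodels. The Wald
  p-value is reported for the slope. Goodness of fit is the residual
  deviance against χ²(n−2). This approximation is trustworthy only for
  sparse or large counts: at mean counts near 1 the deviance/df ratio sits
  around 1.1 and the test rejects true models at large n. Real
  interaction-partner counts are sparse (mostly zeros), and the packaged
  calibration simulation therefore uses an exponential covariate (mean 2)
  with β = (0.5, −1.0), which produces counts in that sparse regime.
- Tissue enrichment compares top-set primary-tissue counts to
  genome-frequency expectations: an overall χ² goodness of fit (T−1 df)
  and per-tissue two-sided exact binomial tests (minimum-likelihood
  method, scipy's default), Bonferroni-multiplied by the number of
  tissues (9) regardless of empty classes.

## GO enrichment

Annotations are true-path propagated over the is_a DAG (other relation
types are ignored and counted). Terms with fewer than `node_size = 10`
annotated, score-covered genes are not tested. Each eligible term gets a
one-sided two-sample KS test of its genes' scores against all remaining
genes, oriented toward high divergence. The default `elim` algorithm
processes terms children before parents; when a term's p < 0.01 its genes
are removed from all ancestors before those are tested, which breaks the
parent–child correlation the DAG induces. `classic` tests every term
independently and equals `elim` whenever no term passes the threshold.
`elim` was chosen as the default topology-aware method because it is fully
specified in the literature and reproducible from its description.
Results are reported per namespace; significance is p < 0.01, strict.

## Synthetic data

The generator emulates the features the analysis relies on, with defaults
chosen once as a realistic desk-scale study:

- 10,000 ortholog triples × 9 tissues (the grass atlas tissue names).
- Ancestral log2 expression ~ Normal(5, 2) per gene and tissue.
- Independent per-lineage drift, Normal(0, √branch_length) per tissue;
  branch lengths (0.25, 0.25, 0.30) mirror the 50:50:60 My divergence
  ratio. Drift on the log scale makes squared profile distances grow
  ≈ linearly with branch length, though the branch decomposition itself
  is concave in the pairwise distances, so LED² ratios between lineages
  are compressed relative to branch-length ratios while the ordering is
  preserved.
- 1% of genes receive a +4 log2-unit (16-fold) shift in one tissue
  (default anther) on one lineage — a dramatic but realistic
  single-tissue gain, 8 per-tissue drift SDs at the default branch
  lengths, so planted genes are recoverable from the LED tail.
- Measurement noise Normal(0, 0.1) on log2 expression; TPM = 2^v − 1
  floored at zero.
- Correlate tables: Ka and branch-length means increase linearly in
  rank-normalized LED with mean-one lognormal noise; interaction counts
  are Poisson with log-mean 0.5 − 1.0 × rank-normalized LED.
- GO: a three-namespace, three-level DAG; one planted term annotating the
  20 top-LED genes, background terms annotating uniform random sets of
  10–40 genes.

All streams derive from one seed; identical configs give byte-identical
tables. What the generator does **not** emulate: read-level sampling
noise, library-size and quantile-normalization artifacts, correlated
tissues, expression-level-dependent noise, or selection. Passing tests
therefore demonstrate that the pipeline recovers the structure it assumes,
not that real grass data satisfy those assumptions.

## Numerical and design notes

- Tissue order is taken from the first loaded table and enforced (exact
  string equality) on the rest.
- Profile rows sum to 1 within 1e-9; all-zero genes are an error rather
  than a silent drop (they cannot pass the expression filter).
- Pipeline outputs are written with full round-trip float precision, and
  staged reruns parse them with round-trip precision, so stage-by-stage
  execution is byte-identical to a one-shot run.
- Problem sizes in the test suite (10⁵ algebra triples, 2,000 permutation
  replicates, 100 Poisson replicates, 10⁴-gene pipeline runs) are sized
  for quick desk verification while keeping Monte-Carlo error well inside
  the asserted bands.

## Known limitations

- Three-taxon trees cannot separate internal-branch changes from
  lineage-specific ones (see above).
- The deviance goodness-of-fit p is reported for any fit but is only
  meaningful away from the mean-count ≈ 1 regime.
- The KS enrichment treats gene scores as exchangeable under the null;
  correlated annotation blocks (beyond the DAG structure handled by
  `elim`) can inflate significance, as in any gene-set method of this
  family.
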