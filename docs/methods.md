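# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limitations of the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The enrichment model

The package implements the standard dual-method workflow for attributing
GWAS heritability to cell types of a clustered single-cell dataset.

### Stratified LD-score regression

For variant j with binary annotation memberships a(j, c), the additive
model gives

    E[chi2_j] = 1 + N * sum_c tau_c * l(j, c),
    l(j, c)   = sum_k r2(j, k) * a(k, c),

with tau_c the per-SNP heritability contribution of annotation c (units:
phenotypic variance per SNP). `ldsc.stratified_regression` fits this by
weighted least squares of chi2 on the N-scaled LD scores plus an
intercept:

- **Weights.** Default 1/max(l_baseline, 1), damping the redundancy of
  correlated variants. An optional second pass divides the weights by
  2·(fitted mean)², the variance of a chi-square with that mean; the
  cell-type scan enables this by default because without it the noise of
  high-signal variants (var ∝ E[chi2]²) dominates the fit and the power
  to rank an enriched annotation saturates.
- **Standard errors.** Delete-one-block jackknife over contiguous
  equal-count variant blocks (default 200, reduced to at most n/50 on
  small panels). Jackknife blocks must not subdivide LD blocks: adjacent
  sub-blocks would be correlated and the SE biased. Callers on synthetic
  panels align the jackknife count with the panel's block count.
- **Inference.** One-sided test of tau_c > 0. The ratio tau_hat/se is
  referred to a Student-t with (blocks − 1) degrees of freedom; with few
  blocks the normal tail is anti-conservative and the null scan fails
  Kolmogorov–Smirnov uniformity, with the t tail it is calibrated (the
  acceptance suite measures this over 1,000 simulated null scans).
- **Degeneracies.** LD-score columns that are numerically constant are
  absorbed by the intercept; their tau is reported NaN with an
  `absorbed` flag rather than fit. Collinear column pairs trigger a
  warned ridge fallback flagged in the result. Conditioning is assessed
  after rescaling columns to unit mean square, so the intercept/LD-score
  magnitude gap does not masquerade as collinearity.

The cell-type scan (`celltype_heritability_scan`) fits one conditional
model per cluster — intercept, baseline annotation(s), that cluster's
annotation — mirroring the one-at-a-time design of cell-type LDSC
pipelines and keeping collinearity manageable. Benjamini–Hochberg FDR is
applied within each declared dataset family; significance is q < 0.05.

### Specificity and gene sets

Expression in TPM is transformed to log2(1 + TPM). Specificity of gene g
for cluster c is the t-statistic of the binary in/out indicator in an
ordinary least-squares regression over samples, adjusted for donor age
and sex (covariates are attached per donor and expanded to samples). The
regression pools all samples; a `cluster_mean` aggregation mode exists
for datasets where only per-cluster profiles are available. Genes are
ranked per cluster by decreasing t, ties broken by gene identifier, and
the top-K genes per cluster (K = 1000 by default, the convention for a
~19k-gene genome) form the cluster's annotation gene set.

Perfectly fit genes (zero residual variance, e.g. constants) have an
undefined t ratio and are reported as t = 0. Clusters whose design is
rank-deficient (e.g. membership confounded with sex) are flagged in
`singular_clusters` with NaN statistics, not dropped silently.

### Gene-level statistics

- **Mapping** is positional on 1-based inclusive gene spans, optionally
  extended by asymmetric windows (default 0 kb, strict positional
  mapping); genes overlapping the MHC interval (chr6:25–34 Mb) and genes
  with non-unique identifiers are removed by default.
- **Gene association** is the mean chi2 of mapped variants. Under the
  null the chi2 sum is a quadratic form distributed as
  sum_i lambda_i chi2_1, with lambda_i the eigenvalues of the gene's LD
  submatrix. Its tail is evaluated by a four-moment (noncentral
  chi-square) match: a two-moment Satterthwaite match misses the
  Monte-Carlo tail by >30% at intermediate correlation, while the
  four-moment match stays within ~1% (the acceptance suite verifies
  ≤10% relative error at p ≈ 0.01 for r ∈ {0, 0.5, 0.9}). The match is
  exact for independent variants, so a single-variant gene reproduces
  the variant's two-sided p.
- **Gene-property scan**: OLS of the probit gene z on [intercept,
  specificity t, dataset-average expression], one-sided p for a positive
  specificity coefficient, BH-FDR across clusters. Continuous
  specificity is used (rather than binary top-K membership) because the
  test asks whether gene-level association increases linearly with
  cell-type-specific expression; fewer than 30 shared genes is an error.
- **Gene heritability**: the gene's Z vector is whitened through the
  eigen-decomposition of its LD submatrix (eigenvalues ≤ 1e-8 dropped,
  reducing the effective dimension); the whitened chi2 sum is chi-square
  with m_eff df under the null, and h2_gene = sum(chi2 − 1)/N. This is a
  deliberate simplification of gene-based variance estimators: negative
  raw estimates are truncated at zero and flagged.
- **Pre-ranked GSEA**: weighted Kolmogorov–Smirnov running sum
  (weight = |ranking statistic|, or reversed rank in the documented
  `rank` mode, which is invariant under monotone transforms of the
  statistic). The permutation null draws random same-size gene sets from
  the ranked universe — sample permutation is impossible from summary
  data — and p = (1 + extreme)/(B + 1). Ranking defaults to the
  heritability probit z.

### Downstream statistics

- **BH-FDR** is the Benjamini–Hochberg step-up (statsmodels backend)
  with strict validation of p ∈ (0, 1].
- **Over-representation** of significant clusters within
  neurotransmitter/region categories is the upper-tail hypergeometric
  P(X ≥ k) with N the cluster universe, K the category size, n the
  number of significant clusters. The universe defaults to all scored
  clusters, with an `annotated`-only mode, since the appropriate
  universe is a modelling choice. Only enrichment is tested; depletion
  is descriptive.
- **Region assignment** requires a strict majority: the unique region
  with fraction > 0.5, else none.
- **QQ slope lambda** is the least-squares slope through the origin of
  observed −log10 p order statistics on expected uniform plotting
  positions −log10(i/(n+1)); lambda = 1 for a calibrated set, and the
  statistic is exactly equivariant under p → p^c. The classic
  median-ratio genomic-control lambda is available as `mode="median"`;
  the slope definition is the default because only it reproduces the
  magnitude of slopes observed for strongly enriched gene sets.
- **Concordance** intersects the FDR-significant sets of the SNP-based
  and gene-based scans; the union identity |A∪B| = |A| + |B| − |A∩B| is
  asserted before reporting.

## The synthetic-data generator

`synthio` generates every input with known ground truth:

- **LD panel**: block-diagonal exchangeable correlation — blocks
  partition the variants, each pair within a block has correlation r
  (default 0.5), zero across blocks. This is a desk-scale stand-in that
  reproduces the l(j, c) structure the regressions need; real LD decay,
  allele-frequency spectra and genome coordinates are out of scope. A
  configurable number of variants is placed inside the MHC interval on
  chromosome 6 and a stated fraction is flagged multi-allelic so the
  harmonization filters are exercised.
- **GWAS summary statistics**: per block, Z ~ MVN(0, R + N·R·D·R) with
  D = diag(sum_c tau_c a(j, c)) — the exact finite-sample law of the
  additive model, so E[chi2] matches the regression's expectation by
  construction rather than asymptotically.
- **Expression**: built on the log2(1+TPM) scale — per-gene baseline
  (uniform 1–5), + log-fold change (default 2.0) for a cluster's markers
  in that cluster's cells, + donor age/sex effects, + unit-variance
  Gaussian noise — then inverted to TPM. Eight donors, balanced sexes,
  ages ~ N(50, 10); marker sets are disjoint across clusters (default
  2% of genes per cluster).
- **Study composition** (`simulate_study`): 20,000 variants in 200
  blocks, 2,000 genes, 24 clusters × 40 cells, GWAS N = 50,000; one
  enriched cluster whose marker-gene variants carry tau (default
  4e-5). The default tau follows a power calibration: it places the
  planted annotation's conditional z around 4.5–5.5 in the scan, above
  95% power for rank-first-and-concordant recovery. Fixture-scale runs
  use top-K = 100 (5% of genes, the proportion the top-1000 rule implies
  at genome scale) and 0 kb gene windows, because the miniature genome
  is only 20 Mb and genome-scale windows would blanket it.
- **Perturbation tables**: per cell type, a gene list at synthetic
  FDR below the 0.01 cut with a stated proportion drawn from the
  enriched cluster's markers, plus decoy genes above the cut so that
  filtering is exercised.

What passing tests on these fixtures do **not** show: robustness to LD
decay and long-range LD, allele frequency dependence of tagging,
population stratification, assay-specific expression noise (dropout,
batch), or annotation error in real atlases. The generator is a
correctness harness, not a realism benchmark.

## Numerical choices

- Tie-breaks in rankings are by gene identifier (deterministic across
  runs and platforms).
- p-values destined for probit transforms or BH are clipped to
  [1e-300, 1 − 1e-16] so downstream arithmetic stays finite.
- Cholesky factorizations add 1e-10 jitter; eigenvalues below 1e-8 are
  treated as null space in whitening.
- All generators are pure functions of their arguments including the
  seed (numpy `default_rng`); the pipeline derives stage seeds from the
  run seed, and reruns with identical config and seed are byte-identical
  (asserted in the test suite).
- Problem sizes in the test and acceptance suites (e.g. 5,000-variant
  panels for the 1,000-scan calibration, 50 seeds for recovery) were
  chosen as the smallest sizes at which each statistical property is
  cleanly measurable.

## Known limitations

- The baseline model on synthetic data is the all-ones annotation (plus
  optional controls); the 50+-annotation human baseline-LD model is out
  of scope, so real-data tau estimates would be confounded by
  unmodelled annotations.
- Gene heritability uses the sum-of-excess-chi2 estimator, not a REML or
  ridge-based gene variance model; it is labelled as such in outputs.
- No allele harmonization against a reference (strand flips, indels) —
  inputs are assumed pre-harmonized; multi-allelic variants are dropped,
  not resolved.
- Heritability is on the observed scale only.
- The hypergeometric universe and the GSEA ranking statistic are
  configurable because the right choices are context-dependent; defaults
  are documented above.
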