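# paincell

Cell-type-resolved genetic enrichment of GWAS signal: which cell types, in
a single-cell expression or chromatin-accessibility atlas, are enriched
for the heritability of a complex trait?

The package is aimed at statistical geneticists who have GWAS summary
statistics for a polygenic trait (for example chronic pain) and a
clustered single-cell dataset (for example a brain snRNA-Seq atlas or
dorsal-root-ganglion single-soma data), and want to run the standard
dual-method enrichment workflow end to end, with every statistical core
implemented, tested, and exercised against synthetic data with known
ground truth.

## The statistics at the core

**Expression specificity.** For each gene *g* and cluster *c*, the
specificity score is the t-statistic of the binary membership indicator
in the covariate-adjusted regression

> expr(g, s) = α + β·1[s ∈ c] + γ₁·age(s) + γ₂·sex(s) + ε

over samples *s* on the log₂(1+TPM) scale. Genes are ranked per cluster
by decreasing t; the top-K genes form that cluster's gene set.

**Stratified (partitioned) heritability.** Under the additive model,
each variant's association strength obeys

> E[χ²ⱼ] = 1 + N·Σ_c τ_c·ℓ(j, c),  ℓ(j, c) = Σ_k r²(j, k)·a(k, c)

where a(k, c) is annotation membership, ℓ(j, c) the stratified LD score,
N the GWAS sample size and τ_c the per-SNP heritability coefficient of
annotation c. Regressing χ² on the N-scaled LD scores (weighted least
squares, delete-one-block jackknife standard errors) yields τ̂_c with a
one-sided test for enrichment. The cell-type scan fits one conditional
model per cluster and applies Benjamini–Hochberg FDR within each dataset
family.

**Gene-level association and gene-property regression.** Variants are
mapped to genes positionally; a gene's statistic is the mean χ² of its
variants, with the null for the correlated sum evaluated by a four-moment
(noncentral chi-square) match on the LD submatrix eigenvalues. The
gene-property scan then regresses the probit gene z-score on the
cluster's specificity score, conditioning on dataset-average expression —
the gene-based counterpart of the SNP-based scan.

**Downstream statistics.** Dual-method concordance (a cluster counts only
if both scans pass FDR), hypergeometric over-representation of
significant clusters within neurotransmitter or region categories, the
strict >50% region-assignment rule, per-gene heritability from
decorrelated excess χ² with pre-ranked GSEA, and the QQ inflation slope λ
(origin-constrained slope of observed vs expected −log₁₀ p order
statistics) for perturbed gene sets.

## Worked example

The `analysis/` scripts run the whole workflow on a synthetic study with
known truth: 20,000 variants in 200 LD blocks, 2,000 genes, 24 clusters,
one of which ("C01") is enriched — the variants inside its 40 marker
genes carry per-SNP heritability τ = 4×10⁻⁵ at GWAS N = 50,000.

```sh
python analysis/01_simulate.py --seed 0          # writes results/fixture/
python analysis/02_celltype_scan.py --seed 0     # writes results/run/
python analysis/03_gene_prioritization.py --seed 0
python analysis/04_perturbed_sets.py --seed 0
```

From `02_celltype_scan.py` at seed 0, the SNP-based scan puts the planted
cluster first and flags it alone:

```
cluster      tau_hat        se       p_one_sided     q_fdr   significant
C01          1.66e-05   3.02e-06     5.38e-08        1.29e-06   True
C02         -3.74e-06   2.34e-06     0.94            1.00       False
...
concordant (significant under both methods): ['C01']
```

τ̂ for C01 is the planted 4×10⁻⁵ diluted by the top-100 annotation (the
annotation holds ~1,000 variants of which ~400 carry signal), so a
coefficient near 1.7×10⁻⁵ is the expected recovery, 5.5 standard errors
above zero. The concordance line is the dual-method criterion: C01 passes
FDR in both the SNP-based and the gene-based scan.

`04_perturbed_sets.py` reports the QQ slope of perturbed gene sets drawn
from the enriched cluster's markers:

```
cell_type     n_genes  lambda  evaluable
neuronal           30    9.23       True
non_neuronal       30    9.41       True
```

λ ≈ 9 against λ = 1 for a null set: the perturbed genes are strongly
enriched for small gene-level association p-values, as planted.

A `paincell` command-line interface mirrors the scripts
(`paincell simulate|specificity|ldsc|magma|genes|enrich|run|report`);
`paincell run --config cfg.yaml` executes the full pipeline from a YAML
config and writes per-stage TSVs plus a JSON run report.

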