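"""Synthetic data generators with known ground truth.

Everything downstream of this module (specificity scoring, stratified
LD-score regression, gene-level statistics, enrichment summaries) is
exercised on data produced here: an LD reference panel with block-diagonal
exchangeable correlation, GWAS summary statistics simulated under the
additive partitioned-heritability model

    E[chi2_j] = 1 + N * sum_c tau_c * l(j, c),

clustered single-cell expression with planted marker genes and donor
age/sex covariates, cluster metadata (neurotransmitter class, region
composition), and perturbed (DEG/DAR-style) gene tables.

Every generator is a pure function of its arguments including ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "LdPanel",
    "SimulationTruth",
    "simulate_ld_panel",
    "simulate_gwas_sumstats",
    "simulate_expression",
    "simulate_gene_coordinates",
    "simulate_cluster_metadata",
    "simulate_perturbation_sets",
    "write_fixture_bundle",
]

# chr6:25-34 Mb, the interval conventionally excluded for its extended LD
MHC_CHROM = 6
MHC_START = 25_000_000
MHC_END = 34_000_000


@dataclass
class LdPanel:
    """Reference panel with block-diagonal exchangeable LD.

    ``variants`` has columns SNP, CHR, BP, A1, A2, is_multiallelic,
    block_id. Within each block every pair of variants has allelic
    correlation ``within_block_correlation``; across blocks correlation is
    zero. Correlation matrices are materialised on demand.
    """

    variants: pd.DataFrame
    within_block_correlation: float

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def block_ids(self) -> np.ndarray:
        return np.unique(self.variants["block_id"].to_numpy())

    def block_index(self, block_id: int) -> np.ndarray:
        """Positional indices of the block's variants."""
        return np.flatnonzero(self.variants["block_id"].to_numpy() == block_id)

    def block_correlation(self, block_id: int) -> np.ndarray:
        m = len(self.block_index(block_id))
        return self.correlation_for_size(m)

    def correlation_for_size(self, m: int) -> np.ndarray:
        r = self.within_block_correlation
        return (1.0 - r) * np.eye(m) + r * np.ones((m, m))

    def correlation_submatrix(self, idx: np.ndarray) -> np.ndarray:
        """Correlation among an arbitrary subset of variants (block-diagonal)."""
        blocks = self.variants["block_id"].to_numpy()[idx]
        same = blocks[:, None] == blocks[None, :]
        r = self.within_block_correlation
        out = np.where(same, r, 0.0)
        np.fill_diagonal(out, 1.0)
        return out


@dataclass
class SimulationTruth:
    """Ground truth planted by the generators."""

    tau_true: dict[str, float] = field(default_factory=dict)
    enriched_cluster_ids: list[str] = field(default_factory=list)
    marker_genes: dict[str, list[str]] = field(default_factory=dict)
    de_genes: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        for name, tau in self.tau_true.items():
            if tau < 0:
                raise ValueError(f"tau must be >= 0 for annotation {name!r}")
        for cl in self.enriched_cluster_ids:
            if not self.marker_genes.get(cl):
                raise ValueError(f"enriched cluster {cl!r} has no marker genes")

    def to_json(self) -> str:
        return json.dumps(
            {
                "tau_true": self.tau_true,
                "enriched_cluster_ids": list(self.enriched_cluster_ids),
                "marker_genes": {k: list(v) for k, v in self.marker_genes.items()},
                "de_genes": {k: list(v) for k, v in self.de_genes.items()},
                "seed": self.seed,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        d = json.loads(text)
        return cls(
            tau_true=d["tau_true"],
            enriched_cluster_ids=d["enriched_cluster_ids"],
            marker_genes=d["marker_genes"],
            de_genes=d["de_genes"],
            seed=d["seed"],
        )


def simulate_ld_panel(
    n_variants: int,
    n_blocks: int,
    within_block_correlation: float = 0.5,
    multiallelic_fraction: float = 0.0,
    n_mhc_variants: int = 0,
    seed: int = 0,
    bp_spacing: int = 1_000,
) -> LdPanel:
    """Generate a block-exchangeable LD panel.

    Variants are laid out on chromosome 1 at ``bp_spacing`` intervals,
    partitioned into ``n_blocks`` contiguous blocks of near-equal size.
    ``n_mhc_variants`` of them (the last ones) are instead placed inside
    the MHC interval on chromosome 6 so that the MHC filter has something
    to remove. ``round(multiallelic_fraction * n_variants)`` variants are
    flagged multi-allelic.
    """
    if n_variants <= 0 or n_blocks <= 0:
        raise ValueError("n_variants and n_blocks must be positive")
    if n_variants < n_blocks:
        raise ValueError("need n_variants >= n_blocks")
    if not 0.0 <= within_block_correlation < 1.0:
        raise ValueError("within_block_correlation must be in [0, 1)")
    if not 0.0 <= multiallelic_fraction <= 1.0:
        raise ValueError("multiallelic_fraction must be in [0, 1]")
    if n_mhc_variants >= n_variants:
        raise ValueError("n_mhc_variants must be < n_variants")

    rng = np.random.default_rng(seed)
    n_main = n_variants - n_mhc_variants
    chrom = np.concatenate(
        [np.ones(n_main, dtype=int), np.full(n_mhc_variants, MHC_CHROM)]
    )
    bp = np.concatenate(
        [
            np.arange(1, n_main + 1) * bp_spacing,
            MHC_START + np.arange(1, n_mhc_variants + 1) * bp_spacing,
        ]
    )
    block_id = (np.arange(n_variants) * n_blocks) // n_variants

    bases = np.array(list("ACGT"))
    a1 = rng.choice(bases, size=n_variants)
    a2 = np.array([rng.choice([b for b in "ACGT" if b != x]) for x in a1])

    n_multi = int(round(multiallelic_fraction * n_variants))
    multi = np.zeros(n_variants, dtype=bool)
    multi[rng.choice(n_variants, size=n_multi, replace=False)] = True

    variants = pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(n_variants)],
            "CHR": chrom,
            "BP": bp,
            "A1": a1,
            "A2": a2,
            "is_multiallelic": multi,
            "block_id": block_id,
        }
    )
    return LdPanel(variants=variants, within_block_correlation=within_block_correlation)


def simulate_gwas_sumstats(
    panel: LdPanel,
    annotations: pd.DataFrame,
    tau_true: dict[str, float],
    n_samples: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate marginal GWAS Z-scores under the partitioned model.

    Per LD block the marginal Z-vector is drawn from the exact
    finite-sample law of the additive model,

        Z ~ MVN(0, R + N * R D R),   D = diag(sum_c tau_c * a(j, c)),

    so that E[chi2_j] = 1 + N * sum_c tau_c * l(j, c) with
    l(j, c) = sum_k r2(j, k) a(k, c).

    ``annotations`` is a variant-by-annotation 0/1 frame aligned to
    ``panel.variants`` (same row order and length); ``tau_true`` maps its
    column names to nonnegative per-SNP variance coefficients.
    """
    if len(annotations) != panel.n_variants:
        raise ValueError("annotation rows are not aligned to the panel variants")
    if n_samples <= 0:
        raise ValueError("sample size must be positive")
    for name, tau in tau_true.items():
        if tau < 0:
            raise ValueError(f"tau must be >= 0 (annotation {name!r})")
        if name not in annotations.columns:
            raise ValueError(f"tau refers to unknown annotation {name!r}")

    rng = np.random.default_rng(seed)
    per_snp_var = np.zeros(panel.n_variants)
    for name, tau in tau_true.items():
        per_snp_var += tau * annotations[name].to_numpy(dtype=float)

    z = np.empty(panel.n_variants)
    for b in panel.block_ids:
        idx = panel.block_index(b)
        R = panel.correlation_for_size(len(idx))
        D = np.diag(per_snp_var[idx])
        cov = R + n_samples * (R @ D @ R)
        # jitter keeps the Cholesky stable when r is close to its bounds
        L = np.linalg.cholesky(cov + 1e-10 * np.eye(len(idx)))
        z[idx] = L @ rng.standard_normal(len(idx))

    from scipy import stats

    out = panel.variants[["SNP", "CHR", "BP", "A1", "A2", "is_multiallelic"]].copy()
    out["N"] = n_samples
    out["Z"] = z
    out["P"] = 2.0 * stats.norm.sf(np.abs(z))
    return out


def simulate_expression(
    n_genes: int,
    clusters: list[str],
    cells_per_cluster: int = 40,
    marker_fraction: float = 0.02,
    log_fold_change: float = 2.0,
    covariate_effects: tuple[float, float] = (0.0, 0.0),
    n_donors: int = 8,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ad.AnnData, pd.DataFrame, SimulationTruth]:
    """Clustered single-cell expression with planted markers.

    Expression is built on the log2(1 + TPM) scale — baseline gene level
    plus ``log_fold_change`` for a cluster's markers in that cluster's
    cells, plus donor age/sex effects (``covariate_effects`` =
    (age_coefficient per standardised year, sex_coefficient)), plus
    Gaussian noise — then inverted to the TPM scale, which is what the
    returned AnnData carries (``uns['expression_scale'] == 'tpm'``).

    Marker sets are disjoint across clusters, each of size
    ``round(marker_fraction * n_genes)``.

    Returns ``(adata, donor_covariates, truth)`` where ``adata`` is cells
    x genes with ``obs['cluster']`` and ``obs['donor']``.
    """
    if len(set(clusters)) != len(clusters):
        raise ValueError("duplicate cluster labels")
    n_markers = int(round(marker_fraction * n_genes))
    if n_markers < 1:
        raise ValueError("marker_fraction * n_genes must be >= 1")
    if n_markers * len(clusters) > n_genes:
        raise ValueError("marker sets would exceed the gene universe")

    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    gene_order = rng.permutation(n_genes)
    marker_genes = {
        cl: sorted(genes[g] for g in gene_order[i * n_markers : (i + 1) * n_markers])
        for i, cl in enumerate(clusters)
    }

    donors = [f"D{i + 1}" for i in range(n_donors)]
    age = rng.normal(50.0, 10.0, size=n_donors)
    sex = (np.arange(n_donors) % 2).astype(int)
    covariates = pd.DataFrame({"donor": donors, "age": age, "sex": sex})

    n_cells = cells_per_cluster * len(clusters)
    cluster_of_cell = np.repeat(clusters, cells_per_cluster)
    donor_of_cell = np.array([donors[i % n_donors] for i in range(n_cells)])
    donor_idx = np.array([donors.index(d) for d in donor_of_cell])

    baseline = rng.uniform(1.0, 5.0, size=n_genes)
    log_expr = np.tile(baseline, (n_cells, 1))
    for i, cl in enumerate(clusters):
        cells = cluster_of_cell == cl
        cols = gene_order[i * n_markers : (i + 1) * n_markers]
        log_expr[np.ix_(cells, cols)] += log_fold_change

    age_coef, sex_coef = covariate_effects
    age_std = (age - age.mean()) / age.std() if n_donors > 1 else age * 0.0
    log_expr += (age_coef * age_std[donor_idx] + sex_coef * sex[donor_idx])[:, None]
    log_expr += rng.normal(0.0, noise_sd, size=log_expr.shape)

    tpm = np.maximum(np.exp2(log_expr) - 1.0, 0.0)
    adata = ad.AnnData(
        X=tpm,
        obs=pd.DataFrame(
            {"cluster": pd.Categorical(cluster_of_cell), "donor": donor_of_cell},
            index=[f"cell{i + 1}" for i in range(n_cells)],
        ),
        var=pd.DataFrame(index=genes),
        uns={"expression_scale": "tpm"},
    )
    truth = SimulationTruth(marker_genes=marker_genes, seed=seed)
    return adata, covariates, truth


def simulate_gene_coordinates(
    panel: LdPanel,
    gene_ids: list[str],
    seed: int = 0,
) -> pd.DataFrame:
    """Tile genes over the panel's variant positions.

    Non-MHC variants are split into ``len(gene_ids)`` contiguous runs and
    each gene's span covers one run (1-based inclusive), so every gene
    maps to at least one variant under strict positional mapping. Gene
    order along the chromosome is a seeded permutation of ``gene_ids`` so
    genomic adjacency is unrelated to gene identity.
    """
    rng = np.random.default_rng(seed)
    main = panel.variants[panel.variants["CHR"] != MHC_CHROM]
    bp = main["BP"].to_numpy()
    n_genes = len(gene_ids)
    if n_genes > len(bp):
        raise ValueError("more genes than non-MHC variants to tile over")
    order = rng.permutation(n_genes)
    bounds = (np.arange(n_genes + 1) * len(bp)) // n_genes
    rows = []
    for slot, gi in enumerate(order):
        lo, hi = bounds[slot], bounds[slot + 1]
        rows.append(
            {
                "gene": gene_ids[gi],
                "chrom": int(main["CHR"].iloc[0]),
                "start": int(bp[lo]),
                "end": int(bp[hi - 1]),
            }
        )
    return pd.DataFrame(rows).sort_values("gene", ignore_index=True)


def simulate_cluster_metadata(
    clusters: list[str],
    neurotransmitter_classes: list[str],
    region_labels: list[str],
    dominant_fraction: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign each cluster a neurotransmitter class and a region mix.

    Each cluster gets one neurotransmitter class and a per-region cell
    fraction vector summing to 1 whose largest entry equals
    ``dominant_fraction`` (the remainder spread uniformly over the other
    regions). Columns: cluster, neurotransmitter, frac_<region>...
    """
    if not clusters or not neurotransmitter_classes or not region_labels:
        raise ValueError("label sets must be nonempty")
    if not 0.0 < dominant_fraction <= 1.0:
        raise ValueError("dominant_fraction must be in (0, 1]")

    rng = np.random.default_rng(seed)
    nts = rng.choice(neurotransmitter_classes, size=len(clusters))
    dominant = rng.choice(len(region_labels), size=len(clusters))
    rows = []
    rest = (
        (1.0 - dominant_fraction) / (len(region_labels) - 1)
        if len(region_labels) > 1
        else 0.0
    )
    for cl, nt, dom in zip(clusters, nts, dominant):
        fracs = np.full(len(region_labels), rest)
        fracs[dom] = dominant_fraction if len(region_labels) > 1 else 1.0
        row = {"cluster": cl, "neurotransmitter": nt}
        row.update({f"frac_{r}": f for r, f in zip(region_labels, fracs)})
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_perturbation_sets(
    truth: SimulationTruth,
    cell_types: list[str],
    overlap_with_enriched: float,
    set_size: int,
    gene_universe: list[str],
    n_decoys: int = 20,
    fdr_column: float = 0.001,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """DEG/DAR-style tables per cell type with a known enriched overlap.

    For each cell type, ``set_size`` genes are listed at a synthetic FDR of
    ``fdr_column`` (below the conventional 0.01 cut); a stated proportion
    ``overlap_with_enriched`` of them is drawn from the marker genes of the
    enriched clusters in ``truth`` and the rest from the other genes.
    ``n_decoys`` additional genes per cell type are listed with FDR above
    the cut so that filtering is actually exercised. Updates and returns
    ``truth`` with the selected (sub-cut) gene lists in ``de_genes``.
    """
    if not 0.0 <= overlap_with_enriched <= 1.0:
        raise ValueError("overlap_with_enriched must be in [0, 1]")
    if set_size <= 0:
        raise ValueError("set_size must be positive")
    if set_size > len(gene_universe):
        raise ValueError("set_size exceeds the gene universe")

    rng = np.random.default_rng(seed)
    enriched_pool = sorted(
        {
            g
            for cl in truth.enriched_cluster_ids
            for g in truth.marker_genes.get(cl, [])
        }
    )
    other_pool = sorted(set(gene_universe) - set(enriched_pool))

    n_enriched = int(round(overlap_with_enriched * set_size))
    if n_enriched > len(enriched_pool):
        raise ValueError("not enough enriched-annotation genes for requested overlap")

    rows = []
    de_genes: dict[str, list[str]] = {}
    for ct in cell_types:
        chosen = list(rng.choice(enriched_pool, size=n_enriched, replace=False)) if n_enriched else []
        chosen += list(
            rng.choice(other_pool, size=set_size - n_enriched, replace=False)
        )
        de_genes[ct] = sorted(chosen)
        for g in chosen:
            rows.append(
                {
                    "gene": g,
                    "cell_type": ct,
                    "log_fold_change": float(rng.normal(0.0, 1.0)),
                    "fdr": fdr_column,
                }
            )
        decoy_pool = sorted(set(other_pool) - set(chosen))
        for g in rng.choice(decoy_pool, size=min(n_decoys, len(decoy_pool)), replace=False):
            rows.append(
                {
                    "gene": g,
                    "cell_type": ct,
                    "log_fold_change": float(rng.normal(0.0, 1.0)),
                    "fdr": float(rng.uniform(0.05, 0.9)),
                }
            )
    truth.de_genes = de_genes
    return pd.DataFrame(rows), truth


def simulate_study(
    n_variants: int = 20_000,
    n_blocks: int = 200,
    n_genes: int = 2_000,
    n_clusters: int = 24,
    cells_per_cluster: int = 40,
    marker_fraction: float = 0.02,
    log_fold_change: float = 2.0,
    within_block_correlation: float = 0.5,
    multiallelic_fraction: float = 0.01,
    n_mhc_variants: int = 200,
    tau: float = 4e-5,
    gwas_n: int = 50_000,
    deg_overlap: float = 1.0,
    deg_set_size: int | None = None,
    seed: int = 0,
) -> dict:
    """Generate a complete, internally consistent synthetic study.

    One cluster (the first) is enriched: the variants inside its marker
    genes carry per-SNP heritability ``tau``; all other variants are null.
    The default scale (20,000 variants in 200 LD blocks, 2,000 genes,
    24 clusters, 8 donors, GWAS N = 50,000) keeps a full analysis in the
    minutes range while leaving the planted signal comfortably detectable
    (see the package methods note for the power calibration of ``tau``).

    Returns a dict with panel, sumstats, adata, covariates, gene_coords,
    cluster_metadata, perturbation, truth, clusters, and the planted
    annotation matrix.
    """
    from .ldsc import build_snp_annotations

    root = np.random.default_rng(seed)
    sub = root.integers(0, 2**31 - 1, size=6)

    clusters = [f"C{i + 1:02d}" for i in range(n_clusters)]
    enriched = clusters[0]
    adata, covariates, truth = simulate_expression(
        n_genes,
        clusters,
        cells_per_cluster=cells_per_cluster,
        marker_fraction=marker_fraction,
        log_fold_change=log_fold_change,
        seed=int(sub[0]),
    )
    panel = simulate_ld_panel(
        n_variants,
        n_blocks,
        within_block_correlation=within_block_correlation,
        multiallelic_fraction=multiallelic_fraction,
        n_mhc_variants=n_mhc_variants,
        seed=int(sub[1]),
    )
    gene_coords = simulate_gene_coordinates(panel, list(adata.var_names), seed=int(sub[2]))
    planted = build_snp_annotations(
        panel.variants,
        gene_sets={"planted": truth.marker_genes[enriched]},
        gene_coords=gene_coords,
        window_kb=0.0,
        add_baseline=False,
    )
    truth.tau_true = {"planted": tau}
    truth.enriched_cluster_ids = [enriched]
    truth.seed = seed
    truth.validate()
    sumstats = simulate_gwas_sumstats(
        panel, planted, truth.tau_true, n_samples=gwas_n, seed=int(sub[3])
    )
    cluster_metadata = simulate_cluster_metadata(
        clusters,
        ["GABAergic", "glutamatergic"],
        ["PFC", "AMY", "HIP", "THA"],
        dominant_fraction=0.8,
        seed=int(sub[4]),
    )
    if deg_set_size is None:
        deg_set_size = min(30, len(truth.marker_genes[enriched]))
    perturbation, truth = simulate_perturbation_sets(
        truth,
        ["neuronal", "non_neuronal"],
        overlap_with_enriched=deg_overlap,
        set_size=deg_set_size,
        gene_universe=list(adata.var_names),
        seed=int(sub[5]),
    )
    return {
        "panel": panel,
        "sumstats": sumstats,
        "adata": adata,
        "covariates": covariates,
        "gene_coords": gene_coords,
        "cluster_metadata": cluster_metadata,
        "perturbation": perturbation,
        "truth": truth,
        "clusters": clusters,
        "planted_annotation": planted,
    }


def write_fixture_bundle(
    outdir: str | Path,
    *,
    panel: LdPanel,
    sumstats: pd.DataFrame,
    adata: ad.AnnData,
    covariates: pd.DataFrame,
    gene_coords: pd.DataFrame,
    cluster_metadata: pd.DataFrame,
    perturbation_table: pd.DataFrame,
    truth: SimulationTruth,
    gene_sets: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Write the full fixture bundle in the pipeline's file formats.

    Produces sumstats TSV, panel TSV, dense expression TSV + cell metadata
    TSV, covariate TSV, gene-coordinate TSV, cluster-metadata TSV, DEG TSV,
    optional GMT, and truth JSON. Returns a manifest frame (file, rows).
    """
    from . import io as pio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []

    def _written(name: str, n_rows: int) -> None:
        manifest.append({"file": name, "rows": n_rows})

    pio.write_sumstats(sumstats, out / "sumstats.tsv")
    _written("sumstats.tsv", len(sumstats))

    panel_tab = panel.variants.copy()
    panel_tab["within_block_correlation"] = panel.within_block_correlation
    panel_tab.to_csv(out / "ld_panel.tsv", sep="\t", index=False)
    _written("ld_panel.tsv", len(panel_tab))

    expr = pd.DataFrame(adata.X.T, index=adata.var_names, columns=adata.obs_names)
    expr.to_csv(out / "expression.tsv", sep="\t", index_label="gene")
    _written("expression.tsv", expr.shape[0])
    cells = adata.obs.reset_index(names="cell")
    cells.to_csv(out / "cells.tsv", sep="\t", index=False)
    _written("cells.tsv", len(cells))

    covariates.to_csv(out / "covariates.tsv", sep="\t", index=False)
    _written("covariates.tsv", len(covariates))
    gene_coords.to_csv(out / "gene_coords.tsv", sep="\t", index=False)
    _written("gene_coords.tsv", len(gene_coords))
    cluster_metadata.to_csv(out / "cluster_metadata.tsv", sep="\t", index=False)
    _written("cluster_metadata.tsv", len(cluster_metadata))
    perturbation_table.to_csv(out / "perturbation.tsv", sep="\t", index=False)
    _written("perturbation.tsv", len(perturbation_table))

    if gene_sets:
        pio.write_gmt(gene_sets, out / "gene_sets.gmt")
        _written("gene_sets.gmt", len(gene_sets))

    (out / "truth.json").write_text(truth.to_json())
    _written("truth.json", 1)

    mdf = pd.DataFrame(manifest)
    mdf.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return mdf
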