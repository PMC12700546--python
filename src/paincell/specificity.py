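"""Cell-type expression specificity.

Expression in TPM is moved to the log2(1 + TPM) scale, then each gene is
regressed, per cluster, on a binary cluster-membership indicator with
donor age and sex as covariates. The indicator's t-statistic is the
specificity score; genes are ranked within each cluster by decreasing t
and the top-K genes per cluster form the gene sets fed to the
partitioned-heritability scan.

The regression unit is the individual sample (cell or pseudobulk column):
the in/out indicator only varies across samples. A ``cluster_mean`` mode
aggregates to one column per cluster first, for datasets where only
cluster-level profiles are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "SpecificityMatrix",
    "transform_and_aggregate",
    "specificity_regression",
    "top_k_gene_sets",
    "average_expression",
]


@dataclass
class SpecificityMatrix:
    """Per-gene per-cluster specificity from the indicator regression.

    ``t`` and ``beta`` are genes x clusters frames; ``singular_clusters``
    lists clusters whose design was rank-deficient (their t column is NaN,
    reported rather than silently dropped).
    """

    beta: pd.DataFrame
    t: pd.DataFrame
    singular_clusters: list[str] = field(default_factory=list)

    @property
    def clusters(self) -> list[str]:
        return list(self.t.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.t.index)

    def ranked_genes(self, cluster: str) -> list[str]:
        """Genes by decreasing t; ties and NaNs broken by gene identifier."""
        col = self.t[cluster]
        order = sorted(col.index, key=lambda g: (-col[g] if np.isfinite(col[g]) else np.inf, g))
        return order

    def rank_table(self) -> pd.DataFrame:
        """Long table (gene, cluster, beta, t, rank_in_cluster)."""
        rows = []
        for cl in self.clusters:
            for rank, g in enumerate(self.ranked_genes(cl), start=1):
                rows.append(
                    {
                        "gene": g,
                        "cluster": cl,
                        "beta": self.beta.at[g, cl],
                        "t": self.t.at[g, cl],
                        "rank_in_cluster": rank,
                    }
                )
        return pd.DataFrame(rows)


def transform_and_aggregate(adata: ad.AnnData, mode: str = "per_sample") -> ad.AnnData:
    """log2(1 + TPM) transform, optionally aggregating to cluster means.

    ``mode='per_sample'`` keeps one column per cell; ``mode='cluster_mean'``
    returns one pseudo-sample per cluster holding the mean of the
    transformed values. The scale tag in ``uns['expression_scale']`` moves
    from ``'tpm'`` to ``'log2_1p_tpm'``; transforming twice is an error.
    """
    scale = adata.uns.get("expression_scale", "tpm")
    if scale != "tpm":
        raise ValueError(f"expected TPM-scale input, got scale tag {scale!r}")
    X = np.asarray(adata.X, dtype=float)
    if np.any(X < 0) or not np.all(np.isfinite(X)):
        raise ValueError("TPM values must be finite and nonnegative")
    if mode not in ("per_sample", "cluster_mean"):
        raise ValueError(f"unknown mode {mode!r}")

    logX = np.log2(1.0 + X)
    if mode == "per_sample":
        out = ad.AnnData(
            X=logX,
            obs=adata.obs.copy(),
            var=adata.var.copy(),
            uns={**adata.uns, "expression_scale": "log2_1p_tpm"},
        )
        return out

    clusters = adata.obs["cluster"].astype(str)
    labels = list(dict.fromkeys(clusters))
    means = np.vstack([logX[(clusters == cl).to_numpy()].mean(axis=0) for cl in labels])
    return ad.AnnData(
        X=means,
        obs=pd.DataFrame({"cluster": pd.Categorical(labels)}, index=labels),
        var=adata.var.copy(),
        uns={**adata.uns, "expression_scale": "log2_1p_tpm"},
    )


def _design_for_cluster(
    adata: ad.AnnData, cluster: str, covariates: pd.DataFrame | None
) -> np.ndarray:
    n = adata.n_obs
    ind = (adata.obs["cluster"].astype(str) == cluster).to_numpy(dtype=float)
    cols = [np.ones(n), ind]
    if covariates is not None:
        cov = covariates.set_index("donor")
        donors = adata.obs["donor"].astype(str)
        missing = sorted(set(donors) - set(cov.index.astype(str)))
        if missing:
            raise ValueError(f"no covariates for donors {missing}")
        cols.append(cov.loc[donors, "age"].to_numpy(dtype=float))
        cols.append(cov.loc[donors, "sex"].to_numpy(dtype=float))
    return np.column_stack(cols)


def specificity_regression(
    adata: ad.AnnData, covariates: pd.DataFrame | None = None
) -> SpecificityMatrix:
    """OLS of each gene's log expression on a cluster indicator + covariates.

    For every (gene, cluster) pair: regress expression on
    [intercept, 1(sample in cluster), age, sex] pooled over all samples,
    and keep the indicator's coefficient and t-statistic. Clusters whose
    design matrix is singular (e.g. membership confounded with sex) are
    flagged and reported with NaN statistics.
    """
    if adata.uns.get("expression_scale") != "log2_1p_tpm":
        raise ValueError("specificity_regression expects log2(1+TPM)-scale input")
    clusters = list(dict.fromkeys(adata.obs["cluster"].astype(str)))
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    counts = adata.obs["cluster"].astype(str).value_counts()
    small = sorted(counts.index[counts < 2])
    if small:
        raise ValueError(f"clusters with fewer than 2 samples: {small}")

    Y = np.asarray(adata.X, dtype=float)  # samples x genes
    genes = list(adata.var_names)
    n, g = Y.shape
    beta = pd.DataFrame(index=genes, columns=clusters, dtype=float)
    tstat = pd.DataFrame(index=genes, columns=clusters, dtype=float)
    singular: list[str] = []

    for cl in clusters:
        X = _design_for_cluster(adata, cl, covariates)
        p = X.shape[1]
        xtx = X.T @ X
        if np.linalg.matrix_rank(xtx) < p:
            singular.append(cl)
            beta[cl] = np.nan
            tstat[cl] = np.nan
            continue
        xtx_inv = np.linalg.inv(xtx)
        coefs = xtx_inv @ (X.T @ Y)  # p x genes
        resid = Y - X @ coefs
        dof = n - p
        sigma2 = (resid**2).sum(axis=0) / dof
        # a perfectly fit (e.g. constant) gene has no residual variance and
        # an undefined ratio; report t = 0 rather than 0/0 noise
        degenerate = sigma2 <= 1e-20 * np.maximum((Y**2).mean(axis=0), 1.0)
        se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(~degenerate & (se > 0), coefs[1] / np.where(se > 0, se, 1.0), 0.0)
        beta[cl] = coefs[1]
        tstat[cl] = t

    return SpecificityMatrix(beta=beta, t=tstat, singular_clusters=singular)


def top_k_gene_sets(spec: SpecificityMatrix, k: int = 1000) -> dict[str, list[str]]:
    """Per cluster, the k genes with the largest specificity t.

    Ties (and NaN columns) break deterministically by gene identifier. If
    fewer than k genes are ranked, the set is truncated to all of them.
    """
    if spec.t.empty:
        raise ValueError("empty specificity matrix")
    if k < 1:
        raise ValueError("k must be >= 1")
    return {cl: spec.ranked_genes(cl)[: min(k, len(spec.genes))] for cl in spec.clusters}


def average_expression(adata: ad.AnnData) -> pd.Series:
    """Dataset-average expression per gene, on the matrix's current scale."""
    return pd.Series(
        np.asarray(adata.X, dtype=float).mean(axis=0), index=adata.var_names, name="avg_expr"
    )
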