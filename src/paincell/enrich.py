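"""Downstream enrichment statistics.

Benjamini-Hochberg FDR, hypergeometric over-representation of significant
cell types within neurotransmitter/region categories, the strict >50%
region-assignment rule, the dual-method (SNP-based x gene-based)
concordance intersection, and the QQ-slope statistic lambda for perturbed
gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_fdr",
    "hypergeom_overrep",
    "assign_region",
    "concordance_intersect",
    "qq_lambda",
    "perturbed_set_enrichment",
    "QqResult",
    "ConcordanceResult",
]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_overrep(
    significant: set[str],
    categories: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of each category in the significant set.

    With universe size N, category size K, n = |significant| draws and
    k = |significant ∩ category| observed, p = P(X >= k) for
    X ~ Hypergeometric(N, K, n). BH-FDR is applied across categories.
    """
    universe = set(universe)
    significant = set(significant)
    if not significant <= universe:
        raise ValueError("significant labels outside the universe")
    if len(significant) == 0:
        warnings.warn("empty significant set: all k = 0, p = 1")
    rows = []
    for name, members in categories.items():
        members = set(members)
        if not members <= universe:
            raise ValueError(f"category {name!r} has labels outside the universe")
        N, K, n = len(universe), len(members), len(significant)
        k = len(significant & members)
        p_upper = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"category": name, "N": N, "K": K, "n": n, "k": k, "p_upper": min(p_upper, 1.0)}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_fdr"] = bh_fdr(out["p_upper"].to_numpy())
    return out


def assign_region(fractions: dict[str, float], tol: float = 1e-9) -> str | None:
    """Region holding strictly more than half the cluster's cells, else None."""
    total = float(sum(fractions.values()))
    if abs(total - 1.0) > max(tol, 1e-6):
        raise ValueError(f"region fractions sum to {total}, not 1")
    for region, frac in fractions.items():
        if frac > 0.5:
            return region
    return None


@dataclass
class ConcordanceResult:
    """Intersection of two methods' significant cell-type sets."""

    significant_a: set[str]
    significant_b: set[str]
    flags: pd.DataFrame  # cluster, significant_a, significant_b, concordant

    @property
    def concordant(self) -> set[str]:
        return self.significant_a & self.significant_b

    @property
    def union(self) -> set[str]:
        return self.significant_a | self.significant_b

    def sizes(self) -> dict[str, int]:
        return {
            "n_a": len(self.significant_a),
            "n_b": len(self.significant_b),
            "n_concordant": len(self.concordant),
            "n_union": len(self.union),
        }


def concordance_intersect(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    alpha: float = 0.05,
    label_a: str = "cluster",
    label_b: str = "cluster",
    q_a: str = "q_fdr",
    q_b: str = "q_fdr",
) -> ConcordanceResult:
    """Clusters significant (q < alpha) under both methods.

    The two result tables must cover the same cluster label space; label
    mismatches are reported by name rather than silently dropped.
    """
    a_labels = set(results_a[label_a])
    b_labels = set(results_b[label_b])
    if a_labels != b_labels:
        offenders = sorted(a_labels ^ b_labels)
        raise ValueError(f"cluster label mismatch between methods: {offenders}")
    sig_a = set(results_a.loc[results_a[q_a] < alpha, label_a])
    sig_b = set(results_b.loc[results_b[q_b] < alpha, label_b])
    flags = pd.DataFrame(
        {
            "cluster": sorted(a_labels),
            "significant_a": [c in sig_a for c in sorted(a_labels)],
            "significant_b": [c in sig_b for c in sorted(a_labels)],
        }
    )
    flags["concordant"] = flags["significant_a"] & flags["significant_b"]
    return ConcordanceResult(significant_a=sig_a, significant_b=sig_b, flags=flags)


@dataclass
class QqResult:
    """QQ-slope record for a gene set's p-values."""

    label: str
    n_genes: int
    lam: float
    resid_sd: float


def qq_lambda(
    pvalues,
    min_set_size: int = 10,
    label: str = "",
    mode: str = "slope",
) -> QqResult:
    """QQ inflation slope of observed vs expected -log10 p order statistics.

    ``mode='slope'`` (default): regress the observed order statistics of
    -log10 p through the origin on the expected uniform plotting positions
    -log10(i / (n + 1)); lambda is the fitted slope, 1 for a calibrated
    set. ``mode='median'`` reports the classic genomic-control median
    ratio on the chi-square scale instead.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size < min_set_size:
        raise ValueError(f"set of {p.size} genes is below the minimum {min_set_size}")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    obs = -np.log10(np.sort(p))
    n = p.size
    expected = -np.log10(np.arange(1, n + 1) / (n + 1.0))
    if mode == "slope":
        lam = float(obs @ expected / (expected @ expected))
        resid_sd = float(np.std(obs - lam * expected))
    elif mode == "median":
        lam = float(
            np.median(stats.chi2.isf(p, 1)) / stats.chi2.ppf(0.5, 1)
        )
        resid_sd = float("nan")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return QqResult(label=label, n_genes=n, lam=lam, resid_sd=resid_sd)


def perturbed_set_enrichment(
    deg_table: pd.DataFrame,
    gene_assoc: pd.DataFrame,
    fdr_cut: float = 0.01,
    gene_sig_cut: float = 0.05,
    min_set_size: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """QQ-slope enrichment of perturbed (DEG/DAR) gene sets.

    Per cell type in ``deg_table`` (columns gene, cell_type, fdr): keep
    genes at FDR < ``fdr_cut``, compute the QQ slope of their gene-level
    association p-values, and list genes that also pass the BH-adjusted
    gene-association cut ``gene_sig_cut``. Cell types with fewer than
    ``min_set_size`` scorable genes are reported as not evaluable.

    Returns (per-cell-type lambda table, overlap gene report with
    per-gene multiplicity across cell types).
    """
    need = {"gene", "cell_type", "fdr"}
    if not need.issubset(deg_table.columns):
        raise ValueError(f"DEG table needs columns {sorted(need)}")
    assoc = gene_assoc.set_index("gene")
    gene_q = pd.Series(bh_fdr(assoc["p"].to_numpy()), index=assoc.index)

    lam_rows = []
    overlap_rows = []
    for ct, sub in deg_table.groupby("cell_type"):
        kept = sub.loc[sub["fdr"] < fdr_cut, "gene"].unique()
        scorable = [g for g in kept if g in assoc.index]
        if len(scorable) < min_set_size:
            lam_rows.append(
                {"cell_type": ct, "n_genes": len(scorable), "lambda": np.nan,
                 "resid_sd": np.nan, "evaluable": False}
            )
            continue
        qq = qq_lambda(assoc.loc[scorable, "p"].to_numpy(), min_set_size, label=str(ct))
        lam_rows.append(
            {"cell_type": ct, "n_genes": qq.n_genes, "lambda": qq.lam,
             "resid_sd": qq.resid_sd, "evaluable": True}
        )
        for g in scorable:
            if gene_q[g] < gene_sig_cut:
                overlap_rows.append({"gene": g, "cell_type": ct})

    lam_table = pd.DataFrame(lam_rows)
    if overlap_rows:
        ov = pd.DataFrame(overlap_rows)
        report = (
            ov.groupby("gene")
            .agg(multiplicity=("cell_type", "nunique"),
                 cell_types=("cell_type", lambda s: ",".join(sorted(set(s)))))
            .reset_index()
        )
    else:
        report = pd.DataFrame(columns=["gene", "multiplicity", "cell_types"])
    return lam_table, report
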