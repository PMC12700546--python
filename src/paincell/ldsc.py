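"""Partitioned-heritability core (stratified LD-score regression).

The model: for variant j with annotation memberships a(j, c) and stratified
LD scores l(j, c) = sum_k r2(j, k) a(k, c),

    E[chi2_j] = 1 + N * sum_c tau_c * l(j, c),

so regressing chi2 on N-scaled LD scores estimates the per-SNP heritability
coefficient tau_c of each annotation. Standard errors come from a
delete-one-block jackknife over contiguous variant blocks, and the
cell-type scan fits one conditional model per cluster (baseline + that
cluster's annotation), with Benjamini-Hochberg FDR applied within each
declared dataset family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import bh_fdr
from .synthio import MHC_CHROM, MHC_END, MHC_START, LdPanel

__all__ = [
    "FilterReport",
    "harmonize_and_filter_sumstats",
    "build_snp_annotations",
    "compute_ld_scores",
    "stratified_regression",
    "celltype_heritability_scan",
]

DEFAULT_MHC = (MHC_CHROM, MHC_START, MHC_END)


@dataclass
class FilterReport:
    """Bookkeeping for ordered sumstats filters (no double counting)."""

    n_input: int = 0
    n_duplicate: int = 0
    n_multiallelic: int = 0
    n_mhc: int = 0
    n_surviving: int = 0

    def reconciles(self) -> bool:
        return (
            self.n_input
            == self.n_surviving + self.n_duplicate + self.n_multiallelic + self.n_mhc
        )


def harmonize_and_filter_sumstats(
    raw: pd.DataFrame,
    mhc_interval: tuple[int, int, int] | None = DEFAULT_MHC,
    drop_multiallelic: bool = True,
) -> tuple[pd.DataFrame, FilterReport]:
    """Validate, deduplicate and filter a raw summary-statistics table.

    Filters are applied in order — duplicates (first kept), multi-allelic
    variants, MHC-interval variants — so the removal counts partition the
    input. Z is reconstructed from P (sign lost) when absent; chi2 = Z^2
    and p are (re)derived so the invariant chi2 = Z^2 holds exactly.
    """
    required = {"SNP", "CHR", "BP", "N"}
    if not required.issubset(raw.columns):
        raise ValueError(f"sumstats missing required columns {sorted(required - set(raw.columns))}")
    if "Z" not in raw.columns and "P" not in raw.columns:
        raise ValueError("sumstats need a Z or P column")

    df = raw.copy()
    report = FilterReport(n_input=len(df))

    dup = df.duplicated(subset="SNP", keep="first")
    if dup.any():
        warnings.warn(f"{int(dup.sum())} duplicate variant ids removed (first kept)")
    report.n_duplicate = int(dup.sum())
    df = df[~dup]

    if drop_multiallelic and "is_multiallelic" in df.columns:
        multi = df["is_multiallelic"].astype(bool)
        report.n_multiallelic = int(multi.sum())
        df = df[~multi]

    if mhc_interval is not None:
        chrom, lo, hi = mhc_interval
        in_mhc = (df["CHR"] == chrom) & (df["BP"] >= lo) & (df["BP"] <= hi)
        report.n_mhc = int(in_mhc.sum())
        df = df[~in_mhc]

    if len(df) == 0:
        raise ValueError("no variants survive harmonization filters")
    report.n_surviving = len(df)

    df = df.copy()
    if "Z" not in df.columns:
        df["Z"] = stats.norm.isf(df["P"].to_numpy() / 2.0)
    df["chi2"] = df["Z"].to_numpy() ** 2
    df["P"] = 2.0 * stats.norm.sf(np.abs(df["Z"].to_numpy()))
    return df.reset_index(drop=True), report


def build_snp_annotations(
    panel_variants: pd.DataFrame,
    gene_sets: dict[str, list[str]] | None = None,
    gene_coords: pd.DataFrame | None = None,
    window_kb: float = 100.0,
    region_sets: dict[str, pd.DataFrame] | None = None,
    flank_bp: int = 0,
    add_baseline: bool = True,
) -> pd.DataFrame:
    """Variant-by-annotation membership matrix from gene sets and/or BED sets.

    Gene-set annotations mark a(j, c) = 1 when variant j (1-based BP) falls
    inside any member gene's 1-based inclusive span extended by
    ``window_kb`` on each side. Region sets are BED frames (0-based
    half-open ``[start, end)``: 1-based positions start+1 .. end), extended
    by ``flank_bp``. A 'baseline' all-ones column is appended.
    """
    chrom = panel_variants["CHR"].to_numpy()
    bp = panel_variants["BP"].to_numpy()
    cols: dict[str, np.ndarray] = {}

    if gene_sets:
        if gene_coords is None:
            raise ValueError("gene_sets given without gene_coords")
        coords = gene_coords.set_index("gene")
        window = window_kb * 1_000.0
        for name, genes in gene_sets.items():
            known = [g for g in genes if g in coords.index]
            skipped = len(genes) - len(known)
            if skipped:
                warnings.warn(f"gene set {name!r}: {skipped} unknown genes skipped")
            member = np.zeros(len(bp), dtype=bool)
            for g in known:
                row = coords.loc[g]
                member |= (
                    (chrom == row["chrom"])
                    & (bp >= row["start"] - window)
                    & (bp <= row["end"] + window)
                )
            if not member.any():
                warnings.warn(f"gene set {name!r} produced an all-zero annotation")
            cols[name] = member.astype(float)

    if region_sets:
        for name, bed in region_sets.items():
            member = np.zeros(len(bp), dtype=bool)
            for _, row in bed.iterrows():
                member |= (
                    (chrom == row["chrom"])
                    & (bp >= row["start"] + 1 - flank_bp)
                    & (bp <= row["end"] + flank_bp)
                )
            cols[name] = member.astype(float)

    if add_baseline:
        cols["baseline"] = np.ones(len(bp))
    out = pd.DataFrame(cols, index=panel_variants["SNP"].to_numpy())
    out.index.name = "SNP"
    return out


def compute_ld_scores(
    panel: LdPanel,
    annotations: pd.DataFrame,
    r2_adjustment: str = "raw",
    n_ref: int = 10_000,
) -> pd.DataFrame:
    """Stratified LD scores l(j, c) = sum_k r2(j, k) a(k, c) within blocks.

    ``r2_adjustment='unbiased'`` applies the standard finite-reference
    correction r2 - (1 - r2) / (n_ref - 2) to off-diagonal pairs.
    """
    if len(annotations) != panel.n_variants:
        raise ValueError("annotations not aligned to panel variants")
    if not np.array_equal(annotations.index.to_numpy(), panel.variants["SNP"].to_numpy()):
        raise ValueError("annotation index does not match panel variant ids")
    if r2_adjustment not in ("raw", "unbiased"):
        raise ValueError(f"unknown r2_adjustment {r2_adjustment!r}")

    A = annotations.to_numpy(dtype=float)
    out = np.empty_like(A)
    for b in panel.block_ids:
        idx = panel.block_index(b)
        R = panel.correlation_for_size(len(idx))
        r2 = R**2
        if r2_adjustment == "unbiased":
            adj = r2 - (1.0 - r2) / (n_ref - 2)
            np.fill_diagonal(adj, 1.0)
            r2 = adj
        out[idx] = r2 @ A[idx]
    ld = pd.DataFrame(out, index=annotations.index, columns=annotations.columns)
    return ld


@dataclass
class PartitionFit:
    """Stratified-regression fit: per-annotation tau, jackknife SE, p."""

    table: pd.DataFrame  # annotation, tau_hat, se, p_one_sided, absorbed
    intercept: float
    intercept_se: float
    n_variants: int
    n_jackknife_blocks: int
    ridge_fallback: bool = False
    extra: dict = field(default_factory=dict)


def _wls_jackknife(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, n_blocks: int
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Weighted LS coefficients + delete-one-block jackknife SEs.

    Blocks are contiguous equal-count runs of the (already ordered) rows.
    Returns (coef, se, ridge_fallback).
    """
    n, p = X.shape
    # column scaling: conditioning should reflect collinearity, not the
    # raw magnitude gap between the intercept and N-scaled LD scores
    scale = np.sqrt((X**2).mean(axis=0))
    scale[scale == 0] = 1.0
    Xs = X / scale
    Xw = Xs * w[:, None]
    xtx = Xs.T @ Xw
    xty = Xw.T @ y

    ridge = False
    if np.linalg.cond(xtx) > 1e10:
        warnings.warn("collinear LD-score columns; ridge fallback applied")
        ridge = True
        xtx = xtx + 1e-8 * np.trace(xtx) / p * np.eye(p)
    coef = np.linalg.solve(xtx, xty) / scale

    bounds = (np.arange(n_blocks + 1) * n) // n_blocks
    thetas = np.empty((n_blocks, p))
    for b in range(n_blocks):
        sl = slice(bounds[b], bounds[b + 1])
        xtx_b = Xs[sl].T @ Xw[sl]
        xty_b = Xw[sl].T @ y[sl]
        m = xtx - xtx_b
        if ridge:
            m = m + 1e-8 * np.trace(m) / p * np.eye(p)
        thetas[b] = np.linalg.solve(m, xty - xty_b) / scale
    mean = thetas.mean(axis=0)
    se = np.sqrt((n_blocks - 1) / n_blocks * ((thetas - mean) ** 2).sum(axis=0))
    return coef, se, ridge


def default_jackknife_blocks(n_variants: int, requested: int = 200) -> int:
    """At most one jackknife block per 50 variants, at least 2."""
    return max(2, min(requested, n_variants // 50))


def stratified_regression(
    sumstats: pd.DataFrame,
    ldscores: pd.DataFrame,
    n_jackknife_blocks: int = 200,
    weight_column: str = "baseline",
    heteroskedasticity_weights: bool = False,
) -> PartitionFit:
    """Regress chi2 on N-scaled stratified LD scores.

    Rows of ``sumstats`` are matched to ``ldscores`` by variant id (SNP);
    the regression is weighted by 1 / max(l_weight, 1) where l_weight is
    the ``weight_column`` LD score (the baseline by default). With
    ``heteroskedasticity_weights`` a second pass divides the weights by
    the squared fitted mean (var[chi2] ~ 2 E[chi2]^2), the standard
    two-step scheme that keeps high-signal variants from dominating the
    fit noise. One-sided p-values test tau_c > 0 against the normal
    upper tail.
    """
    if n_jackknife_blocks < 2:
        raise ValueError("need >= 2 jackknife blocks")
    common = sumstats["SNP"].isin(ldscores.index)
    ss = sumstats[common]
    if len(ss) == 0:
        raise ValueError("no variants shared between sumstats and LD scores")
    # keep the LD-score (panel) ordering so jackknife blocks are genomic runs
    present = set(ss["SNP"])
    order = [s for s in ldscores.index if s in present]
    ss = ss.set_index("SNP").loc[order]
    L = ldscores.loc[order]

    n_blocks = default_jackknife_blocks(len(ss), n_jackknife_blocks)
    chi2 = ss["chi2"].to_numpy() if "chi2" in ss.columns else ss["Z"].to_numpy() ** 2
    N = ss["N"].to_numpy(dtype=float)
    # LD-score columns that are (numerically) constant are absorbed by the
    # intercept; their tau is unidentifiable and reported as NaN
    annots = list(L.columns)
    absorbed = [
        c for c in annots
        if np.std(L[c].to_numpy()) <= 1e-12 * max(1.0, abs(np.mean(L[c].to_numpy())))
    ]
    fitted = [c for c in annots if c not in absorbed]
    if not fitted:
        raise ValueError(
            "all LD-score columns are constant; nothing to fit "
            "(an annotation covering every variant is absorbed by the "
            "intercept — check top-K size and gene windows against the "
            "panel's extent)"
        )
    X = np.column_stack([np.ones(len(ss))] + [N * L[c].to_numpy() for c in fitted])
    if weight_column in L.columns:
        w = 1.0 / np.maximum(L[weight_column].to_numpy(), 1.0)
    else:
        w = np.ones(len(ss))

    coef, se, ridge = _wls_jackknife(X, chi2, w, n_blocks)
    if heteroskedasticity_weights:
        fitted_mean = np.maximum(X @ coef, 1.0)
        w = w / (2.0 * fitted_mean**2)
        coef, se, ridge = _wls_jackknife(X, chi2, w, n_blocks)
    tau = dict(zip(fitted, coef[1:]))
    tau_se = dict(zip(fitted, se[1:]))
    rows = []
    for c in annots:
        if c in absorbed:
            rows.append({"annotation": c, "tau_hat": np.nan, "se": np.nan,
                         "p_one_sided": np.nan, "absorbed": True})
            continue
        z = tau[c] / tau_se[c] if tau_se[c] > 0 else np.nan
        # the jackknife ratio is t-distributed with ~(blocks - 1) df; the
        # normal tail is anti-conservative when blocks are few
        rows.append({"annotation": c, "tau_hat": tau[c], "se": tau_se[c],
                     "p_one_sided": float(stats.t.sf(z, n_blocks - 1)),
                     "absorbed": False})
    return PartitionFit(
        table=pd.DataFrame(rows),
        intercept=float(coef[0]),
        intercept_se=float(se[0]),
        n_variants=len(ss),
        n_jackknife_blocks=n_blocks,
        ridge_fallback=ridge,
    )


def celltype_heritability_scan(
    sumstats: pd.DataFrame,
    panel: LdPanel,
    cluster_annotations: pd.DataFrame,
    baseline_annotations: pd.DataFrame | None = None,
    families: dict[str, str] | None = None,
    n_jackknife_blocks: int = 200,
    fdr_alpha: float = 0.05,
    r2_adjustment: str = "raw",
    heteroskedasticity_weights: bool = True,
) -> pd.DataFrame:
    """One conditional stratified regression per cell-type cluster.

    Each cluster's model is [intercept, baseline annotation(s), that
    cluster's annotation]; the reported coefficient is the cluster's tau
    conditional on the baseline. BH-FDR is applied within each dataset
    family (``families`` maps cluster label -> family name; default one
    family 'all'), flagging q < ``fdr_alpha``.
    """
    if cluster_annotations.shape[1] == 0:
        raise ValueError("no cluster annotations supplied")
    clusters = list(cluster_annotations.columns)
    if baseline_annotations is None:
        baseline_annotations = pd.DataFrame(
            {"baseline": np.ones(panel.n_variants)},
            index=panel.variants["SNP"].to_numpy(),
        )
        baseline_annotations.index.name = "SNP"
    base_cols = list(baseline_annotations.columns)

    all_annot = pd.concat([baseline_annotations, cluster_annotations], axis=1)
    ld = compute_ld_scores(panel, all_annot, r2_adjustment=r2_adjustment)

    fam = families or {}
    rows = []
    for cl in clusters:
        fit = stratified_regression(
            sumstats,
            ld[base_cols + [cl]],
            n_jackknife_blocks=n_jackknife_blocks,
            weight_column=base_cols[0],
            heteroskedasticity_weights=heteroskedasticity_weights,
        )
        row = fit.table.set_index("annotation").loc[cl]
        rows.append(
            {
                "cluster": cl,
                "tau_hat": row["tau_hat"],
                "se": row["se"],
                "p_one_sided": row["p_one_sided"],
                "family": fam.get(cl, "all"),
                "n_snps_in_annot": int(cluster_annotations[cl].sum()),
            }
        )
    out = pd.DataFrame(rows)

    out["q_fdr"] = np.nan
    for family, sub in out.groupby("family"):
        if len(sub) == 0:
            raise ValueError(f"empty FDR family {family!r}")
        out.loc[sub.index, "q_fdr"] = bh_fdr(sub["p_one_sided"].to_numpy())
    out["significant"] = out["q_fdr"] < fdr_alpha
    return out
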