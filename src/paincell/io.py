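"""Readers and writers for the pipeline's plain-text formats.

Conventions: summary statistics are tab-separated with a header row and
columns SNP, CHR, BP, A1, A2, N and Z and/or P; BED is 0-based half-open;
GMT lines are ``name<TAB>description<TAB>gene...``; gene coordinates are a
TSV with 1-based inclusive spans; expression is a dense genes x cells TSV
(or an MTX triplet with row/column label files).
"""

from __future__ import annotations

import re
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "N"]


class ParseError(ValueError):
    """A file failed to parse under its declared format."""


def normalize_chrom(value) -> int:
    """Map 'chr1'/'1' style chromosome names to integers (X=23, Y=24, MT=25)."""
    s = str(value).strip()
    s = re.sub(r"^chr", "", s, flags=re.IGNORECASE)
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if s.upper() in special:
        return special[s.upper()]
    try:
        return int(s)
    except ValueError as exc:
        raise ParseError(f"unrecognised chromosome name {value!r}") from exc


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read a summary-statistics TSV, reconstructing Z from P if needed."""
    from scipy import stats

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required sumstats columns {missing}")
    if "Z" not in df.columns and "P" not in df.columns:
        raise ParseError(f"{path}: need a Z or P column")
    df = df.copy()
    df["CHR"] = df["CHR"].map(normalize_chrom)
    if "Z" not in df.columns:
        # sign is unrecoverable from P alone; magnitude preserves chi2
        df["Z"] = stats.norm.isf(df["P"].to_numpy() / 2.0)
    if "P" not in df.columns:
        df["P"] = 2.0 * stats.norm.sf(np.abs(df["Z"].to_numpy()))
    return df


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["SNP", "CHR", "BP", "A1", "A2", "is_multiallelic", "N", "Z", "P"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def check_z_p_consistency(df: pd.DataFrame, tol: float = 1e-4) -> int:
    """Count rows where |Z| disagrees with the Z implied by P."""
    from scipy import stats

    implied = stats.norm.isf(df["P"].to_numpy() / 2.0)
    return int(np.sum(np.abs(np.abs(df["Z"].to_numpy()) - implied) > tol))


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED (0-based half-open) into columns chrom, start, end [, name]."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: BED line has fewer than 3 fields")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer BED coordinates") from exc
        if start > end:
            raise ParseError(f"{path}:{lineno}: BED start > end")
        row = {"chrom": normalize_chrom(parts[0]), "start": start, "end": end}
        if len(parts) > 3:
            row["name"] = parts[3]
        rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"] if rows and "name" in rows[0] else ["chrom", "start", "end"])


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    out = df[["chrom", "start", "end"] + (["name"] if "name" in df.columns else [])]
    out.to_csv(path, sep="\t", index=False, header=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
        name, genes = parts[0], [g for g in parts[2:] if g]
        if name in sets:
            raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = list(dict.fromkeys(genes))
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gene_coords(path: str | Path) -> pd.DataFrame:
    """Gene coordinate TSV with columns gene, chrom, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    need = {"gene", "chrom", "start", "end"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: gene coordinate table needs columns {sorted(need)}")
    df = df.copy()
    df["chrom"] = df["chrom"].map(normalize_chrom)
    if (df["start"] > df["end"]).any():
        bad = df.index[df["start"] > df["end"]][0]
        raise ParseError(f"{path}: gene row {bad} has start > end")
    return df


def read_expression_tsv(expr_path: str | Path, cells_path: str | Path) -> ad.AnnData:
    """Dense genes x cells TSV plus a cell metadata TSV (cell, cluster, donor)."""
    expr = pd.read_csv(expr_path, sep="\t", index_col="gene")
    cells = pd.read_csv(cells_path, sep="\t")
    if "cell" not in cells.columns or "cluster" not in cells.columns:
        raise ParseError(f"{cells_path}: cell table needs 'cell' and 'cluster' columns")
    cells = cells.set_index("cell")
    missing = [c for c in expr.columns if c not in cells.index]
    if missing:
        raise ParseError(f"{cells_path}: no metadata for cells {missing[:5]}")
    obs = cells.loc[expr.columns]
    obs["cluster"] = pd.Categorical(obs["cluster"])
    adata = ad.AnnData(
        X=expr.to_numpy().T,
        obs=obs,
        var=pd.DataFrame(index=expr.index),
        uns={"expression_scale": "tpm"},
    )
    return adata


def read_expression_mtx(
    mtx_path: str | Path, genes_path: str | Path, cells_path: str | Path
) -> ad.AnnData:
    """MTX triplet (genes x cells) with gene and cell label files."""
    from scipy.io import mmread

    mat = mmread(str(mtx_path)).tocsr()
    genes = [line.split("\t")[0] for line in Path(genes_path).read_text().splitlines() if line]
    cells = pd.read_csv(cells_path, sep="\t")
    if mat.shape[0] != len(genes):
        raise ParseError(f"{mtx_path}: matrix rows != number of gene labels")
    if mat.shape[1] != len(cells):
        raise ParseError(f"{mtx_path}: matrix columns != number of cell rows")
    obs = cells.set_index("cell")
    obs["cluster"] = pd.Categorical(obs["cluster"])
    return ad.AnnData(
        X=np.asarray(mat.todense()).T,
        obs=obs,
        var=pd.DataFrame(index=genes),
        uns={"expression_scale": "tpm"},
    )


def load_fixture_bundle(indir: str | Path) -> dict:
    """Load everything written by :func:`paincell.synthio.write_fixture_bundle`."""
    from .synthio import LdPanel, SimulationTruth

    d = Path(indir)
    panel_tab = pd.read_csv(d / "ld_panel.tsv", sep="\t")
    r = float(panel_tab["within_block_correlation"].iloc[0])
    panel = LdPanel(
        variants=panel_tab.drop(columns=["within_block_correlation"]),
        within_block_correlation=r,
    )
    out = {
        "panel": panel,
        "sumstats": read_sumstats(d / "sumstats.tsv"),
        "adata": read_expression_tsv(d / "expression.tsv", d / "cells.tsv"),
        "covariates": pd.read_csv(d / "covariates.tsv", sep="\t"),
        "gene_coords": read_gene_coords(d / "gene_coords.tsv"),
        "cluster_metadata": pd.read_csv(d / "cluster_metadata.tsv", sep="\t"),
        "perturbation": pd.read_csv(d / "perturbation.tsv", sep="\t"),
        "truth": SimulationTruth.from_json((d / "truth.json").read_text()),
    }
    gmt = d / "gene_sets.gmt"
    if gmt.exists():
        out["gene_sets"] = read_gmt(gmt)
    return out
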