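"""Configuration, orchestration, and reporting for the full pipeline.

Stages run in dependency order: specificity -> gene-set annotations -> LD
scores -> heritability scan; SNP-to-gene mapping -> gene association ->
gene-property scan; dual-method concordance; category over-representation;
gene heritability -> pre-ranked GSEA; perturbed-set QQ enrichment. Outputs
are tab-separated tables plus a JSON run report; a fixed seed makes reruns
byte-identical, and an unchanged config hash lets a completed run be
reused without recomputation.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, enrich, genes, io, ldsc, specificity

__all__ = ["PipelineConfig", "load_inputs", "run_pipeline", "write_report"]

_ALLOWED_STAGES = {"specificity", "ldsc", "magma", "concordance", "overrep", "herit", "perturbed"}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    input_dir: str
    out_dir: str
    seed: int = 0
    top_k: int = 1000
    window_kb: float = 100.0
    flank_bp: int = 0
    n_jackknife_blocks: int = 200
    fdr_alpha: float = 0.05
    deg_fdr_cut: float = 0.01
    gene_sig_cut: float = 0.05
    gsea_permutations: int = 200
    gene_window_kb: float = 0.0
    drop_multiallelic: bool = True
    apply_mhc_filter: bool = True
    universe_mode: str = "all"  # or 'annotated'
    stages: list[str] = field(default_factory=lambda: sorted(_ALLOWED_STAGES))

    def __post_init__(self) -> None:
        unknown = set(self.stages) - _ALLOWED_STAGES
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.universe_mode not in ("all", "annotated"):
            raise ValueError(f"unknown universe_mode {self.universe_mode!r}")
        if "concordance" in self.stages and not {"ldsc", "magma"} <= set(self.stages):
            raise ValueError("concordance requires both the ldsc and magma stages")
        if "perturbed" in self.stages and "magma" not in self.stages:
            raise ValueError("perturbed-set enrichment requires the magma stage")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_inputs(config: PipelineConfig) -> dict:
    """Load and validate the input bundle named by the config."""
    bundle = io.load_fixture_bundle(config.input_dir)
    n_bad = io.check_z_p_consistency(bundle["sumstats"])
    if n_bad:
        import warnings

        warnings.warn(f"{n_bad} sumstats rows with inconsistent |Z| vs P")
    return bundle


def _region_categories(meta: pd.DataFrame) -> dict[str, set[str]]:
    frac_cols = [c for c in meta.columns if c.startswith("frac_")]
    cats: dict[str, set[str]] = {c.removeprefix("frac_"): set() for c in frac_cols}
    for _, row in meta.iterrows():
        region = enrich.assign_region({c.removeprefix("frac_"): row[c] for c in frac_cols})
        if region is not None:
            cats[region].add(row["cluster"])
    return cats


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Execute all configured stages; returns the run report.

    If the output directory already holds a completed report produced
    under the same config hash, the run is reused and stages are skipped
    (``force=True`` recomputes regardless).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report_path = out / "report.json"
    chash = config.config_hash()
    if not force and report_path.exists():
        prev = json.loads(report_path.read_text())
        if prev.get("config_hash") == chash:
            prev["stages_skipped"] = True
            return prev

    t0 = time.time()
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": chash,
        "stages_skipped": False,
        "counts": {},
    }
    (out / "effective_config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=True))

    bundle = load_inputs(config)
    panel = bundle["panel"]
    stages = set(config.stages)

    sumstats, filt = ldsc.harmonize_and_filter_sumstats(
        bundle["sumstats"],
        mhc_interval=ldsc.DEFAULT_MHC if config.apply_mhc_filter else None,
        drop_multiallelic=config.drop_multiallelic,
    )
    report["counts"]["sumstats"] = asdict(filt)

    spec = None
    top_sets: dict[str, list[str]] = {}
    if "specificity" in stages:
        logged = specificity.transform_and_aggregate(bundle["adata"], mode="per_sample")
        spec = specificity.specificity_regression(logged, bundle["covariates"])
        top_sets = specificity.top_k_gene_sets(spec, k=config.top_k)
        spec.rank_table().to_csv(out / "specificity.tsv", sep="\t", index=False)
        io.write_gmt(top_sets, out / "top_sets.gmt")
        report["counts"]["specificity"] = {
            "n_genes": len(spec.genes),
            "n_clusters": len(spec.clusters),
            "n_singular_clusters": len(spec.singular_clusters),
            "top_k": min(config.top_k, len(spec.genes)),
        }

    scan = None
    if "ldsc" in stages:
        if not top_sets:
            raise ValueError("ldsc stage requires the specificity stage")
        annots = ldsc.build_snp_annotations(
            panel.variants,
            gene_sets=top_sets,
            gene_coords=bundle["gene_coords"],
            window_kb=config.window_kb,
            add_baseline=False,
        )
        scan = ldsc.celltype_heritability_scan(
            sumstats,
            panel,
            annots,
            n_jackknife_blocks=config.n_jackknife_blocks,
            fdr_alpha=config.fdr_alpha,
        )
        scan.to_csv(out / "sldsc_scan.tsv", sep="\t", index=False)
        report["counts"]["sldsc"] = {
            "n_clusters": len(scan),
            "n_significant": int(scan["significant"].sum()),
        }

    assoc = prop = None
    mapping = None
    if "magma" in stages:
        mapping, map_report = genes.map_snps_to_genes(
            sumstats,
            bundle["gene_coords"],
            window_up_kb=config.gene_window_kb,
            window_down_kb=config.gene_window_kb,
        )
        assoc = genes.gene_association(sumstats, mapping, panel)
        assoc.to_csv(out / "gene_assoc.tsv", sep="\t", index=False)
        if spec is None:
            raise ValueError("magma stage requires the specificity stage")
        logged = specificity.transform_and_aggregate(bundle["adata"], mode="per_sample")
        avg = specificity.average_expression(logged)
        prop = genes.gene_property_scan(assoc, spec.t, avg)
        prop.to_csv(out / "gene_property_scan.tsv", sep="\t", index=False)
        report["counts"]["magma"] = {
            **map_report,
            "n_scored_genes": len(assoc),
            "n_significant_clusters": int((prop["q_fdr"] < config.fdr_alpha).sum()),
        }

    if "concordance" in stages:
        conc = enrich.concordance_intersect(
            scan, prop, alpha=config.fdr_alpha, q_a="q_fdr", q_b="q_fdr"
        )
        conc.flags.to_csv(out / "concordance.tsv", sep="\t", index=False)
        sizes = conc.sizes()
        assert sizes["n_union"] == sizes["n_a"] + sizes["n_b"] - sizes["n_concordant"]
        report["counts"]["concordance"] = sizes
        report["concordant_clusters"] = sorted(conc.concordant)

    if "overrep" in stages:
        meta = bundle["cluster_metadata"]
        sig = set(scan.loc[scan["significant"], "cluster"]) if scan is not None else set()
        nt_cats = {
            nt: set(meta.loc[meta["neurotransmitter"] == nt, "cluster"])
            for nt in meta["neurotransmitter"].unique()
        }
        if config.universe_mode == "all":
            universe = set(meta["cluster"])
        else:
            universe = set().union(*nt_cats.values())
        ov_nt = enrich.hypergeom_overrep(sig & universe, nt_cats, universe)
        ov_nt.insert(0, "category_kind", "neurotransmitter")
        region_cats = _region_categories(meta)
        ov_rg = enrich.hypergeom_overrep(sig & universe, region_cats, universe)
        ov_rg.insert(0, "category_kind", "region")
        overrep = pd.concat([ov_nt, ov_rg], ignore_index=True)
        overrep.to_csv(out / "overrepresentation.tsv", sep="\t", index=False)
        report["counts"]["overrep"] = {"n_categories": len(overrep)}

    if "herit" in stages:
        if mapping is None:
            mapping, _ = genes.map_snps_to_genes(
                sumstats, bundle["gene_coords"],
                window_up_kb=config.gene_window_kb,
                window_down_kb=config.gene_window_kb,
            )
        herit = genes.gene_heritability_test(sumstats, mapping, panel)
        herit.to_csv(out / "gene_heritability.tsv", sep="\t", index=False)
        from scipy import stats as sps

        ranking = pd.Series(
            sps.norm.isf(herit["p"].clip(1e-300, 1.0)), index=herit["gene"], name="herit_z"
        )
        sets_for_gsea = top_sets or bundle.get("gene_sets", {})
        gsea = genes.preranked_gsea(
            ranking,
            sets_for_gsea,
            n_permutations=config.gsea_permutations,
            seed=config.seed,
        )
        gsea.to_csv(out / "gsea.tsv", sep="\t", index=False)
        report["counts"]["herit"] = {
            "n_genes": len(herit),
            "n_significant_genes": int((herit["q_fdr"] < config.fdr_alpha).sum()),
            "n_gsea_sets": len(gsea),
        }

    if "perturbed" in stages:
        lam_table, overlap = enrich.perturbed_set_enrichment(
            bundle["perturbation"],
            assoc,
            fdr_cut=config.deg_fdr_cut,
            gene_sig_cut=config.gene_sig_cut,
        )
        lam_table.to_csv(out / "perturbed_lambda.tsv", sep="\t", index=False)
        overlap.to_csv(out / "perturbed_overlap.tsv", sep="\t", index=False)
        report["counts"]["perturbed"] = {
            "n_cell_types": len(lam_table),
            "n_evaluable": int(lam_table["evaluable"].sum()),
            "n_overlap_genes": len(overlap),
        }
        report["lambda_by_cell_type"] = {
            str(r["cell_type"]): (None if not r["evaluable"] else float(r["lambda"]))
            for _, r in lam_table.iterrows()
        }

    report["wall_time_s"] = round(time.time() - t0, 3)
    write_report(report, out, fmt="json")
    return report


def analyze_study(
    study: dict,
    top_k: int = 100,
    window_kb: float = 0.0,
    n_jackknife_blocks: int = 200,
    fdr_alpha: float = 0.05,
) -> dict:
    """Run the dual-method cell-type analysis on an in-memory study.

    Chains specificity scoring, top-K annotation building, the stratified
    heritability scan, gene association, the gene-property scan, and the
    concordance intersection, without touching disk. ``top_k`` defaults to
    5% of a 2,000-gene universe, the proportion the top-1000 rule implies
    on a genome-scale gene set. Returns the intermediate tables keyed by
    stage.
    """
    logged = specificity.transform_and_aggregate(study["adata"], mode="per_sample")
    spec = specificity.specificity_regression(logged, study["covariates"])
    top_sets = specificity.top_k_gene_sets(spec, k=top_k)
    sumstats, filt = ldsc.harmonize_and_filter_sumstats(study["sumstats"])
    annots = ldsc.build_snp_annotations(
        study["panel"].variants,
        gene_sets=top_sets,
        gene_coords=study["gene_coords"],
        window_kb=window_kb,
        add_baseline=False,
    )
    scan = ldsc.celltype_heritability_scan(
        sumstats, study["panel"], annots,
        n_jackknife_blocks=n_jackknife_blocks, fdr_alpha=fdr_alpha,
    )
    mapping, _ = genes.map_snps_to_genes(sumstats, study["gene_coords"])
    assoc = genes.gene_association(sumstats, mapping, study["panel"])
    avg = specificity.average_expression(logged)
    prop = genes.gene_property_scan(assoc, spec.t, avg)
    conc = enrich.concordance_intersect(scan, prop, alpha=fdr_alpha)
    return {
        "sumstats": sumstats,
        "filter_report": filt,
        "specificity": spec,
        "top_sets": top_sets,
        "scan": scan,
        "mapping": mapping,
        "gene_assoc": assoc,
        "property_scan": prop,
        "concordance": conc,
    }


def write_report(report: dict, out_dir: str | Path, fmt: str = "json") -> Path:
    """Serialise the run report (JSON, or a TSV bundle of its count tables)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        path = out / "report.json"
        path.write_text(json.dumps(_to_jsonable(report), indent=1, sort_keys=True))
        return path
    if fmt == "tsv_bundle":
        path = out / "report_counts.tsv"
        rows = []
        for stage, counts in report.get("counts", {}).items():
            for key, val in counts.items():
                rows.append({"stage": stage, "key": key, "value": val})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return path
    raise ValueError(f"unknown report format {fmt!r}")


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj
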