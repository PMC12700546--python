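"""Partitioned-heritability core: filters, annotations, LD scores, the
stratified regression and the cell-type scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paincell import ldsc, synthio


def _toy_sumstats():
    """10 variants: 2 inside the MHC interval, 1 multi-allelic (disjoint)."""
    rows = []
    for i in range(7):
        rows.append({"SNP": f"v{i}", "CHR": 1, "BP": 1000 + i, "A1": "A", "A2": "G",
                     "N": 1000, "Z": 1.0, "is_multiallelic": i == 0})
    rows.append({"SNP": "m1", "CHR": 6, "BP": 26_000_000, "A1": "A", "A2": "G",
                 "N": 1000, "Z": 1.0, "is_multiallelic": False})
    rows.append({"SNP": "m2", "CHR": 6, "BP": 33_000_000, "A1": "A", "A2": "G",
                 "N": 1000, "Z": 1.0, "is_multiallelic": False})
    rows.append({"SNP": "v7", "CHR": 2, "BP": 500, "A1": "A", "A2": "G",
                 "N": 1000, "Z": 2.0, "is_multiallelic": False})
    return pd.DataFrame(rows)


class TestHarmonize:
    def test_toy_table_filter_counts(self):
        out, rep = ldsc.harmonize_and_filter_sumstats(_toy_sumstats())
        assert len(out) == 7
        assert (rep.n_multiallelic, rep.n_mhc) == (1, 2)
        assert rep.reconciles()

    def test_no_op_filters_are_identity(self):
        out, rep = ldsc.harmonize_and_filter_sumstats(
            _toy_sumstats(), mhc_interval=None, drop_multiallelic=False
        )
        assert len(out) == 10
        assert rep.reconciles()

    def test_duplicates_removed_first_kept(self):
        df = pd.concat([_toy_sumstats(), _toy_sumstats().iloc[[1]]], ignore_index=True)
        with pytest.warns(UserWarning, match="duplicate"):
            out, rep = ldsc.harmonize_and_filter_sumstats(df)
        assert rep.n_duplicate == 1
        assert rep.reconciles()

    def test_z_reconstructed_from_p_matches_chi2(self):
        df = _toy_sumstats().drop(columns="Z")
        df["P"] = [0.05, 0.5, 0.01, 0.2, 0.9, 0.3, 0.7, 0.4, 0.6, 0.001]
        out, _ = ldsc.harmonize_and_filter_sumstats(df, mhc_interval=None, drop_multiallelic=False)
        implied_chi2 = stats.chi2.isf(df["P"].to_numpy(), 1)
        assert np.allclose(out["chi2"].to_numpy(), implied_chi2, rtol=1e-10)

    def test_schema_errors(self):
        with pytest.raises(ValueError):
            ldsc.harmonize_and_filter_sumstats(_toy_sumstats().drop(columns=["N"]))
        only_mhc = _toy_sumstats().iloc[[7, 8]]
        with pytest.raises(ValueError, match="survive"):
            ldsc.harmonize_and_filter_sumstats(only_mhc)


class TestAnnotations:
    def _variants(self, positions, chrom=1):
        return pd.DataFrame({
            "SNP": [f"v{i}" for i in range(len(positions))],
            "CHR": chrom, "BP": positions,
        })

    def test_gene_window_membership(self):
        coords = pd.DataFrame({"gene": ["g"], "chrom": [1], "start": [1_000], "end": [2_000]})
        variants = self._variants([50_000, 200_000])
        ann = ldsc.build_snp_annotations(
            variants, gene_sets={"s": ["g"]}, gene_coords=coords, window_kb=100.0
        )
        assert ann["s"].tolist() == [1.0, 0.0]
        assert ann["baseline"].tolist() == [1.0, 1.0]

    def test_bed_half_open_arithmetic(self):
        bed = pd.DataFrame({"chrom": [1], "start": [100], "end": [200]})
        variants = self._variants([100, 101, 200, 201])
        ann = ldsc.build_snp_annotations(variants, region_sets={"r": bed}, add_baseline=False)
        # BED [100, 200) covers 1-based positions 101..200
        assert ann["r"].tolist() == [0.0, 1.0, 1.0, 0.0]
        empty = pd.DataFrame({"chrom": [1], "start": [100], "end": [100]})
        ann0 = ldsc.build_snp_annotations(variants, region_sets={"r": empty}, add_baseline=False)
        assert ann0["r"].sum() == 0.0

    def test_flank_extends_regions(self):
        bed = pd.DataFrame({"chrom": [1], "start": [100], "end": [200]})
        variants = self._variants([95, 205])
        ann = ldsc.build_snp_annotations(
            variants, region_sets={"r": bed}, flank_bp=10, add_baseline=False
        )
        assert ann["r"].tolist() == [1.0, 1.0]

    def test_empty_gene_set_warns_all_zero(self):
        coords = pd.DataFrame({"gene": ["g"], "chrom": [1], "start": [10], "end": [20]})
        variants = self._variants([1000])
        with pytest.warns(UserWarning, match="unknown genes|all-zero"):
            ann = ldsc.build_snp_annotations(
                variants, gene_sets={"s": ["absent"]}, gene_coords=coords, window_kb=0.0
            )
        assert ann["s"].sum() == 0.0


class TestLdScores:
    def test_identity_ld_scores_equal_membership(self):
        panel = synthio.simulate_ld_panel(100, 10, within_block_correlation=0.0, seed=0)
        rng = np.random.default_rng(1)
        ann = pd.DataFrame({"a": (rng.random(100) < 0.4).astype(float)},
                           index=panel.variants["SNP"].to_numpy())
        ld = ldsc.compute_ld_scores(panel, ann)
        assert np.array_equal(ld["a"].to_numpy(), ann["a"].to_numpy())

    def test_two_variant_block_r_half(self):
        panel = synthio.simulate_ld_panel(2, 1, within_block_correlation=0.5, seed=0)
        ann = pd.DataFrame({"a": [1.0, 1.0]}, index=panel.variants["SNP"].to_numpy())
        ld = ldsc.compute_ld_scores(panel, ann)
        assert np.allclose(ld["a"].to_numpy(), [1.25, 1.25])

    def test_baseline_dominates_subannotations(self, small_panel):
        rng = np.random.default_rng(2)
        ann = pd.DataFrame(
            {"sub": (rng.random(small_panel.n_variants) < 0.3).astype(float),
             "baseline": np.ones(small_panel.n_variants)},
            index=small_panel.variants["SNP"].to_numpy(),
        )
        ld = ldsc.compute_ld_scores(small_panel, ann)
        assert (ld["baseline"].to_numpy() >= ld["sub"].to_numpy() - 1e-12).all()

    def test_unbiased_adjustment_shrinks_offdiagonal_mass(self, small_panel, all_ones_annotation):
        raw = ldsc.compute_ld_scores(small_panel, all_ones_annotation, "raw")
        adj = ldsc.compute_ld_scores(small_panel, all_ones_annotation, "unbiased", n_ref=100)
        assert (adj["all"].to_numpy() < raw["all"].to_numpy()).all()

    def test_misalignment_rejected(self, small_panel, all_ones_annotation):
        with pytest.raises(ValueError):
            ldsc.compute_ld_scores(small_panel, all_ones_annotation.iloc[:-1])


class TestStratifiedRegression:
    def _noiseless(self, seed=3, n=2_000, blocks=20, taus=(3e-5, 1e-5), N=10_000):
        panel = synthio.simulate_ld_panel(n, blocks, 0.5, seed=seed)
        rng = np.random.default_rng(0)
        ann = pd.DataFrame(
            {"a1": rng.integers(0, 2, n).astype(float),
             "a2": rng.integers(0, 2, n).astype(float)},
            index=panel.variants["SNP"].to_numpy(),
        )
        ld = ldsc.compute_ld_scores(panel, ann)
        ss = panel.variants[["SNP"]].copy()
        ss["N"] = N
        ss["chi2"] = (1.0 + N * (taus[0] * ld["a1"] + taus[1] * ld["a2"])).to_numpy()
        return panel, ann, ld, ss, taus

    def test_noiseless_recovery_to_1e8(self):
        _, _, ld, ss, taus = self._noiseless()
        fit = ldsc.stratified_regression(ss, ld, n_jackknife_blocks=20)
        got = fit.table.set_index("annotation")["tau_hat"]
        assert abs(got["a1"] - taus[0]) / taus[0] < 1e-8
        assert abs(got["a2"] - taus[1]) / taus[1] < 1e-8
        assert fit.intercept == pytest.approx(1.0, abs=1e-8)

    def test_variant_permutation_leaves_tau_unchanged(self):
        _, _, ld, ss, _ = self._noiseless()
        fit1 = ldsc.stratified_regression(ss, ld, n_jackknife_blocks=20)
        perm = ss.sample(frac=1.0, random_state=5)
        fit2 = ldsc.stratified_regression(perm, ld, n_jackknife_blocks=20)
        assert np.allclose(
            fit1.table["tau_hat"].to_numpy(), fit2.table["tau_hat"].to_numpy()
        )

    def test_jackknife_se_close_to_analytic_ols_se(self):
        """Homoskedastic noise: jackknife SE within 10% of the OLS SE."""
        panel = synthio.simulate_ld_panel(20_000, 200, 0.0, seed=7)
        rng = np.random.default_rng(8)
        ann = pd.DataFrame({"a": (rng.random(20_000) < 0.5).astype(float)},
                           index=panel.variants["SNP"].to_numpy())
        ld = ldsc.compute_ld_scores(panel, ann)
        ss = panel.variants[["SNP"]].copy()
        ss["N"] = 10_000
        y = 1.0 + rng.normal(0.0, 1.0, 20_000)
        ss["chi2"] = y
        fit = ldsc.stratified_regression(ss, ld, n_jackknife_blocks=200)
        X = np.column_stack([np.ones(20_000), 10_000 * ld["a"].to_numpy()])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        sigma2 = resid @ resid / (20_000 - 2)
        se_ols = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(fit.table["se"].iloc[0] - se_ols) / se_ols < 0.10

    def test_collinear_columns_trigger_ridge_flag(self):
        _, _, ld, ss, _ = self._noiseless()
        ld2 = ld.copy()
        ld2["a2"] = ld2["a1"]  # exact collinearity
        with pytest.warns(UserWarning, match="collinear"):
            fit = ldsc.stratified_regression(ss, ld2, n_jackknife_blocks=20)
        assert fit.ridge_fallback

    def test_constant_column_absorbed_by_intercept(self):
        _, _, ld, ss, _ = self._noiseless()
        ld2 = ld.copy()
        ld2["const"] = 1.0
        fit = ldsc.stratified_regression(ss, ld2, n_jackknife_blocks=20)
        row = fit.table.set_index("annotation").loc["const"]
        assert bool(row["absorbed"]) and np.isnan(row["tau_hat"])


class TestCelltypeScan:
    def test_single_cluster_family_q_equals_p(self, small_panel, all_ones_annotation):
        ss = synthio.simulate_gwas_sumstats(small_panel, all_ones_annotation, {"all": 0.0}, 5_000, seed=1)
        ss["chi2"] = ss["Z"] ** 2
        rng = np.random.default_rng(2)
        ann = pd.DataFrame({"c1": (rng.random(small_panel.n_variants) < 0.3).astype(float)},
                           index=small_panel.variants["SNP"].to_numpy())
        scan = ldsc.celltype_heritability_scan(ss, small_panel, ann, n_jackknife_blocks=20)
        assert scan["q_fdr"].iloc[0] == pytest.approx(scan["p_one_sided"].iloc[0])

    def test_fdr_families_are_separate(self, small_panel, all_ones_annotation):
        ss = synthio.simulate_gwas_sumstats(small_panel, all_ones_annotation, {"all": 0.0}, 5_000, seed=3)
        ss["chi2"] = ss["Z"] ** 2
        rng = np.random.default_rng(4)
        ann = pd.DataFrame(
            {f"c{i}": (rng.random(small_panel.n_variants) < 0.3).astype(float) for i in range(4)},
            index=small_panel.variants["SNP"].to_numpy(),
        )
        fam = {"c0": "f1", "c1": "f1", "c2": "f2", "c3": "f2"}
        scan = ldsc.celltype_heritability_scan(
            ss, small_panel, ann, families=fam, n_jackknife_blocks=20
        )
        from paincell.enrich import bh_fdr

        for f in ("f1", "f2"):
            sub = scan[scan["family"] == f]
            assert np.allclose(sub["q_fdr"].to_numpy(), bh_fdr(sub["p_one_sided"].to_numpy()))

    def test_planted_cluster_detected(self, small_study):
        from paincell import specificity

        logged = specificity.transform_and_aggregate(small_study["adata"])
        spec = specificity.specificity_regression(logged, small_study["covariates"])
        top = specificity.top_k_gene_sets(spec, k=30)
        ss, _ = ldsc.harmonize_and_filter_sumstats(small_study["sumstats"])
        annots = ldsc.build_snp_annotations(
            small_study["panel"].variants, gene_sets=top,
            gene_coords=small_study["gene_coords"], window_kb=0.0, add_baseline=False,
        )
        scan = ldsc.celltype_heritability_scan(
            ss, small_study["panel"], annots, n_jackknife_blocks=60
        )
        best = scan.sort_values("p_one_sided").iloc[0]
        assert best["cluster"] == small_study["truth"].enriched_cluster_ids[0]

    def test_empty_annotation_set_rejected(self, small_panel, all_ones_annotation):
        ss = synthio.simulate_gwas_sumstats(small_panel, all_ones_annotation, {"all": 0.0}, 5_000, seed=1)
        ss["chi2"] = ss["Z"] ** 2
        empty = pd.DataFrame(index=small_panel.variants["SNP"].to_numpy())
        with pytest.raises(ValueError):
            ldsc.celltype_heritability_scan(ss, small_panel, empty)
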