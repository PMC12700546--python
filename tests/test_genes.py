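"""Gene-level statistics: mapping, LD-aware association, property scan,
heritability, and pre-ranked GSEA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paincell import genes, synthio
from paincell.genes import quadform_sf


def _sumstats(positions, zscores, chrom=1, N=10_000):
    return pd.DataFrame({
        "SNP": [f"v{i}" for i in range(len(positions))],
        "CHR": chrom, "BP": positions, "N": N,
        "Z": zscores, "chi2": np.asarray(zscores, dtype=float) ** 2,
    })


class TestMapping:
    def test_boundary_inclusion_one_based(self):
        ss = _sumstats([100, 200, 201], [1, 1, 1])
        coords = pd.DataFrame({"gene": ["g"], "chrom": [1], "start": [100], "end": [200]})
        mapping, _ = genes.map_snps_to_genes(ss, coords)
        assert mapping["g"] == ["v0", "v1"]

    def test_mhc_genes_dropped_when_flagged(self):
        ss = _sumstats([26_000_000], [1], chrom=6)
        coords = pd.DataFrame({"gene": ["mhc_gene"], "chrom": [6],
                               "start": [25_900_000], "end": [26_100_000]})
        mapping, report = genes.map_snps_to_genes(ss, coords, drop_mhc_genes=True)
        assert "mhc_gene" not in mapping and report["n_mhc"] == 1
        mapping2, _ = genes.map_snps_to_genes(ss, coords, drop_mhc_genes=False)
        assert mapping2["mhc_gene"] == ["v0"]

    def test_matches_brute_force_interval_oracle(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(np.arange(1, 10_000), size=12, replace=False))
        ss = _sumstats(pos, np.ones(12))
        coords = pd.DataFrame({
            "gene": [f"g{i}" for i in range(5)],
            "chrom": 1,
            "start": rng.integers(1, 8_000, 5),
        })
        coords["end"] = coords["start"] + rng.integers(100, 3_000, 5)
        up = down = 0.5  # kb
        mapping, _ = genes.map_snps_to_genes(ss, coords, window_up_kb=up, window_down_kb=down)
        oracle = {}
        for _, g in coords.iterrows():
            hits = [f"v{j}" for j, p in enumerate(pos)
                    if g["start"] - up * 1000 <= p <= g["end"] + down * 1000]
            if hits:
                oracle[g["gene"]] = hits
        assert {k: sorted(v) for k, v in mapping.items()} == {k: sorted(v) for k, v in oracle.items()}

    def test_nonunique_names_removed(self):
        ss = _sumstats([100, 5000], [1, 1])
        coords = pd.DataFrame({"gene": ["dup", "dup"], "chrom": [1, 1],
                               "start": [50, 4000], "end": [150, 6000]})
        mapping, report = genes.map_snps_to_genes(ss, coords)
        assert mapping == {} and report["n_nonunique"] == 1


class TestGeneAssociation:
    def test_single_snp_gene_p_equals_snp_two_sided_p(self):
        z = 2.3
        ss = _sumstats([100], [z])
        out = genes.gene_association(ss, {"g": ["v0"]}, panel=None)
        assert out["p"].iloc[0] == pytest.approx(2 * stats.norm.sf(z), rel=1e-10)

    def test_independent_snps_match_exact_chi2_sum_tail(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=6)
        ss = _sumstats(np.arange(1, 7) * 100, z)
        out = genes.gene_association(ss, {"g": [f"v{i}" for i in range(6)]}, panel=None)
        exact = stats.chi2.sf((z**2).sum(), 6)
        assert out["p"].iloc[0] == pytest.approx(exact, rel=1e-8)
        assert out["stat"].iloc[0] == pytest.approx((z**2).mean())

    @pytest.mark.parametrize("r", [0.0, 0.5, 0.9])
    def test_null_tail_matches_monte_carlo(self, r):
        """Approximate p at the ~0.01 tail within 10% of Monte Carlo."""
        m, ndraw = 5, 200_000
        R = (1 - r) * np.eye(m) + r * np.ones((m, m))
        lam = np.linalg.eigvalsh(R)
        rng = np.random.default_rng(int(10 * r))
        Z = rng.standard_normal((ndraw, m)) @ np.linalg.cholesky(R + 1e-12 * np.eye(m)).T
        sums = (Z**2).sum(axis=1)
        from scipy.optimize import brentq

        thr = brentq(lambda q: quadform_sf(q, lam) - 0.01, 1.0, 500.0)
        emp = (sums >= thr).mean()
        assert abs(emp - 0.01) / 0.01 < 0.10

    def test_type_one_error_calibrated(self):
        """Rejection rate at alpha=0.05 in [0.04, 0.06] for null genes."""
        m = 4
        for r in (0.0, 0.5):
            R = (1 - r) * np.eye(m) + r * np.ones((m, m))
            lam = np.linalg.eigvalsh(R)
            rng = np.random.default_rng(int(100 * r) + 3)
            Z = rng.standard_normal((10_000, m)) @ np.linalg.cholesky(R + 1e-12 * np.eye(m)).T
            sums = (Z**2).sum(axis=1)
            from scipy.optimize import brentq

            thr = brentq(lambda q: quadform_sf(q, lam) - 0.05, 1.0, 500.0)
            rate = (sums >= thr).mean()
            assert 0.04 <= rate <= 0.06

    def test_missing_panel_variants_fall_back_to_independence(self, small_panel):
        ss = _sumstats([100, 200], [1.0, 2.0])
        with pytest.warns(UserWarning, match="missing from the LD panel"):
            out = genes.gene_association(ss, {"g": ["v0", "v1"]}, panel=small_panel)
        exact = stats.chi2.sf(5.0, 2)
        assert out["p"].iloc[0] == pytest.approx(exact, rel=1e-8)


class TestPropertyScan:
    def _inputs(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        gene_ids = [f"g{i}" for i in range(n)]
        spec_t = pd.DataFrame({"c1": rng.normal(size=n)}, index=gene_ids)
        avg = pd.Series(rng.normal(size=n), index=gene_ids, name="avg")
        avg = avg - avg.mean()
        # orthogonalize average expression against specificity
        s = spec_t["c1"].to_numpy()
        a = avg.to_numpy()
        avg = pd.Series(a - (a @ s) / (s @ s) * s, index=gene_ids)
        return gene_ids, spec_t, avg

    def test_constructed_linear_signal_recovered_exactly(self):
        gene_ids, spec_t, avg = self._inputs()
        z = 0.5 * spec_t["c1"].to_numpy()
        assoc = pd.DataFrame({"gene": gene_ids, "n_snps": 1, "stat": 1.0,
                              "p": 0.5, "z": z})
        out = genes.gene_property_scan(assoc, spec_t, avg)
        assert out["beta_property"].iloc[0] == pytest.approx(0.5, abs=1e-8)

    def test_null_beta_near_zero(self):
        gene_ids, spec_t, avg = self._inputs(seed=2)
        rng = np.random.default_rng(3)
        assoc = pd.DataFrame({"gene": gene_ids, "n_snps": 1, "stat": 1.0,
                              "p": 0.5, "z": rng.normal(size=len(gene_ids))})
        out = genes.gene_property_scan(assoc, spec_t, avg)
        assert abs(out["beta_property"].iloc[0]) < 3.0 * out["se"].iloc[0] + 0.2

    def test_collinear_specificity_flagged(self):
        gene_ids, spec_t, _ = self._inputs()
        avg = pd.Series(2.0 * spec_t["c1"].to_numpy(), index=gene_ids)
        assoc = pd.DataFrame({"gene": gene_ids, "n_snps": 1, "stat": 1.0,
                              "p": 0.5, "z": spec_t["c1"].to_numpy()})
        out = genes.gene_property_scan(assoc, spec_t, avg)
        assert out["flag"].iloc[0] == "collinear_or_undefined"
        assert np.isnan(out["beta_property"].iloc[0])

    def test_too_few_genes_rejected(self):
        gene_ids, spec_t, avg = self._inputs(n=20)
        assoc = pd.DataFrame({"gene": gene_ids, "n_snps": 1, "stat": 1.0,
                              "p": 0.5, "z": np.zeros(20)})
        with pytest.raises(ValueError, match="overlapping genes"):
            genes.gene_property_scan(assoc, spec_t, avg)


class TestGeneHeritability:
    def test_null_gene_calibration(self, small_panel, all_ones_annotation):
        h2s, ps = [], []
        mapping = {}
        snp_ids = small_panel.variants["SNP"].tolist()
        for g in range(200):
            mapping[f"g{g}"] = snp_ids[g * 10 : g * 10 + 10]
        ss = synthio.simulate_gwas_sumstats(
            small_panel, all_ones_annotation, {"all": 0.0}, 10_000, seed=21
        )
        out = genes.gene_heritability_test(ss, mapping, small_panel)
        raw = np.where(out["h2_truncated"], -1e-9, out["h2_gene"])  # sign only
        # mean raw h2 ~ 0: truncation means ~half the genes are flagged
        assert 0.25 < out["h2_truncated"].mean() < 0.75
        ks = stats.kstest(out["p"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_planted_gene_h2_matches_expectation(self):
        """Independent SNPs with E[chi2 - 1] = 4 each: h2 ~ m*4/N."""
        m, N, n_rep = 8, 10_000, 200
        rng = np.random.default_rng(6)
        h2s = []
        for _ in range(n_rep):
            z = rng.normal(0.0, np.sqrt(5.0), size=m)  # chi2 mean 5
            ss = _sumstats(np.arange(1, m + 1) * 100, z, N=N)
            out = genes.gene_heritability_test(ss, {"g": [f"v{i}" for i in range(m)]}, None)
            h2s.append(out["h2_gene"].iloc[0])
        expected = m * 4.0 / N
        mc_se = np.std(h2s) / np.sqrt(n_rep)
        assert abs(np.mean(h2s) - expected) < 2 * mc_se + 1e-5

    def test_unmapped_genes_reported_not_p1(self):
        ss = _sumstats([100], [1.0])
        out = genes.gene_heritability_test(ss, {"g1": ["v0"], "g2": ["absent"]}, None)
        assert list(out["gene"]) == ["g1"]
        assert out.attrs["n_genes_without_snps"] == 1


class TestPrerankedGsea:
    def _ranking(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        vals = np.sort(rng.normal(size=n))[::-1]
        return pd.Series(vals, index=[f"g{i}" for i in range(n)])

    def test_top_block_set_is_extreme(self):
        ranking = self._ranking(2_000)
        sets = {"top": [f"g{i}" for i in range(50)]}
        out = genes.preranked_gsea(ranking, sets, n_permutations=200, seed=1)
        assert out["es"].iloc[0] > 0
        assert out["p_perm"].iloc[0] <= 2.0 / 201

    def test_es_bounded_by_one(self):
        ranking = self._ranking()
        rng = np.random.default_rng(2)
        sets = {f"s{i}": list(rng.choice(ranking.index, 30, replace=False)) for i in range(5)}
        out = genes.preranked_gsea(ranking, sets, n_permutations=100, seed=0)
        assert (out["es"].abs() <= 1.0).all()

    def test_seed_determinism(self):
        ranking = self._ranking()
        sets = {"s": list(ranking.index[:25])}
        a = genes.preranked_gsea(ranking, sets, n_permutations=150, seed=7)
        b = genes.preranked_gsea(ranking, sets, n_permutations=150, seed=7)
        assert a["p_perm"].iloc[0] == b["p_perm"].iloc[0]

    def test_rank_weights_invariant_under_monotone_transform(self):
        ranking = self._ranking()
        sets = {"s": list(ranking.index[10:40])}
        a = genes.preranked_gsea(ranking, sets, 100, seed=3, weight_mode="rank")
        monotone = pd.Series(np.exp(ranking.to_numpy() / 2), index=ranking.index)
        b = genes.preranked_gsea(monotone, sets, 100, seed=3, weight_mode="rank")
        assert a["es"].iloc[0] == pytest.approx(b["es"].iloc[0])
        assert a["p_perm"].iloc[0] == b["p_perm"].iloc[0]

    def test_set_outside_universe_rejected(self):
        ranking = self._ranking()
        with pytest.raises(ValueError, match="outside the ranked universe"):
            genes.preranked_gsea(ranking, {"bad": ["nope"]}, 100, seed=0)
        with pytest.raises(ValueError, match="100 permutations"):
            genes.preranked_gsea(ranking, {"s": [ranking.index[0]]}, 10, seed=0)
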