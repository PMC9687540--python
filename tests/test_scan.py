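"""Whole-genome scanning: EMMAX pass, refinement, thresholds, GC lambda."""

import numpy as np
import pytest
from scipy import stats

import genegwas as g
from genegwas.scan import GeneScanRecord, ScanResult


@pytest.fixture(scope="module")
def scan_setup():
    """Simulated panel + blocks + spectral kinship + polygenic phenotype."""
    cfg = g.SimConfig(n_individuals=150, n_genes=100, seed=17)
    panel, catalog = g.simulate_genotype_panel(cfg)
    panel = g.filter_by_maf(panel, 0.05)
    blocks = g.filter_genes_by_snp_count(
        g.assign_snps_to_genes(panel, catalog), 5)
    spectral = g.spectral_decompose(g.compute_rrm(panel))
    pheno = g.simulate_polygenic_phenotype(panel, spectral, 0.5, seed=18)
    return panel, catalog, blocks, spectral, pheno


class TestEmmaxScan:
    def test_all_genes_present_with_valid_p(self, scan_setup):
        panel, _, blocks, spectral, pheno = scan_setup
        records, skipped = g.emmax_scan(panel, blocks, pheno.values, spectral,
                                        "EPC", h2_fixed=0.5)
        assert len(records) == len(blocks)
        assert not skipped
        p = np.array([r.p for r in records])
        assert np.all((p > 0) & (p <= 1))
        assert all(r.mode == "emmax" for r in records)

    def test_degenerate_gene_goes_to_skip_log(self, scan_setup):
        panel, _, blocks, spectral, pheno = scan_setup
        # fabricate a block over SNPs forced monomorphic
        panel2 = g.GenotypePanel(
            sample_ids=panel.sample_ids, snp_ids=panel.snp_ids,
            chrom=panel.chrom, pos=panel.pos, dosage=panel.dosage.copy())
        bad = blocks[0]
        panel2.dosage[:, bad.snp_indices] = 2.0
        records, skipped = g.emmax_scan(panel2, blocks[:3], pheno.values,
                                        spectral, "EPC", h2_fixed=0.5)
        assert bad.gene_id in {gid for gid, _ in skipped}
        assert bad.gene_id not in {r.gene_id for r in records}

    def test_matches_gene_at_a_time_fit(self, scan_setup):
        """No cross-gene leakage: scan p equals an isolated fit's p."""
        panel, _, blocks, spectral, pheno = scan_setup
        h2 = 0.37
        records, _ = g.emmax_scan(panel, blocks[:10], pheno.values, spectral,
                                  "EPC", h2_fixed=h2)
        for rec, block in zip(records, blocks[:10]):
            design = g.build_gene_design(block, panel, "EPC")
            ystar, xstar, w = g.whiten(pheno.values, design.columns,
                                       spectral, h2)
            fit = g.barebones_fit(ystar, xstar, w, h2)
            assert rec.p == pytest.approx(fit.p, rel=1e-10)


class TestRefineScan:
    def test_screen_alpha_one_refines_everything(self, scan_setup):
        panel, _, blocks, spectral, pheno = scan_setup
        records, _ = g.emmax_scan(panel, blocks[:20], pheno.values, spectral,
                                  "EPC", h2_fixed=0.5)
        refined = g.refine_scan(records, 1.0, pheno.values, spectral, panel,
                                blocks[:20], h2_upper=0.5)
        assert all(r.mode == "refined" for r in refined)
        assert all(r.h2_used <= 0.5 + 1e-9 for r in refined)

    def test_tiny_screen_alpha_refines_nothing(self, scan_setup):
        panel, _, blocks, spectral, pheno = scan_setup
        records, _ = g.emmax_scan(panel, blocks[:20], pheno.values, spectral,
                                  "EPC", h2_fixed=0.5)
        out = g.refine_scan(records, 1e-300, pheno.values, spectral, panel,
                            blocks[:20], h2_upper=0.5)
        assert out == records

    def test_refined_likelihood_dominates_emmax(self, scan_setup):
        panel, _, blocks, spectral, pheno = scan_setup
        records, _ = g.emmax_scan(panel, blocks[:20], pheno.values, spectral,
                                  "EPC", h2_fixed=0.5)
        refined = g.refine_scan(records, 1.0, pheno.values, spectral, panel,
                                blocks[:20], h2_upper=0.5)
        for before, after in zip(records, refined):
            assert after.neg2logL <= before.neg2logL + 1e-6

    def test_two_round_count_guarantee(self, scan_setup):
        """Number of refits equals number of screened genes."""
        panel, _, blocks, spectral, pheno = scan_setup
        records, _ = g.emmax_scan(panel, blocks, pheno.values, spectral,
                                  "EPC", h2_fixed=0.5)
        alpha = 0.10
        n_screened = sum(r.p <= alpha for r in records)
        refined = g.refine_scan(records, alpha, pheno.values, spectral,
                                panel, blocks, h2_upper=0.5)
        assert sum(r.mode == "refined" for r in refined) == n_screened


class TestRunGeneGwas:
    def test_one_record_per_surviving_gene(self, scan_setup):
        panel, catalog, blocks, _, pheno = scan_setup
        res = g.run_gene_gwas(panel, catalog, pheno, "epc",
                              g.ScanConfig(min_snps=5))
        assert res.n_genes_tested == len(res.records)
        assert len({r.gene_id for r in res.records}) == len(res.records)

    def test_phenotype_order_invariance(self, scan_setup):
        panel, catalog, _, _, pheno = scan_setup
        res1 = g.run_gene_gwas(panel, catalog, pheno, "fpc",
                               g.ScanConfig(min_snps=5, mode="emmax"))
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(pheno))
        shuffled = g.PhenotypeVector(pheno.sample_ids[perm],
                                     pheno.values[perm], pheno.trait_name)
        res2 = g.run_gene_gwas(panel, catalog, shuffled, "fpc",
                               g.ScanConfig(min_snps=5, mode="emmax"))
        p1 = res1.pvalues()
        p2 = res2.pvalues()
        assert np.allclose(p1, p2, atol=1e-10)

    def test_fpc_df_beta_all_one(self, scan_setup):
        panel, catalog, _, _, pheno = scan_setup
        res = g.run_gene_gwas(panel, catalog, pheno, "fpc",
                              g.ScanConfig(min_snps=5, mode="emmax"))
        assert all(r.df_beta == 1 for r in res.records)

    def test_too_few_shared_samples_raises(self, scan_setup):
        panel, catalog, _, _, pheno = scan_setup
        lonely = g.PhenotypeVector(["nobody"], [1.0], "t")
        with pytest.raises(g.GeneGwasError, match="sample"):
            g.run_gene_gwas(panel, catalog, lonely, "epc")


class TestThresholdsAndLambda:
    def test_bonferroni_paper_scale_values(self):
        assert g.bonferroni_threshold(16893, 0.05) == pytest.approx(5.529,
                                                                    abs=5e-4)
        assert g.bonferroni_threshold(24594, 0.05) == pytest.approx(5.692,
                                                                    abs=5e-4)
        assert g.bonferroni_threshold(1, 0.05) == pytest.approx(1.301,
                                                                abs=5e-4)

    def test_bonferroni_domain(self):
        with pytest.raises(ValueError):
            g.bonferroni_threshold(0, 0.05)
        with pytest.raises(ValueError):
            g.bonferroni_threshold(10, 1.5)

    def test_lambda_definitional_half(self):
        assert g.genomic_control_lambda(np.full(101, 0.5)) == pytest.approx(
            1.0, abs=1e-12)

    def test_lambda_near_one_for_uniform(self):
        rng = np.random.default_rng(19)
        p = rng.uniform(size=10_000)
        assert 0.95 <= g.genomic_control_lambda(p) <= 1.05

    def test_halving_p_inflates_lambda(self):
        rng = np.random.default_rng(20)
        p = rng.uniform(size=2000)
        assert (g.genomic_control_lambda(p / 2)
                > g.genomic_control_lambda(p))

    def test_lambda_rejects_bad_input(self):
        with pytest.raises(ValueError):
            g.genomic_control_lambda(np.array([]))
        with pytest.raises(ValueError):
            g.genomic_control_lambda(np.array([0.0, 0.5]))


class TestQqPoints:
    def test_single_point(self):
        exp, obs = g.qq_points(np.array([0.3]))
        assert exp[0] == pytest.approx(-np.log10(0.5))
        assert obs[0] == pytest.approx(-np.log10(0.3))

    def test_length_preserved(self):
        rng = np.random.default_rng(21)
        p = rng.uniform(size=137)
        exp, obs = g.qq_points(p)
        assert len(exp) == len(obs) == 137

    def test_uniform_near_diagonal(self):
        rng = np.random.default_rng(22)
        p = rng.uniform(size=5000)
        exp, obs = g.qq_points(p)
        # ignore the extreme tail where order statistics are noisy
        body = exp < 2.5
        assert np.abs(exp[body] - obs[body]).max() < 0.25


def _mk_result(gene_ids, neg_log10s):
    records = [
        GeneScanRecord(gene_id=gid, chrom="1", start=1, end=2, n_snps=10,
                       df_beta=2, h2_used=0.5, beta_norm=1.0, sigma2e=1.0,
                       F=1.0, p=10 ** -nl, neg_log10_p=nl, neg2logL=0.0,
                       method="EPC", mode="emmax")
        for gid, nl in zip(gene_ids, neg_log10s)
    ]
    return ScanResult(records=records, genomic_h2=0.5,
                      n_genes_tested=len(records), bonferroni_neg_log10=2.0,
                      gc_lambda=1.0)


class TestSharedQtgTable:
    def test_single_shared_gene(self):
        res = {
            "oil": _mk_result(["a", "b"], [3.0, 1.0]),
            "dts": _mk_result(["a", "c"], [4.0, 5.0]),
        }
        table = g.shared_qtg_table(res, threshold=2.0)
        assert len(table) == 1
        assert table.iloc[0]["gene_id"] == "a"
        assert table.iloc[0]["traits"] == "dts,oil"

    def test_disjoint_sets_empty(self):
        res = {
            "t1": _mk_result(["a"], [3.0]),
            "t2": _mk_result(["b"], [3.0]),
        }
        assert len(g.shared_qtg_table(res, 2.0)) == 0

    def test_trait_order_invariance(self):
        r1 = _mk_result(["a", "b"], [3.0, 3.0])
        r2 = _mk_result(["a", "b"], [3.0, 1.0])
        t_fwd = g.shared_qtg_table({"x": r1, "y": r2}, 2.0)
        t_rev = g.shared_qtg_table({"y": r2, "x": r1}, 2.0)
        assert t_fwd.equals(t_rev)

    def test_needs_two_traits(self):
        with pytest.raises(g.GeneGwasError):
            g.shared_qtg_table({"only": _mk_result(["a"], [3.0])}, 2.0)


class TestFilterSummary:
    def test_percent_values(self):
        assert g.snp_retention_percent(347_481, 681_258) == pytest.approx(
            51.01, abs=0.005)
        assert g.snp_retention_percent(932_712, 1_250_000) == pytest.approx(
            74.6, abs=0.05)

    def test_formatted_line(self):
        line = g.format_filter_summary(347_481, 681_258)
        assert "51.01%" in line and "347,481" in line
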