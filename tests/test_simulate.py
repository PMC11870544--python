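import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from stimqtl import simulate as sim


class TestGenotypes:
    def test_hwe_mean_dosage(self):
        d = sim.SimDesign(n_donors=10_000, n_snps=40, n_genes=5, n_peaks=5,
                          maf_range=(0.5, 0.5), ld_rho=0.0, seed=1)
        gm = sim.simulate_genotypes(d)
        assert abs(gm.dosage.mean() - 1.0) < 0.02

    def test_zero_ld_gives_independent_neighbours(self):
        d = sim.SimDesign(n_donors=10_000, n_snps=20, n_genes=5, n_peaks=5,
                          ld_rho=0.0, seed=2)
        gm = sim.simulate_genotypes(d)
        X = gm.dosage.astype(float)
        for j in range(5):
            r = np.corrcoef(X[:, j], X[:, j + 1])[0, 1]
            assert abs(r) < 0.05

    def test_ld_matches_copula_monte_carlo_oracle(self):
        """Adjacent-dosage correlation vs a brute-force draw from the same
        thresholded bivariate Gaussian (the generator's declared model)."""
        rho, maf = 0.9, 0.3
        rng = np.random.default_rng(0)
        n_mc = 1_000_000
        x1 = rng.standard_normal(n_mc)
        x2 = rho * x1 + np.sqrt(1 - rho**2) * rng.standard_normal(n_mc)
        y1 = rho * x1 + np.sqrt(1 - rho**2) * rng.standard_normal(n_mc)
        y2 = rho * y1 + np.sqrt(1 - rho**2) * rng.standard_normal(n_mc)
        thr = stats.norm.ppf(maf)
        # oracle haplotype pairs -> dosage correlation; two haplotypes per
        # donor, so use half the draws per haplotype
        half = n_mc // 2
        d1 = (x1[:half] < thr).astype(int) + (x1[half:] < thr).astype(int)
        d2 = (x2[:half] < thr).astype(int) + (x2[half:] < thr).astype(int)
        r_oracle = np.corrcoef(d1, d2)[0, 1]

        d = sim.SimDesign(n_donors=10_000, n_snps=20, n_genes=5, n_peaks=5,
                          ld_rho=rho, maf_range=(maf, maf), seed=3)
        gm = sim.simulate_genotypes(d)
        X = gm.dosage.astype(float)
        rs = [np.corrcoef(X[:, j], X[:, j + 1])[0, 1] for j in range(10)]
        assert abs(np.mean(rs) - r_oracle) < 0.03

    def test_deterministic_under_seed(self):
        d = sim.SimDesign(n_donors=20, n_snps=50, n_genes=5, n_peaks=5,
                          seed=9)
        a = sim.simulate_genotypes(d)
        b = sim.simulate_genotypes(d)
        np.testing.assert_array_equal(a.dosage, b.dosage)


class TestCells:
    def test_cell_count_is_product(self):
        d = sim.SimDesign(n_donors=24, n_snps=10, n_genes=5, n_peaks=5,
                          cells_per_donor_context=50, seed=4)
        cells = sim.simulate_cells(d)
        assert len(cells) == 24 * 9 * 50

    def test_pseudotime_ordered_by_time_point(self):
        d = sim.SimDesign(n_donors=24, n_snps=10, n_genes=5, n_peaks=5,
                          cells_per_donor_context=50, seed=4)
        cells = sim.simulate_cells(d)
        means = cells.groupby("time")["pseudotime"].mean()
        assert means["0h"] < means["1h"] < means["6h"]

    def test_byte_identical_under_seed(self):
        d = sim.SimDesign(n_donors=6, n_snps=10, n_genes=5, n_peaks=5,
                          seed=5)
        a = sim.simulate_cells(d)
        b = sim.simulate_cells(d)
        pd.testing.assert_frame_equal(a, b)


class TestExpression:
    def test_nb_mean_identity_without_effects(self):
        """With no donor effects, no modules and beta = 0 the per-gene mean
        count matches exp(mu) x E[size factor] within 3 SE."""
        d = sim.SimDesign(n_donors=100, n_snps=20, n_genes=30, n_peaks=5,
                          cells_per_donor_context=40, donor_sd=0.0,
                          module_spec=[], base_log_sd=0.5, seed=6)
        gm = sim.simulate_genotypes(d)
        cells = sim.simulate_cells(d)
        expr, _, _ = sim.simulate_expression(gm, cells, d)
        counts = expr.counts.toarray()
        n_cells = counts.shape[0]
        # reconstruct mu_g from the generator's own stream contract
        rng = np.random.default_rng([d.seed, 3])
        mu = rng.normal(d.base_log_mean, d.base_log_sd, size=d.n_genes)
        expected = np.exp(mu) * np.exp(d.size_factor_sd**2 / 2)
        observed = counts.mean(axis=0)
        se = counts.std(axis=0) / np.sqrt(n_cells)
        frac_ok = np.mean(np.abs(observed - expected) < 3 * se + 1e-9)
        assert frac_ok > 0.9

    def test_planted_effect_is_context_specific(self):
        d = sim.SimDesign(n_donors=60, n_snps=300, n_genes=30, n_peaks=30,
                          seed=7)
        lay = sim.layout(d)
        g = lay.genes[0]
        snp = next(s.id for s in lay.snp_meta
                   if abs(s.pos - g.tss) < 100_000)
        d.qtl_spec = [sim.PlantedQtl(feature=g.id, snp=snp, beta=1.0,
                                     contexts=["npglut_1h"])]
        gm = sim.simulate_genotypes(d)
        cells = sim.simulate_cells(d)
        expr, _, _ = sim.simulate_expression(gm, cells, d)
        counts = expr.counts.toarray()[:, 0]
        dosage = gm.dosage[:, gm.snp_idx(snp)]
        donor_idx = cells["donor_id"].map(
            {dn: i for i, dn in enumerate(gm.donors)}).to_numpy()
        gvec = dosage[donor_idx]
        ctx = (cells["cell_type"] + "_" + cells["time"]).to_numpy()

        def effect_z(label):
            m = ctx == label
            lo, hi = counts[m & (gvec == 0)], counts[m & (gvec == 2)]
            se = np.sqrt(lo.var() / len(lo) + hi.var() / len(hi))
            return (hi.mean() - lo.mean()) / se

        assert effect_z("npglut_1h") > 3
        assert abs(effect_z("npglut_0h")) < 3

    def test_poisson_limit_variance(self):
        d = sim.SimDesign(n_donors=50, n_snps=10, n_genes=20, n_peaks=5,
                          cells_per_donor_context=40, donor_sd=0.0,
                          module_spec=[], nb_dispersion=None,
                          size_factor_sd=0.0, seed=8)
        gm = sim.simulate_genotypes(d)
        cells = sim.simulate_cells(d)
        expr, _, _ = sim.simulate_expression(gm, cells, d)
        counts = expr.counts.toarray()
        ratio = counts.var(axis=0) / counts.mean(axis=0)
        assert np.median(np.abs(ratio - 1.0)) < 0.1


class TestAccessibilityPriming:
    def test_peak_leads_gene_at_one_hour(self):
        """Primed chromatin: sustained peaks are open by 1h while their
        late-module genes remain near baseline at 1h."""
        d = sim.SimDesign(
            n_donors=40, n_snps=100, n_genes=60, n_peaks=60,
            module_spec=[sim.ModuleSpec("late_genes", "late", 40,
                                        amplitude=1.5)],
            seed=9)
        d.peak_module_spec = [sim.ModuleSpec("primed", "sustained", 40,
                                             amplitude=1.5)]
        gm = sim.simulate_genotypes(d)
        cells = sim.simulate_cells(d)
        expr, _, _ = sim.simulate_expression(gm, cells, d)
        atac, _, _ = sim.simulate_accessibility(gm, cells, d)
        t = cells["time"].to_numpy()
        e = expr.counts.toarray()[:, :40].mean(axis=1)
        a = atac.counts.toarray()[:, :40].mean(axis=1)
        peak_rise = a[t == "1h"].mean() / a[t == "0h"].mean()
        gene_rise = e[t == "1h"].mean() / e[t == "0h"].mean()
        gene_rise_6h = e[t == "6h"].mean() / e[t == "0h"].mean()
        assert peak_rise > 1.5
        assert gene_rise < peak_rise * 0.75
        assert gene_rise_6h > gene_rise  # the gene catches up later

    def test_null_caqtl_pvalues_uniform(self):
        """Without planted effects, donor-level genotype association
        p-values at peak pseudobulk are uniform."""
        from stimqtl import qtl as sq

        d = sim.SimDesign(n_donors=40, n_snps=600, n_genes=5, n_peaks=500,
                          seed=10)
        gm = sim.simulate_genotypes(d)
        cells = sim.simulate_cells(d)
        atac, _, _ = sim.simulate_accessibility(gm, cells, d)
        pb = sq.pseudobulk(atac, cells, min_cells=5)
        lay = sim.layout(d)
        res = sq.map_qtl(pb, gm, lay.peaks, "GABA_0h", n_genotype_pcs=0,
                         n_phenotype_pcs=0)
        # one p per feature-SNP pair; under the null these are uniform
        ks = stats.kstest(res.full["p"], "uniform")
        assert ks.pvalue > 0.01


class TestAlleleCounts:
    def _design(self, beta, seed=11):
        d = sim.SimDesign(n_donors=40, n_snps=120, n_genes=5, n_peaks=100,
                          asoc_depth_factor=2.0, seed=seed)
        lay = sim.layout(d)
        spec = []
        for pk in lay.peaks[:40]:
            s = sim.snp_in_peak(lay, pk.id)
            if s is not None:
                spec.append(sim.PlantedQtl(feature=pk.id, snp=s, beta=beta,
                                           contexts="all"))
        d.caqtl_spec = spec
        return d

    def _run(self, d):
        gm = sim.simulate_genotypes(d)
        cells = sim.simulate_cells(d)
        atac, _, _ = sim.simulate_accessibility(gm, cells, d)
        table, truth = sim.simulate_allele_counts(gm, atac, cells, d)
        return gm, table, truth

    def test_balanced_when_no_effect(self):
        gm, table, _ = self._run(self._design(beta=0.0))
        frac = table["alt_count"].sum() / (table["alt_count"].sum()
                                           + table["ref_count"].sum())
        n = table[["ref_count", "alt_count"]].to_numpy().sum()
        assert n > 1e4
        assert abs(frac - 0.5) < 0.01

    def test_planted_imbalance_recovered(self):
        target = 0.7
        beta = float(np.log(target / (1 - target)))  # kappa = 1
        gm, table, truth = self._run(self._design(beta=beta))
        frac = table["alt_count"].sum() / (table["alt_count"].sum()
                                           + table["ref_count"].sum())
        assert abs(frac - target) < 0.02
        assert np.allclose(truth["alt_fraction"], target)

    def test_homozygous_donors_emit_no_rows(self):
        gm, table, _ = self._run(self._design(beta=0.0))
        snp_idx = {s.id: j for j, s in enumerate(gm.snps)}
        donor_idx = {dn: i for i, dn in enumerate(gm.donors)}
        for r in table.itertuples(index=False):
            assert gm.dosage[donor_idx[r.donor], snp_idx[r.snp]] == 1


class TestGwas:
    def test_null_z_marginally_standard(self):
        d = sim.SimDesign(n_donors=200, n_snps=2000, n_genes=5, n_peaks=5,
                          seed=12)
        gm = sim.simulate_genotypes(d)
        gwas, truth = sim.simulate_gwas(gm, d)
        assert truth.empty
        assert abs(gwas.z.mean()) < 0.05
        assert abs(gwas.z.std() - 1.0) < 0.05

    def test_single_causal_closed_form(self, rng):
        """z = sqrt(n) R b + eps with identity R: E[z] = 5 at the causal
        SNP, 0 elsewhere."""
        blocks = [(np.arange(10), np.eye(10))]
        b = np.zeros(10)
        b[3] = 0.05
        zs = np.vstack([sim.draw_gwas_z(b, blocks, 10_000, rng)
                        for _ in range(200)])
        assert abs(zs[:, 3].mean() - 5.0) < 0.3
        others = np.delete(np.arange(10), 3)
        assert np.abs(zs[:, others].mean(axis=0)).max() < 0.3

    def test_deterministic_under_seed(self):
        d = sim.SimDesign(n_donors=50, n_snps=100, n_genes=5, n_peaks=5,
                          seed=13)
        gm = sim.simulate_genotypes(d)
        z1 = sim.simulate_gwas(gm, d)[0].z
        z2 = sim.simulate_gwas(gm, d)[0].z
        np.testing.assert_array_equal(z1, z2)


class TestCaseLabels:
    def test_exact_case_count_and_determinism(self):
        d = sim.SimDesign(n_donors=100, n_snps=10, n_genes=5, n_peaks=5,
                          case_spec=sim.CaseSpec(n_cases=28), seed=14)
        cases, controls = sim.simulate_case_labels(d)
        assert len(cases) == 28 and len(controls) == 72
        assert cases == sim.simulate_case_labels(d)[0]

    def test_too_many_cases_rejected(self):
        d = sim.SimDesign(n_donors=10, n_snps=10, n_genes=5, n_peaks=5,
                          case_spec=sim.CaseSpec(n_cases=11), seed=14)
        with pytest.raises(ValueError):
            sim.simulate_case_labels(d)

    def test_de_shift_confined_to_context(self):
        d = sim.SimDesign(
            n_donors=40, n_snps=50, n_genes=20, n_peaks=5,
            cells_per_donor_context=40, module_spec=[],
            case_spec=sim.CaseSpec(n_cases=20, de_genes=["gene0000"],
                                   de_lfc=1.5, de_contexts=["GABA_6h"]),
            seed=15)
        gm = sim.simulate_genotypes(d)
        cells = sim.simulate_cells(d)
        expr, _, _ = sim.simulate_expression(gm, cells, d)
        cases = set(sim.simulate_case_labels(d)[0])
        counts = expr.counts.toarray()[:, 0]
        is_case = cells["donor_id"].isin(cases).to_numpy()
        ctx = (cells["cell_type"] + "_" + cells["time"]).to_numpy()

        def tstat(label):
            m = ctx == label
            a, b = counts[m & is_case], counts[m & ~is_case]
            return (a.mean() - b.mean()) / np.sqrt(a.var() / len(a)
                                                   + b.var() / len(b))

        assert tstat("GABA_6h") > 3
        assert abs(tstat("GABA_0h")) < 3
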