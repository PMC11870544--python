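import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stimqtl import qtl as sq
from stimqtl import simulate as sim
from stimqtl.core import Feature, GenotypeMatrix, SNP


class TestInverseNormal:
    def test_exact_blom_quantiles_n5(self):
        """Rank -> quantile map for n = 5 against the Blom formula computed
        independently."""
        x = np.array([10.0, 2.0, 7.0, 30.0, 5.0])
        out = sq.inverse_normal_transform(x)
        ranks = [4, 1, 3, 5, 2]
        expected = [stats.norm.ppf((r - 0.375) / (5 + 0.25)) for r in ranks]
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_monotone_invariance(self, rng):
        x = rng.normal(size=40)
        np.testing.assert_allclose(sq.inverse_normal_transform(x),
                                   sq.inverse_normal_transform(np.exp(x)))


class TestPseudobulk:
    def test_counts_summed_per_donor(self, small_dataset):
        ds = small_dataset
        pb = sq.pseudobulk(ds["expr"], ds["cells"], min_cells=1)
        cells = ds["cells"]
        sub = cells[(cells["cell_type"] == "GABA") & (cells["time"] == "0h")
                    & (cells["donor_id"] == "D000")]
        rows = [ds["expr"].cells.index(c) for c in sub["cell_id"]]
        raw_sum = np.asarray(ds["expr"].counts[rows, :].sum(axis=0)).ravel()
        # CPM of the first feature reproduces the raw sums
        total = raw_sum.sum()
        expected = np.log2(raw_sum / total * 1e6 + 1.0)
        got = pb.matrix("GABA_0h", "log").loc["D000"].to_numpy()
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_min_cells_exclusion_recorded(self, small_dataset):
        ds = small_dataset
        pb = sq.pseudobulk(ds["expr"], ds["cells"], min_cells=10**6)
        assert not pb.log  # nobody retained
        pb2 = sq.pseudobulk(ds["expr"], ds["cells"],
                            min_cells=ds["design"].cells_per_donor_context)
        assert pb2.excluded["GABA_0h"] == []

    def test_int_matrix_is_standard_normalish(self, small_dataset):
        ds = small_dataset
        pb = sq.pseudobulk(ds["expr"], ds["cells"], min_cells=1)
        m = pb.matrix("npglut_6h", "int").to_numpy()
        # ties (all-zero features) pull the Blom mean slightly off zero
        assert abs(m.mean()) < 0.05
        no_ties = m[:, m.std(axis=0) > 0.5]
        assert abs(no_ties.mean()) < 0.01


def _toy_mapping_setup(rng, n_donors=80, beta=0.8):
    snps = [SNP(f"rs{j}", "chr1", 1000 * (j + 1), "A", "G", 0.3)
            for j in range(6)]
    dosage = rng.binomial(2, 0.3, size=(n_donors, 6))
    gm = GenotypeMatrix([f"D{i:03d}" for i in range(n_donors)], snps, dosage)
    gene = Feature(id="g1", kind="gene", chrom="chr1", tss=2500, strand="+")
    y = beta * dosage[:, 1] + rng.normal(0, 0.5, n_donors)
    pb = sq.ContextPseudobulk(feature_ids=["g1"])
    df = pd.DataFrame({"g1": y}, index=gm.donors)
    pb.log["GABA_0h"] = df
    pb.int["GABA_0h"] = df
    return gm, gene, pb


class TestMapQtl:
    def test_planted_effect_recovered(self, rng):
        gm, gene, pb = _toy_mapping_setup(rng)
        res = sq.map_qtl(pb, gm, [gene], "GABA_0h", n_genotype_pcs=0,
                         n_phenotype_pcs=0)
        lead = res.leads.iloc[0]
        assert lead["snp"] == "rs1"
        assert lead["beta"] == pytest.approx(0.8, abs=0.2)
        assert lead["q"] < 0.05

    def test_feature_level_bonferroni(self, rng):
        gm, gene, pb = _toy_mapping_setup(rng)
        res = sq.map_qtl(pb, gm, [gene], "GABA_0h", n_genotype_pcs=0,
                         n_phenotype_pcs=0)
        n_cis = len(res.full)
        lead = res.leads.iloc[0]
        assert lead["p_feature"] == pytest.approx(
            min(1.0, lead["p"] * n_cis))

    def test_collinear_covariate_raises(self, rng):
        gm, gene, pb = _toy_mapping_setup(rng)
        cov = pd.DataFrame(
            {"dup": gm.dosage[:, 1].astype(float)}, index=gm.donors)
        with pytest.raises(ValueError, match="collinear"):
            sq.map_qtl(pb, gm, [gene], "GABA_0h", n_genotype_pcs=0,
                       n_phenotype_pcs=0, covariates=cov)

    def test_too_few_donors_refused(self, rng):
        gm, gene, pb = _toy_mapping_setup(rng, n_donors=8)
        with pytest.raises(ValueError, match="donors"):
            sq.map_qtl(pb, gm, [gene], "GABA_0h")


class TestRandomInterceptLmm:
    def _panel(self, rng, n_donors=30, sd_u=1.0, beta_gxt=0.0):
        g_d = rng.binomial(2, 0.3, n_donors).astype(float)
        u = rng.normal(0, sd_u, n_donors)
        rows = []
        for d in range(n_donors):
            for ti, t in enumerate(("0h", "1h", "6h")):
                y = (0.5 * g_d[d] + 0.3 * ti + u[d]
                     + beta_gxt * g_d[d] * (t == "6h")
                     + rng.normal(0, 0.4))
                rows.append((d, g_d[d], t, y))
        df = pd.DataFrame(rows, columns=["donor", "g", "time", "y"])
        return df

    def _fit_mine(self, df):
        t1 = (df["time"] == "1h").astype(float).to_numpy()
        t6 = (df["time"] == "6h").astype(float).to_numpy()
        g = df["g"].to_numpy()
        X = np.column_stack([np.ones(len(df)), g, t1, t6, g * t1, g * t6])
        return sq.fit_random_intercept(
            df["y"].to_numpy(), X, df["donor"].to_numpy(),
            ["i", "g", "t1", "t6", "gxt1", "gxt6"])

    def test_matches_statsmodels_mixedlm(self, rng):
        """Fixed effects and variance components agree with the
        independently implemented REML fit in statsmodels."""
        import statsmodels.formula.api as smf

        df = self._panel(rng, beta_gxt=0.6)
        fit = self._fit_mine(df)
        sm_fit = smf.mixedlm(
            "y ~ g + C(time, Treatment('0h')) "
            "+ g:C(time, Treatment('0h'))", df,
            groups=df["donor"]).fit(reml=True)
        # statsmodels parameter order: Intercept, time dummies, g, interactions
        np.testing.assert_allclose(fit.beta[1],
                                   sm_fit.params["g"], atol=1e-4)
        np.testing.assert_allclose(
            fit.beta[5], sm_fit.params["g:C(time, Treatment('0h'))[T.6h]"],
            atol=1e-4)
        lam_sm = float(sm_fit.cov_re.iloc[0, 0] / sm_fit.scale)
        assert fit.lam == pytest.approx(lam_sm, rel=0.05)

    def test_boundary_variance_falls_back_to_ols(self, rng):
        df = self._panel(rng, sd_u=0.0)
        fit = self._fit_mine(df)
        assert fit.ols_fallback

    def test_interaction_test_calibrated_under_null(self, rng):
        pvals = []
        for _ in range(300):
            df = self._panel(rng, n_donors=24)
            fit = self._fit_mine(df)
            t = fit.beta[5] / np.sqrt(fit.cov[5, 5])
            pvals.append(2 * stats.t.sf(abs(t), fit.df_within))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_lmm_beats_pooled_ols_with_large_donor_effects(self, rng):
        """With donor intercept SD of 2, the pooled OLS interaction test is
        anticonservative while the mixed model keeps its size."""
        p_lmm, p_ols = [], []
        for _ in range(300):
            df = self._panel(rng, n_donors=24, sd_u=2.0)
            fit = self._fit_mine(df)
            t = fit.beta[5] / np.sqrt(fit.cov[5, 5])
            p_lmm.append(2 * stats.t.sf(abs(t), fit.df_within))
            t1 = (df["time"] == "1h").astype(float).to_numpy()
            t6 = (df["time"] == "6h").astype(float).to_numpy()
            g = df["g"].to_numpy()
            X = np.column_stack([np.ones(len(df)), g, t1, t6, g * t1,
                                 g * t6])
            y = df["y"].to_numpy()
            bhat, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ bhat
            s2 = resid @ resid / (len(y) - X.shape[1])
            cov = s2 * np.linalg.inv(X.T @ X)
            tt = bhat[5] / np.sqrt(cov[5, 5])
            p_ols.append(2 * stats.t.sf(abs(tt), len(y) - X.shape[1]))
        size_lmm = np.mean(np.array(p_lmm) < 0.05)
        size_ols = np.mean(np.array(p_ols) < 0.05)
        assert size_lmm <= 0.08
        # pooled OLS treats 72 correlated rows as independent and misstates
        # the interaction variance under strong donor heterogeneity
        assert size_ols < size_lmm * 0.5


class TestPi1:
    def test_pure_null_near_zero(self):
        p = np.random.default_rng(2024).uniform(size=10_000)
        assert abs(sq.pi1(p)["pi1"]) < 0.03

    def test_pure_signal_near_one(self):
        assert sq.pi1(np.full(100, 1e-7))["pi1"] > 0.95

    def test_mixture_weight_recovered(self):
        # heavy-tailed alternative (Beta(0.1,1)): the lambda<=0.9 functional
        # sits slightly below the true weight, still inside +-0.05
        r = np.random.default_rng(123)
        p = np.concatenate([r.beta(0.1, 1, 3000), r.uniform(size=7000)])
        assert sq.pi1(p)["pi1"] == pytest.approx(0.3, abs=0.05)

    def test_sharp_mixture_weight_unbiased(self):
        # well-separated alternative (|z| ~ N(4,1)): estimator is unbiased
        r = np.random.default_rng(2024)
        z = np.concatenate([r.normal(4, 1, 3000), r.normal(0, 1, 7000)])
        p = 2 * stats.norm.sf(np.abs(z))
        assert sq.pi1(p)["pi1"] == pytest.approx(0.3, abs=0.05)

    def test_small_n_refused(self):
        with pytest.raises(ValueError):
            sq.pi1(np.array([0.5] * 10))


class TestConcordance:
    def _frame(self, rng, n=200):
        return pd.DataFrame({
            "feature": [f"g{i}" for i in range(n)],
            "snp": [f"rs{i}" for i in range(n)],
            "beta": rng.normal(0, 1, n),
            "ref": ["A"] * n, "alt": ["G"] * n,
        })

    def test_identity(self, rng):
        a = self._frame(rng)
        out = sq.concordance(a, a)
        assert out["sign_concordance"] == 1.0
        assert out["slope"] == pytest.approx(1.0)
        assert out["r"] == pytest.approx(1.0)

    def test_noisy_copy_slope_near_one(self, rng):
        a = self._frame(rng, n=500)
        b = a.copy()
        b["beta"] = a["beta"] + rng.normal(0, 0.1, len(a))
        out = sq.concordance(a, b)
        assert out["slope"] == pytest.approx(1.0, abs=0.05)

    def test_allele_flip_invariance(self, rng):
        a = self._frame(rng)
        b = a.copy()
        b["beta"] = -b["beta"]
        b["ref"], b["alt"] = a["alt"], a["ref"]
        out = sq.concordance(a, b)
        assert out["sign_concordance"] == 1.0
        assert out["slope"] == pytest.approx(1.0)

    def test_disjoint_sets_refused(self, rng):
        a = self._frame(rng)
        b = self._frame(rng)
        b["feature"] = "other"
        with pytest.raises(ValueError):
            sq.concordance(a, b)


class TestSharingMatrix:
    def _mapping(self, rng, n=100, signal=True):
        feats = [f"g{i}" for i in range(n)]
        beta = rng.normal(2.0, 0.2, n) if signal else rng.normal(0, 0.1, n)
        p = np.full(n, 1e-8) if signal else rng.uniform(size=n)
        full = pd.DataFrame({"feature": feats, "context": "x",
                             "snp": [f"rs{i}" for i in range(n)],
                             "beta": beta, "se": 0.1, "p": p})
        leads = full.copy()
        leads["p_feature"] = leads["p"]
        leads["q"] = sq.bh_qvalues(leads["p_feature"].to_numpy())
        leads["egene"] = leads["q"] < 0.05
        return sq.QtlMapping(full=full, leads=leads)

    def test_identical_contexts_fully_shared(self, rng):
        m = self._mapping(rng)
        out = sq.sharing_matrix({"a": m, "b": m})
        assert out["replication"].loc["a", "b"] == 1.0
        assert out["pi1"].loc["a", "b"] > 0.95

    def test_null_context_low_replication(self, rng):
        a = self._mapping(rng)
        b = self._mapping(rng, signal=False)
        out = sq.sharing_matrix({"a": a, "b": b})
        # p < 0.05 with matching sign: roughly half of the 5%
        assert out["replication"].loc["a", "b"] < 0.1
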