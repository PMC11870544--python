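import numpy as np
import pandas as pd
import pytest

from stimqtl import finemap as fm
from stimqtl import simulate as sim
from stimqtl.core import GwasSummary

PRIORS = {"snp": (0.05, 25.0), "gene": (0.3, 25.0), "peak": (0.1, 25.0)}


class TestBuildTraitModels:
    def _leads(self, rows):
        return pd.DataFrame(rows, columns=["feature", "context", "snp",
                                           "beta", "se", "p", "q"])

    def test_gene_models_gated_on_q(self):
        leads = self._leads([("g1", "GABA_0h", "rs1", 0.5, 0.1, 1e-6, 0.01),
                             ("g2", "GABA_0h", "rs2", 0.4, 0.1, 0.02, 0.2)])
        models = fm.build_trait_models(leads, "gene")
        assert [m.trait_id for m in models] == ["g1@GABA_0h"]
        assert models[0].weights == {"rs1": 0.5}

    def test_peak_top_variant_by_pvalue(self):
        leads = self._leads([("pk1", "GABA_0h", "rs1", 0.5, 0.1, 1e-8,
                              0.001)])
        asoc = pd.DataFrame({
            "peak": ["pk1"], "snp": ["rs9"], "context": ["GABA_0h"],
            "ref": [40], "alt": [80], "p": [1e-4], "q": [0.01],
            "significant": [True], "total": [120],
        })
        models = fm.build_trait_models(leads, "peak", asoc_results=asoc)
        # the caQTL lead has the smaller p, so its SNP wins
        assert models[0].weights == {"rs1": 0.5}

    def test_asoc_only_peak_uses_asoc_variant(self):
        leads = self._leads([])
        asoc = pd.DataFrame({
            "peak": ["pk2"], "snp": ["rs7"], "context": ["npglut_1h"],
            "ref": [30], "alt": [60], "p": [1e-5], "q": [0.005],
            "significant": [True], "total": [90],
        })
        models = fm.build_trait_models(leads, "peak", asoc_results=asoc)
        assert len(models) == 1
        m = models[0]
        assert m.trait_id == "pk2@npglut_1h"
        assert m.weights == {"rs7": pytest.approx(np.log(2.0))}


class TestImputeTraitZ:
    def _gwas(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        return GwasSummary(["rs1", "rs2"], np.array([4.2, 1.0]), 10_000,
                           [(np.array([0, 1]), R)])

    def test_single_snp_reduction(self):
        tm = fm.TraitModel("t1", "g1", "c", "gene", {"rs1": 0.7})
        out = fm.impute_trait_z([tm], self._gwas())
        assert out["z"].iloc[0] == pytest.approx(4.2)

    def test_negative_weight_flips_sign(self):
        tm = fm.TraitModel("t1", "g1", "c", "gene", {"rs1": -0.7})
        out = fm.impute_trait_z([tm], self._gwas())
        assert out["z"].iloc[0] == pytest.approx(-4.2)

    def test_two_snp_weights_match_matrix_oracle(self):
        w = np.array([0.6, -0.3])
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        z = np.array([4.2, 1.0])
        tm = fm.TraitModel("t1", "g1", "c", "gene",
                           {"rs1": 0.6, "rs2": -0.3})
        out = fm.impute_trait_z([tm], self._gwas())
        expected = float(w @ z) / np.sqrt(float(w @ R @ w))
        assert out["z"].iloc[0] == pytest.approx(expected)

    def test_missing_weight_snp_dropped(self):
        tm = fm.TraitModel("t1", "g1", "c", "gene", {"rsX": 1.0})
        assert fm.impute_trait_z([tm], self._gwas()).empty


class TestFinemapBlock:
    def test_two_variable_posterior_matches_enumeration(self):
        """L = 1 with independent variables: the SER must equal the exact
        posterior computed from multivariate-normal marginal likelihoods."""
        z = np.array([6.0, 0.0])
        R = np.eye(2)
        res = fm.finemap_block(["a", "b"], ["snp", "snp"], z, R, PRIORS,
                               L=1)
        exact = fm.exact_finemap_block(["snp", "snp"], z, R, PRIORS, L=1)
        np.testing.assert_allclose(res.pip, exact, atol=1e-8)
        assert res.pip[0] > 0.99 * (res.pip[0] + res.pip[1])

    def test_null_z_pips_at_prior_level(self):
        z = np.zeros(10)
        R = np.eye(10)
        res = fm.finemap_block([f"v{i}" for i in range(10)], ["snp"] * 10,
                               z, R, {"snp": (0.02, 25.0)}, L=1)
        assert (res.pip <= 0.02 + 0.01).all()

    def test_duplicate_variables_split_pip(self):
        R = np.ones((2, 2))
        z = np.array([6.0, 6.0])
        res = fm.finemap_block(["a", "b"], ["snp", "snp"], z, R,
                               {"snp": (0.1, 25.0)}, L=1)
        assert res.pip[0] == pytest.approx(res.pip[1], abs=1e-9)
        assert res.pip.sum() == pytest.approx(1.0, abs=0.01)

    def test_correlated_block_matches_enumeration(self, rng):
        for _ in range(10):
            p = 8
            R = 0.6 ** np.abs(np.subtract.outer(np.arange(p),
                                                np.arange(p))).astype(float)
            z = rng.normal(0, 1, p)
            z[2] += 5
            res = fm.finemap_block([f"v{i}" for i in range(p)],
                                   ["snp"] * p, z, R,
                                   {"snp": (0.05, 25.0)}, L=1)
            exact = fm.exact_finemap_block(["snp"] * p, z, R,
                                           {"snp": (0.05, 25.0)}, L=1)
            assert 0.5 * np.abs(res.pip - exact).sum() < 1e-6

    def test_two_components_on_separated_signals(self, rng):
        p = 8
        R = np.eye(p)
        z = rng.normal(0, 1, p)
        z[1] += 7
        z[5] -= 6
        res = fm.finemap_block([f"v{i}" for i in range(p)], ["snp"] * p,
                               z, R, {"snp": (0.05, 25.0)}, L=2)
        exact = fm.exact_finemap_block(["snp"] * p, z, R,
                                       {"snp": (0.05, 25.0)}, L=2)
        assert 0.5 * np.abs(res.pip - exact).sum() < 1e-3
        assert res.pip[1] > 0.9 and res.pip[5] > 0.9


class TestEmGroupPriors:
    def test_too_few_blocks_rejected(self):
        with pytest.raises(ValueError):
            fm.em_group_priors([{"ids": [], "groups": [], "z": [],
                                 "R": []}] * 5)

    def test_null_blocks_give_no_enrichment(self):
        blocks = sim.simulate_finemap_blocks(
            80, snps_per_block=15, genes_per_block=2, pi_snp=0.0,
            pi_gene=0.0, seed=5)
        res = fm.em_group_priors(blocks, L=1)
        # priors collapse toward the floor for every group
        assert res.priors["gene"][0] < 0.05
        assert res.priors["snp"][0] < 0.02

    def test_stronger_signal_raises_sigma2(self):
        blocks = sim.simulate_finemap_blocks(
            60, snps_per_block=15, genes_per_block=2, pi_snp=0.01,
            pi_gene=0.3, sigma2=25.0, seed=6)
        res1 = fm.em_group_priors(blocks, L=1)
        doubled = [dict(b, z=2 * b["z"]) for b in blocks]
        res2 = fm.em_group_priors(doubled, L=1)
        assert res2.priors["gene"][1] > res1.priors["gene"][1]
        # ordering of inclusion priors is preserved
        assert res2.priors["gene"][0] > res2.priors["snp"][0]


class TestHeritabilityPartition:
    def test_single_dominant_trait_takes_all(self):
        blocks = [{"ids": ["s0", "s1", "g@GABA_0h"],
                   "groups": ["snp", "snp", "gene"],
                   "z": np.array([0.1, -0.2, 9.0]),
                   "R": np.eye(3)}] * 10
        res = fm.em_group_priors(blocks, L=1, max_iter=5)
        h2 = fm.heritability_partition(res)
        overall = h2[h2["context"].isna()].set_index("group")
        assert overall.loc["gene", "h2_prop_pct"] > 95.0

    def test_null_gwas_gives_zero_partition(self):
        blocks = [{"ids": [f"s{i}" for i in range(5)],
                   "groups": ["snp"] * 5,
                   "z": np.zeros(5), "R": np.eye(5)}] * 12
        res = fm.em_group_priors(blocks, L=1, max_iter=3)
        h2 = fm.heritability_partition(res)
        # contributions exist only at the prior level; shares remain defined
        assert (h2["h2_prop_pct"] <= 100.0).all()


class TestGenePipAggregation:
    def test_dynamic_rule_forced_arithmetic(self):
        pips = pd.DataFrame({"gene": ["g1"] * 3,
                             "context": ["GABA_0h", "GABA_1h", "GABA_6h"],
                             "pip": [0.1, 0.4, 0.3]})
        out = fm.aggregate_gene_pip(pips).iloc[0]
        assert out["gene_pip"] == pytest.approx(0.8)
        assert out["class"] == "dynamic"  # (0.4 + 0.3) - 0.1 = 0.6 >= 0.5

    def test_static_when_baseline_dominates(self):
        pips = pd.DataFrame({"gene": ["g1"] * 3,
                             "context": ["GABA_0h", "GABA_1h", "GABA_6h"],
                             "pip": [0.6, 0.1, 0.1]})
        assert fm.aggregate_gene_pip(pips).iloc[0]["class"] == "static"

    def test_boundary_margin_is_dynamic(self):
        pips = pd.DataFrame({"gene": ["g1"] * 2,
                             "context": ["GABA_0h", "GABA_6h"],
                             "pip": [0.0, 0.5]})
        assert fm.aggregate_gene_pip(pips).iloc[0]["class"] == "dynamic"

    def test_confidence_strata(self):
        pips = pd.DataFrame({"gene": ["g1", "g2", "g3"],
                             "context": ["GABA_1h"] * 3,
                             "pip": [0.85, 0.6, 0.2]})
        out = fm.aggregate_gene_pip(pips).set_index("gene")
        assert out.loc["g1", "confidence"] == "high"
        assert out.loc["g2", "confidence"] == "plausible"
        assert out.loc["g3", "confidence"] == "low"

    def test_capped_pip_reported(self):
        pips = pd.DataFrame({"gene": ["g1"] * 3,
                             "context": ["GABA_0h", "GABA_1h", "GABA_6h"],
                             "pip": [0.5, 0.5, 0.5]})
        out = fm.aggregate_gene_pip(pips).iloc[0]
        assert out["gene_pip"] == pytest.approx(1.5)
        assert out["gene_pip_capped"] == 1.0


class TestLinkCpeakTargets:
    def test_evidence_channels_combined(self):
        from stimqtl.core import Feature

        tm = fm.TraitModel("pk1@GABA_0h", "pk1", "GABA_0h", "peak",
                           {"rs1": 0.4})
        linked = pd.DataFrame([("pk1", "gA")], columns=["peak", "gene"])
        eqtl = pd.DataFrame({"feature": ["gA"], "snp": ["rs1"],
                             "q": [0.1]})
        abc = pd.DataFrame({"peak": ["pk1"], "gene": ["gA"],
                            "score": [0.5]})
        peak = Feature(id="pk1", kind="peak", chrom="chr1", start=100,
                       end=600)
        gene_inside = Feature(id="gA", kind="gene", chrom="chr1", tss=300,
                              strand="+")
        out = fm.link_cpeak_targets([tm], linked, eqtl, abc,
                                    [gene_inside], peaks=[peak])
        row = out.iloc[0]
        assert row["gene"] == "gA"
        assert set(row["evidence"].split(";")) == {"abc", "coactivation",
                                                   "eqtl", "overlap"}
        assert row["n_evidence"] == 4

    def test_eqtl_fdr_gate(self):
        tm = fm.TraitModel("pk1@c", "pk1", "c", "peak", {"rs1": 0.4})
        eqtl = pd.DataFrame({"feature": ["gA"], "snp": ["rs1"],
                             "q": [0.3]})  # above the 0.2 gate
        out = fm.link_cpeak_targets(
            [tm], pd.DataFrame(columns=["peak", "gene"]), eqtl,
            pd.DataFrame(columns=["peak", "gene", "score"]), [])
        assert out.empty
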