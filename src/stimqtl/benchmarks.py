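"""Calibration and parameter-recovery studies on synthetic data.

Each function builds a synthetic experiment with planted truth via
:mod:`stimqtl.simulate`, runs the matching estimator, and returns the
recovered quantities. Together they document what the pipeline's tests can
and cannot show: type-I error of the dynamic (interaction) QTL test, effect
recovery of cis mapping, allelic-imbalance exactness and power, fine-mapping
posterior correctness and prior-enrichment recovery, temporal-module and
regulator recovery. Problem sizes are desk scale (tens of donors, hundreds
of features) so a full run takes minutes on one core.

Every function takes a single ``seed`` that fully determines its output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import asoc as sasoc
from . import differential as sdiff
from . import finemap as fm
from . import grn as sgrn
from . import linking as lk
from . import qtl as sq
from . import simulate as sim
from . import trajectory as tj
from .core import snp_in_cis


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1000 + k) % (2**31 - 1)


def _nearest_cis_snp(lay, gene, window_bp=100_000):
    pos = np.array([s.pos for s in lay.snp_meta])
    j = int(np.argmin(np.abs(pos - gene.tss)))
    if abs(pos[j] - gene.tss) <= window_bp:
        return lay.snp_meta[j].id
    return None


# ---------------------------------------------------------------------------
# dynamic QTL test: null calibration and classification power
# ---------------------------------------------------------------------------

def dynamic_null_calibration(seed: int = 1, n_features: int = 2000,
                             n_donors: int = 24, donor_sd: float = 1.0) -> dict:
    """Type-I error of the genotype-by-time interaction test when the planted
    genetic effect is identical at every time point (large donor effects)."""
    d = sim.SimDesign(n_donors=n_donors, n_snps=n_features,
                      n_genes=n_features, n_peaks=50, gene_spacing=10_000,
                      donor_sd=donor_sd, seed=_sub_seed(seed, 1))
    lay = sim.layout(d)
    qtls = []
    for g in lay.genes:
        s = _nearest_cis_snp(lay, g)
        if s is not None:
            qtls.append(sim.PlantedQtl(feature=g.id, snp=s, beta=0.5,
                                       contexts="all"))
    d.qtl_spec = qtls
    gm = sim.simulate_genotypes(d)
    cells = sim.simulate_cells(d)
    expr, _, _ = sim.simulate_expression(gm, cells, d)
    pb = sq.pseudobulk(expr, cells, min_cells=5)
    leads = pd.DataFrame([(q.feature, q.snp) for q in qtls],
                         columns=["feature", "snp"])
    res = sq.dynamic_test(pb, gm, leads, "GABA")
    t1 = float((res["p_1h"] < 0.05).mean())
    t6 = float((res["p_6h"] < 0.05).mean())
    return {
        "type1_1h": t1,
        "type1_6h": t6,
        "type1": (t1 + t6) / 2.0,  # both interaction contrasts pooled
        "type1_joint": float((res["p_joint"] < 0.05).mean()),
        "n": int(len(res)),
    }


def eqtl_recovery(seed: int = 1, n_donors: int = 100,
                  n_planted: int = 200) -> dict:
    """Slope of estimated vs planted cis effects (log2 scale) and the
    fraction of planted eQTL reaching feature-level q < 0.05."""
    d = sim.SimDesign(n_donors=n_donors, seed=_sub_seed(seed, 2))
    lay = sim.layout(d)
    rng = np.random.default_rng(_sub_seed(seed, 3))
    picked = rng.choice(len(lay.genes), size=min(n_planted, len(lay.genes)),
                        replace=False)
    qtls = []
    for gi in picked:
        g = lay.genes[gi]
        s = _nearest_cis_snp(lay, g)
        if s is not None:
            beta = float(rng.uniform(0.4, 0.8) * rng.choice([-1, 1]))
            qtls.append(sim.PlantedQtl(feature=g.id, snp=s, beta=beta,
                                       contexts="all"))
    d.qtl_spec = qtls
    gm = sim.simulate_genotypes(d)
    cells = sim.simulate_cells(d)
    expr, truth, _ = sim.simulate_expression(gm, cells, d)
    pb = sq.pseudobulk(expr, cells, min_cells=5)
    planted_genes = [g for g in lay.genes
                     if g.id in {q.feature for q in qtls}]
    res = sq.map_qtl(pb, gm, planted_genes, "GABA_0h", scale="log")
    lead_truth = (truth[truth["context"] == "GABA_0h"]
                  [["feature", "snp", "beta"]]
                  .rename(columns={"beta": "true_beta"}))
    m = res.full.merge(lead_truth, on=["feature", "snp"])
    slope = float(np.polyfit(m["true_beta"], m["beta"], 1)[0])
    sig = res.leads.merge(lead_truth, on="feature")
    return {"slope": slope, "power": float((sig["q"] < 0.05).mean()),
            "n": int(len(m))}


def dynamic_classification(seed: int = 1, n_donors: int = 100,
                           n_dynamic: int = 200, n_static: int = 200) -> dict:
    """Power to classify planted dynamic eQTL (effect only at 6h) and the
    misclassification rate of planted static eQTL (equal effect at all
    times)."""
    n_genes = n_dynamic + n_static
    d = sim.SimDesign(n_donors=n_donors, n_snps=1000, n_genes=n_genes,
                      n_peaks=50, gene_spacing=20_000,
                      seed=_sub_seed(seed, 4))
    lay = sim.layout(d)
    qtls, kind = [], {}
    stim_6h = [f"{ct}_6h" for ct in ("GABA", "nmglut", "npglut")]
    for gi, g in enumerate(lay.genes):
        s = _nearest_cis_snp(lay, g)
        if s is None:
            continue
        if gi < n_dynamic:
            qtls.append(sim.PlantedQtl(feature=g.id, snp=s, beta=0.8,
                                       contexts=stim_6h))
            kind[g.id] = "dynamic"
        else:
            qtls.append(sim.PlantedQtl(feature=g.id, snp=s, beta=0.8,
                                       contexts="all"))
            kind[g.id] = "static"
    d.qtl_spec = qtls
    gm = sim.simulate_genotypes(d)
    cells = sim.simulate_cells(d)
    expr, _, _ = sim.simulate_expression(gm, cells, d)
    pb = sq.pseudobulk(expr, cells, min_cells=5)
    leads = pd.DataFrame([(q.feature, q.snp) for q in qtls],
                         columns=["feature", "snp"])
    res = sq.dynamic_test(pb, gm, leads, "GABA")
    res["kind"] = res["feature"].map(kind)
    grp = res.groupby("kind")["dynamic"].mean()
    return {"power_dynamic": float(grp.get("dynamic", np.nan)),
            "false_dynamic": float(grp.get("static", np.nan)),
            "n": int(len(res))}


# ---------------------------------------------------------------------------
# allele-specific open chromatin
# ---------------------------------------------------------------------------

def asoc_calibration(seed: int = 1, n_null: int = 2000, n_planted: int = 200,
                     n_donors: int = 12, coverage: int = 50) -> dict:
    """Exactness of the binomial test, FDR calibration under the balanced
    null, and detection power at a planted alt fraction of 0.7 (per-donor
    coverage 50, pooled over het donors)."""
    toy = pd.DataFrame({"snp": ["s"], "donor": ["d"], "context": ["GABA_0h"],
                        "ref_count": [3], "alt_count": [1]})
    p_exact = sasoc.asoc_test(sasoc.aggregate(toy, 1, 1))["p"].iloc[0]

    rng = np.random.default_rng(_sub_seed(seed, 5))
    rows = []
    for s in range(n_null):
        for dn in range(n_donors):
            alt = rng.binomial(coverage, 0.5)
            rows.append((f"null{s}", f"D{dn}", "GABA_0h",
                         coverage - alt, alt))
    null_tab = pd.DataFrame(rows, columns=["snp", "donor", "context",
                                           "ref_count", "alt_count"])
    null_res = sasoc.asoc_test(sasoc.aggregate(null_tab))
    rows2 = list(rows)
    for s in range(n_planted):
        for dn in range(n_donors):
            alt = rng.binomial(coverage, 0.7)
            rows2.append((f"true{s}", f"D{dn}", "GABA_0h",
                          coverage - alt, alt))
    mix = pd.DataFrame(rows2, columns=["snp", "donor", "context",
                                       "ref_count", "alt_count"])
    mix_res = sasoc.asoc_test(sasoc.aggregate(mix))
    power = mix_res[mix_res["snp"].str.startswith("true")]["significant"].mean()
    return {"p_exact_31": float(p_exact),
            "null_sig_frac": float(null_res["significant"].mean()),
            "power": float(power), "n_null": n_null}


def asoc_caqtl_concordance(seed: int = 1, n_caqtl: int = 300) -> dict:
    """Pearson r between pooled log allelic ratio and the mapped caQTL
    effect when the generator couples the two (kappa = 1)."""
    d = sim.SimDesign(n_donors=24, n_snps=500, n_genes=50, n_peaks=400,
                      seed=_sub_seed(seed, 6))
    lay = sim.layout(d)
    rng = np.random.default_rng(_sub_seed(seed, 7))
    caqtls = []
    for j in range(min(n_caqtl, len(lay.peaks))):
        pk = lay.peaks[j]
        s = sim.snp_in_peak(lay, pk.id)
        if s is None:
            continue
        beta = float(rng.uniform(0.3, 0.9) * rng.choice([-1, 1]))
        caqtls.append(sim.PlantedQtl(feature=pk.id, snp=s, beta=beta,
                                     contexts="all"))
    d.caqtl_spec = caqtls
    gm = sim.simulate_genotypes(d)
    cells = sim.simulate_cells(d)
    atac, _, _ = sim.simulate_accessibility(gm, cells, d)
    allele_counts, _ = sim.simulate_allele_counts(gm, atac, cells, d)
    asoc_res = sasoc.asoc_test(sasoc.aggregate(allele_counts))
    pb = sq.pseudobulk(atac, cells, min_cells=5)
    snp_of = {c.feature: c.snp for c in caqtls}
    peaks_with = [p for p in lay.peaks if p.id in snp_of]
    frames = []
    for ctx in pb.contexts():
        full = sq.map_qtl(pb, gm, peaks_with, ctx, scale="log").full
        sel = full[[snp_of.get(f) == s
                    for f, s in zip(full["feature"], full["snp"])]]
        frames.append(sel)
    ca = pd.concat(frames, ignore_index=True)
    out = sasoc.caqtl_concordance(asoc_res, ca[["snp", "context", "beta"]])
    return {"r": out["r"], "sign_concordance": out["sign_concordance"],
            "n_pairs": out["n_pairs"]}


# ---------------------------------------------------------------------------
# pi1
# ---------------------------------------------------------------------------

def pi1_recovery(seed: int = 1, n: int = 10_000, pi1_true: float = 0.3) -> dict:
    """pi1 on a realistic mixture (30% two-sided p-values of N(4,1) z-scores,
    70% null) and on the pure null."""
    rng = np.random.default_rng(_sub_seed(seed, 8))
    p_null = rng.uniform(size=n)
    k = int(round(pi1_true * n))
    z = np.concatenate([rng.normal(4.0, 1.0, size=k),
                        rng.normal(0.0, 1.0, size=n - k)])
    p_mix = 2 * stats.norm.sf(np.abs(z))
    return {"pi1_null": sq.pi1(p_null)["pi1"],
            "pi1_mixture": sq.pi1(p_mix)["pi1"],
            "pi1_true": pi1_true, "n": n}


# ---------------------------------------------------------------------------
# fine-mapping
# ---------------------------------------------------------------------------

PRIORS = {"snp": (0.01, 25.0), "gene": (0.3, 25.0), "peak": (0.05, 25.0)}


def finemap_oracle_equivalence(seed: int = 1, n_blocks: int = 50) -> dict:
    """Total-variation distance between the single-effect regression PIPs and
    direct posterior enumeration on random blocks of 12 variables."""
    blocks = sim.simulate_finemap_blocks(
        n_blocks, snps_per_block=10, genes_per_block=2, pi_snp=0.01,
        pi_gene=0.3, sigma2=25.0, rho=0.4, seed=_sub_seed(seed, 9))
    tvs = []
    for b in blocks:
        res = fm.finemap_block(b["ids"], b["groups"], b["z"], b["R"],
                               PRIORS, L=1)
        exact = fm.exact_finemap_block(b["groups"], b["z"], b["R"],
                                       PRIORS, L=1)
        tvs.append(0.5 * float(np.abs(res.pip - exact).sum()))
    return {"max_tv": max(tvs), "mean_tv": float(np.mean(tvs)),
            "n_blocks": n_blocks}


def finemap_enrichment(seed: int = 1, n_blocks: int = 500,
                       enrichment_true: float = 30.0) -> dict:
    """EM recovery of the gene-vs-SNP causal enrichment and PIP calibration
    (max |mean PIP - causal fraction| over occupied deciles)."""
    pi_snp = 0.01
    blocks = sim.simulate_finemap_blocks(
        n_blocks, snps_per_block=20, genes_per_block=2, pi_snp=pi_snp,
        pi_gene=pi_snp * enrichment_true, sigma2=25.0, rho=0.4,
        seed=_sub_seed(seed, 10))
    res = fm.em_group_priors(blocks, L=1, max_iter=40)
    pips = np.concatenate([b.pip for b in res.blocks])
    causal = np.concatenate([b["causal"] for b in blocks])
    gaps = []
    bins = np.clip((pips * 10).astype(int), 0, 9)
    for dec in range(10):
        m = bins == dec
        # a causal fraction is only estimable to ~0.1 with >= 50 variables
        # in the decile (binomial SE <= 0.07); sparser deciles are skipped
        if m.sum() >= 50:
            gaps.append(abs(float(pips[m].mean()) - float(causal[m].mean())))
    return {"enrichment": float(res.enrichment["gene"]),
            "enrichment_true": enrichment_true,
            "max_decile_gap": max(gaps), "n_blocks": n_blocks}


def h2_partition_ratio(seed: int = 1, n_reps: int = 10,
                       share_ratio_true: float = 2.5) -> dict:
    """Recovered peak-vs-gene share of mediated heritability when the
    planted peak causal share is ``share_ratio_true`` times the gene share."""
    pi_gene = 0.1
    ratios = []
    for rep in range(n_reps):
        blocks = sim.simulate_finemap_blocks(
            150, snps_per_block=15, genes_per_block=2, peaks_per_block=2,
            pi_snp=0.01, pi_gene=pi_gene,
            pi_peak=pi_gene * share_ratio_true, sigma2=25.0, rho=0.4,
            seed=_sub_seed(seed, 11 + rep))
        res = fm.em_group_priors(blocks, L=1, max_iter=30)
        h2 = fm.heritability_partition(res)
        overall = (h2[h2["context"].isna()]
                   .set_index("group")["h2_prop_pct"])
        ratios.append(float(overall["peak"] / overall["gene"]))
    return {"mean_ratio": float(np.mean(ratios)),
            "min_ratio": float(np.min(ratios)),
            "max_ratio": float(np.max(ratios)),
            "ratio_true": share_ratio_true, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# temporal modules, priming, GRN
# ---------------------------------------------------------------------------

def _module_design(seed: int, lead_bins: int = 10) -> sim.SimDesign:
    lead = lead_bins / tj.DEFAULT_N_BINS
    mods = [sim.ModuleSpec("m_early", "pulse_early", 100),
            sim.ModuleSpec("m_late", "late", 100),
            sim.ModuleSpec("m_sustained", "sustained", 100),
            sim.ModuleSpec("m_down", "down", 100)]
    d = sim.SimDesign(n_donors=24, n_snps=200, n_genes=400, n_peaks=400,
                      module_spec=mods, seed=seed)
    d.peak_module_spec = [
        sim.ModuleSpec("p_early", "pulse_early", 100),
        sim.ModuleSpec("p_late", sim.shifted_shape("late", lead), 100),
        sim.ModuleSpec("p_sustained", "sustained", 100),
        sim.ModuleSpec("p_down", "down", 100)]
    return d


def module_recovery(seed: int = 1) -> dict:
    """K-means recovery (ARI) of four planted temporal archetypes and the
    priming-detection rate for genes whose promoter peak leads expression by
    10 pseudotime bins."""
    d = _module_design(_sub_seed(seed, 20))
    gm = sim.simulate_genotypes(d)
    cells = sim.simulate_cells(d)
    expr, _, gene_mod = sim.simulate_expression(gm, cells, d)
    atac, _, _ = sim.simulate_accessibility(gm, cells, d)
    cts = ("GABA", "nmglut", "npglut")
    gprof = {ct: tj.bin_pseudotime(expr, cells, ct) for ct in cts}
    # timing comparison uses composition-free binning (see bin_pseudotime)
    gprof_raw = {ct: tj.bin_pseudotime(expr, cells, ct, normalize="none")
                 for ct in cts}
    pprof_raw = {ct: tj.bin_pseudotime(atac, cells, ct, normalize="none")
                 for ct in cts}
    genes = [f"gene{i:04d}" for i in range(400)]
    ma = tj.cluster_modules(gprof, genes, k=4, seed=0)
    ari = ma.ari({g: gene_mod.get(g, "none") for g in genes})
    n_prim = 0
    priming_genes = range(100, 200)  # the late module, peaks lead by 10 bins
    for i in priming_genes:
        E = np.vstack([gprof_raw[ct].loc[f"gene{i:04d}"].to_numpy()
                       for ct in cts])
        A = np.vstack([pprof_raw[ct].loc[f"peak{i:04d}"].to_numpy()
                       for ct in cts])
        n_prim += tj.concordance(E, A)["class"] == "priming"
    return {"ari": float(ari), "priming_rate": n_prim / 100.0,
            "n_genes": 400}


def grn_recovery(seed: int = 1) -> dict:
    """Recovery of a planted regulator driving 150 targets: significant
    edges to true targets, and whether factors with motifs only in
    constitutive peaks ever pass the 100-target regulator filter."""
    mods = [sim.ModuleSpec("m_late", "late", 150),
            sim.ModuleSpec("m_early", "pulse_early", 100)]
    d = sim.SimDesign(n_donors=24, n_snps=400, n_genes=600, n_peaks=700,
                      module_spec=mods, seed=_sub_seed(seed, 21))
    d.peak_module_spec = [sim.ModuleSpec("p_late", "late", 150),
                          sim.ModuleSpec("p_early", "pulse_early", 100)]
    gm = sim.simulate_genotypes(d)
    cells = sim.simulate_cells(d)
    expr, _, _ = sim.simulate_expression(gm, cells, d)
    atac, _, peak_mod = sim.simulate_accessibility(gm, cells, d)
    lay = sim.layout(d)
    targets = [f"gene{i:04d}" for i in range(150)]
    motif_map, _ = sim.simulate_motif_map(d, {}, peak_mod,
                                          {"TFreg": targets})
    pb = sq.pseudobulk(expr, cells, min_cells=5)
    de_genes = tj.select_variable_degs(sdiff.response_de_all(pb),
                                       fc_threshold=2.0)
    links = lk.link_peaks(expr, atac, cells, lay.genes, "GABA")
    pkprof = tj.bin_pseudotime(atac, cells, "GABA")
    gprof = tj.bin_pseudotime(expr, cells, "GABA")
    act = sgrn.motif_activity(pkprof, motif_map, seed=0)
    edges = sgrn.infer_grn(act, gprof, links, motif_map, "GABA",
                           target_genes=de_genes)
    counts = edges.groupby("tf").size()
    n_true = int(len(edges[(edges["tf"] == "TFreg")
                           & edges["target"].isin(targets)]))
    null_counts = counts.drop("TFreg", errors="ignore")
    n_null_tfs = int(motif_map["tf"].nunique()) - 1
    frac_null_called = (float((null_counts >= 100).sum()) / n_null_tfs
                        if n_null_tfs else 0.0)
    return {"true_targets_recovered": n_true,
            "max_null_targets": int(null_counts.max()) if len(null_counts)
            else 0,
            "frac_null_called": frac_null_called,
            "n_true_targets": 150}


ALL_BENCHMARKS = {
    "dynamic_null_calibration": dynamic_null_calibration,
    "eqtl_recovery": eqtl_recovery,
    "dynamic_classification": dynamic_classification,
    "asoc_calibration": asoc_calibration,
    "asoc_caqtl_concordance": asoc_caqtl_concordance,
    "pi1_recovery": pi1_recovery,
    "finemap_oracle_equivalence": finemap_oracle_equivalence,
    "finemap_enrichment": finemap_enrichment,
    "h2_partition_ratio": h2_partition_ratio,
    "module_recovery": module_recovery,
    "grn_recovery": grn_recovery,
}
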