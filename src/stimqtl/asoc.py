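"""Allele-specific open chromatin (ASoC) analysis.

Within a heterozygous individual the two alleles of a SNP inside an open
chromatin region are exposed to the same trans environment, so a departure of
the alt-read fraction from 1/2 is a cis signal of allele-specific
accessibility. Reads are pooled over heterozygous donors per (SNP, context),
tested with an exact two-sided binomial test against p0 = 0.5, and controlled
with BH per context.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix, bh_qvalues

logger = logging.getLogger("stimqtl")

REQUIRED_COLUMNS = ("snp", "donor", "context", "ref_count", "alt_count")


def aggregate(allele_counts: pd.DataFrame, min_total: int = 20,
              min_donors: int = 2) -> pd.DataFrame:
    """Pool ref/alt reads over het donors per (snp, context).

    Keeps entries with total reads >= ``min_total`` and number of
    contributing het donors >= ``min_donors``.
    """
    if min_total < 0 or min_donors < 0:
        raise ValueError("thresholds must be >= 0")
    missing = set(REQUIRED_COLUMNS) - set(allele_counts.columns)
    if missing:
        raise ValueError(f"allele count table missing columns {sorted(missing)}")
    if ((allele_counts["ref_count"] + allele_counts["alt_count"]) < 1).any():
        raise ValueError("rows with zero total reads")
    g = allele_counts.groupby(["snp", "context"], sort=True).agg(
        ref=("ref_count", "sum"), alt=("alt_count", "sum"),
        n_donors=("donor", "nunique"),
    ).reset_index()
    g["total"] = g["ref"] + g["alt"]
    keep = (g["total"] >= min_total) & (g["n_donors"] >= min_donors)
    return g[keep].reset_index(drop=True)


def asoc_test(pooled: pd.DataFrame, p0: float = 0.5,
              alpha: float = 0.05) -> pd.DataFrame:
    """Exact two-sided binomial test of allelic balance per (snp, context).

    ``p0`` allows a fixed non-0.5 null (e.g. for a known reference-mapping
    bias); BH q-values are computed within each context.
    """
    if pooled.empty:
        return pooled.assign(alt_fraction=[], p=[], q=[], significant=[])
    rows = []
    for r in pooled.itertuples(index=False):
        total = int(r.ref + r.alt)
        p = stats.binomtest(int(r.alt), total, p0).pvalue
        rows.append(p)
    out = pooled.copy()
    out["alt_fraction"] = out["alt"] / out["total"]
    out["p"] = rows
    out["q"] = np.nan
    for ctx, idx in out.groupby("context").groups.items():
        out.loc[idx, "q"] = bh_qvalues(out.loc[idx, "p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out


def caqtl_concordance(asoc_results: pd.DataFrame, caqtl_results: pd.DataFrame,
                      both_significant: bool = False) -> dict:
    """Correlation between pooled log allelic ratio and caQTL effect size.

    ``asoc_results`` from :func:`asoc_test`; ``caqtl_results`` with columns
    (snp, context, beta) on the alt-allele scale (optional ref/alt columns in
    both frames trigger allele alignment). Reports Pearson r over shared
    (snp, context) pairs and the sign concordance among pairs significant in
    both analyses (all pairs if ``both_significant`` is False).
    """
    merged = asoc_results.merge(caqtl_results, on=["snp", "context"],
                                suffixes=("_asoc", "_caqtl"))
    if len(merged) < 10:
        raise ValueError(f"only {len(merged)} shared (snp, context) pairs (< 10)")
    log_ratio = np.log(merged["alt"] / merged["ref"])
    beta = merged["beta"].to_numpy().copy()
    if {"ref_asoc", "alt_asoc", "ref_caqtl", "alt_caqtl"}.issubset(merged.columns):
        flipped = (merged["ref_asoc"] == merged["alt_caqtl"]) & \
                  (merged["alt_asoc"] == merged["ref_caqtl"])
        beta[flipped.to_numpy()] *= -1.0
    r = float(np.corrcoef(log_ratio, beta)[0, 1])
    agree = np.sign(log_ratio.to_numpy()) == np.sign(beta)
    mask = np.ones(len(merged), dtype=bool)
    if both_significant and {"significant", "q_caqtl"}.issubset(merged.columns):
        mask = (merged["significant"] & (merged["q_caqtl"] < 0.05)).to_numpy()
    sign_conc = float(agree[mask].mean()) if mask.any() else np.nan
    return {"r": r, "sign_concordance": sign_conc, "n_pairs": len(merged)}


def ld_proxies(genotypes: GenotypeMatrix, index_snp: str,
               r2_threshold: float = 0.8) -> list[str]:
    """SNPs whose dosage r^2 with the index SNP is >= the threshold
    (the index itself always qualifies)."""
    if not 0 < r2_threshold <= 1:
        raise ValueError("r2_threshold must be in (0, 1]")
    j = genotypes.snp_idx(index_snp)
    X = genotypes.dosage.astype(float)
    x = X[:, j]
    if x.std() == 0:
        return [index_snp]
    xc = x - x.mean()
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((Xc ** 2).sum(axis=0)) * np.sqrt((xc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (Xc.T @ xc) / denom, 0.0)
    r2 = r ** 2
    r2[j] = 1.0
    return [genotypes.snps[k].id for k in np.where(r2 >= r2_threshold)[0]]


def gwas_ld_intersect(asoc_results: pd.DataFrame, gwas_index_snps: list[str],
                      genotypes: GenotypeMatrix,
                      r2_threshold: float = 0.8) -> pd.DataFrame:
    """Per GWAS index SNP: is the locus explained by an ASoC variant?

    A locus is "ASoC-explained" in a context set when the index SNP or any LD
    proxy (dosage r^2 >= threshold) is significant ASoC there. Contexts are
    split into resting (0h) and stimulated (1h/6h) to expose the gain of
    ASoC support under stimulation.
    """
    sig = asoc_results[asoc_results["significant"]]
    sig_by_snp = sig.groupby("snp")["context"].apply(list).to_dict()
    rows = []
    for snp in gwas_index_snps:
        try:
            proxies = ld_proxies(genotypes, snp, r2_threshold)
        except KeyError:
            logger.warning("GWAS index SNP %s absent from genotypes; skipped", snp)
            continue
        contexts: set[str] = set()
        support = []
        for p in proxies:
            for ctx in sig_by_snp.get(p, []):
                contexts.add(ctx)
                support.append(p)
        at_rest = any(c.endswith("_0h") for c in contexts)
        stimulated = any(c.endswith(("_1h", "_6h")) for c in contexts)
        rows.append((snp, len(proxies), bool(contexts), at_rest, stimulated,
                     ";".join(sorted(set(support)))))
    return pd.DataFrame(rows, columns=["index_snp", "n_proxies", "asoc_explained",
                                       "explained_at_rest",
                                       "explained_stimulated",
                                       "supporting_snps"])
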