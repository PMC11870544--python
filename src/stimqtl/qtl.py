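"""Pseudobulk construction and per-context / dynamic QTL mapping.

eQTL and caQTL mapping runs per context (cell type x time point) on donor
pseudobulk: counts are summed per donor, CPM-normalized, log2(x+1)
transformed and then rank-based inverse-normal transformed per feature.
Association is OLS of the transformed value on allele dosage plus covariates,
with Bonferroni-within-feature / BH-across-features multiplicity control.

Dynamic (response) QTL are detected with a donor random-intercept linear
mixed model fit by restricted maximum likelihood: stacking a cell type's
three time points, genotype-by-time interaction contrasts test whether the
genetic effect differs between the resting and stimulated states while the
random intercept absorbs non-genetic differences between donor lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import (
    CELL_TYPES,
    CONTEXTS,
    TIME_POINTS,
    CountMatrix,
    Feature,
    GenotypeMatrix,
    bh_qvalues,
    snp_in_cis,
)

logger = logging.getLogger("stimqtl")

DEFAULT_GENE_CIS_BP = 100_000
DEFAULT_PEAK_CIS_BP = 25_000


# ---------------------------------------------------------------------------
# pseudobulk
# ---------------------------------------------------------------------------

def inverse_normal_transform(x: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal (Blom) transform; ties get average ranks."""
    x = np.asarray(x, dtype=float)
    n = x.size
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - c) / (n - 2 * c + 1))


@dataclass
class ContextPseudobulk:
    """Donor x feature pseudobulk per context.

    ``log`` holds log2(CPM+1); ``int`` the per-feature inverse-normal
    transform of it. ``excluded`` records donors dropped for having fewer
    than ``min_cells`` cells in a context.
    """

    feature_ids: list[str]
    log: dict = field(default_factory=dict)    # context label -> DataFrame
    int: dict = field(default_factory=dict)
    n_cells: dict = field(default_factory=dict)  # context label -> Series
    excluded: dict = field(default_factory=dict)
    min_cells: int = 1

    def donors(self, context: str) -> list[str]:
        return list(self.log[context].index)

    def matrix(self, context: str, scale: str = "int") -> pd.DataFrame:
        return {"int": self.int, "log": self.log}[scale][context]

    def contexts(self) -> list[str]:
        return list(self.log)


def pseudobulk(counts: CountMatrix, cells: pd.DataFrame,
               min_cells: int = 10) -> ContextPseudobulk:
    """Sum counts per donor x context, CPM -> log2(x+1) -> per-feature INT."""
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    cell_pos = {c: i for i, c in enumerate(counts.cells)}
    idx = cells["cell_id"].map(cell_pos)
    if idx.isna().any():
        raise ValueError("cell annotation references cells absent from counts")
    row_of = idx.to_numpy()
    pb = ContextPseudobulk(feature_ids=counts.feature_ids, min_cells=min_cells)
    X = counts.counts.tocsr()
    groups = cells.groupby(["cell_type", "time", "donor_id"], sort=True).indices
    by_context: dict[str, list] = {}
    for (ct, t, donor), loc in groups.items():
        by_context.setdefault(f"{ct}_{t}", []).append((donor, row_of[loc]))
    for label in sorted(by_context):
        sums, keep, ncell, dropped = [], [], [], []
        for donor, rows in by_context[label]:
            if len(rows) < min_cells:
                dropped.append(donor)
                continue
            sums.append(np.asarray(X[rows, :].sum(axis=0)).ravel())
            keep.append(donor)
            ncell.append(len(rows))
        if not keep:
            continue
        mat = np.vstack(sums).astype(float)
        libsize = mat.sum(axis=1, keepdims=True)
        libsize[libsize == 0] = 1.0
        logcpm = np.log2(mat / libsize * 1e6 + 1.0)
        pb.log[label] = pd.DataFrame(logcpm, index=keep,
                                     columns=counts.feature_ids)
        intmat = np.apply_along_axis(inverse_normal_transform, 0, logcpm)
        pb.int[label] = pd.DataFrame(intmat, index=keep,
                                     columns=counts.feature_ids)
        pb.n_cells[label] = pd.Series(ncell, index=keep)
        pb.excluded[label] = dropped
        if dropped:
            logger.info("%s: excluded %d donors with < %d cells",
                        label, len(dropped), min_cells)
    return pb


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def genotype_pcs(genotypes: GenotypeMatrix, n_pcs: int = 3) -> pd.DataFrame:
    X = genotypes.dosage.astype(float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    pcs = U[:, :n_pcs] * S[:n_pcs]
    return pd.DataFrame(pcs, index=genotypes.donors,
                        columns=[f"gPC{i+1}" for i in range(pcs.shape[1])])


def expression_pcs(matrix: pd.DataFrame, n_pcs: int = 5) -> pd.DataFrame:
    Z = matrix.to_numpy() - matrix.to_numpy().mean(axis=0)
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    k = min(n_pcs, U.shape[1])
    return pd.DataFrame(U[:, :k] * S[:k], index=matrix.index,
                        columns=[f"ePC{i+1}" for i in range(k)])


def _residualize(Y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Project out columns of C (which must include an intercept)."""
    Q, _ = np.linalg.qr(C)
    return Y - Q @ (Q.T @ Y)


# ---------------------------------------------------------------------------
# per-context cis mapping
# ---------------------------------------------------------------------------

@dataclass
class QtlMapping:
    """Per-context cis mapping output: all tested pairs plus per-feature leads."""

    full: pd.DataFrame    # feature, context, snp, beta, se, p
    leads: pd.DataFrame   # + p_feature (Bonferroni), q (BH across features), egene


def map_qtl(pb: ContextPseudobulk, genotypes: GenotypeMatrix,
            features: list[Feature], context: str, *,
            cis_bp: int | None = None, n_genotype_pcs: int = 3,
            n_phenotype_pcs: int = 5, covariates: pd.DataFrame | None = None,
            scale: str = "int", min_donors: int = 10) -> QtlMapping:
    """OLS cis-QTL scan for one context.

    ``scale="int"`` (default) maps on the inverse-normal transformed
    pseudobulk; ``scale="log"`` keeps the log2-CPM scale, on which planted
    simulator effects are directly comparable to the estimates.
    """
    mat = pb.matrix(context, scale)
    donors = list(mat.index)
    if len(donors) < min_donors:
        raise ValueError(
            f"{context}: only {len(donors)} donors retained (< {min_donors})"
        )
    kind = features[0].kind if features else "gene"
    if cis_bp is None:
        cis_bp = DEFAULT_GENE_CIS_BP if kind == "gene" else DEFAULT_PEAK_CIS_BP

    didx = [genotypes.donor_idx(d) for d in donors]
    G = genotypes.dosage[didx, :].astype(float)

    # shrink the PC set on small cohorts so the OLS keeps >= 5 residual df
    max_pcs = max(0, len(donors) - 7)
    if n_genotype_pcs + n_phenotype_pcs > max_pcs:
        g_new = min(n_genotype_pcs, max_pcs)
        p_new = min(n_phenotype_pcs, max_pcs - g_new)
        logger.warning("%s: %d donors support only %d PCs; using %d genotype "
                       "+ %d phenotype PCs", context, len(donors), max_pcs,
                       g_new, p_new)
        n_genotype_pcs, n_phenotype_pcs = g_new, p_new

    cov_parts = [np.ones((len(donors), 1))]
    if n_genotype_pcs:
        cov_parts.append(genotype_pcs(genotypes, n_genotype_pcs).loc[donors].to_numpy())
    if n_phenotype_pcs:
        cov_parts.append(expression_pcs(mat, n_phenotype_pcs).to_numpy())
    if covariates is not None:
        cov_parts.append(covariates.loc[donors].to_numpy())
    C = np.column_stack(cov_parts)
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariate design is rank-deficient")
    k = C.shape[1]
    n = len(donors)
    dof = n - k - 1
    if dof < 3:
        raise ValueError("too few donors for the covariate set")

    raw_var = G.var(axis=0)
    Gres = _residualize(G, C)
    Yres = _residualize(mat.to_numpy(), C)
    gss = (Gres ** 2).sum(axis=0)

    fid = {f: j for j, f in enumerate(pb.feature_ids)}
    rows = []
    for f in features:
        j = fid.get(f.id)
        if j is None:
            continue
        cis = [i for i, s in enumerate(genotypes.snps)
               if snp_in_cis(s, f, cis_bp)]
        cis = [i for i in cis if raw_var[i] > 0]
        if not cis:
            logger.debug("%s: no cis SNPs, skipped", f.id)
            continue
        for i in cis:
            if gss[i] < 1e-10 * n:
                raise ValueError(
                    f"SNP {genotypes.snps[i].id} is collinear with covariates"
                )
        y = Yres[:, j]
        yss = float(y @ y)
        g = Gres[:, cis]
        gy = g.T @ y
        beta = gy / gss[cis]
        rss = yss - beta * gy
        rss = np.maximum(rss, 0.0)
        sigma2 = rss / dof
        se = np.sqrt(np.maximum(sigma2 / gss[cis], 1e-300))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta / se, 0.0)
        p = 2 * stats.t.sf(np.abs(tstat), dof)
        for c_i, i in enumerate(cis):
            rows.append((f.id, context, genotypes.snps[i].id,
                         beta[c_i], se[c_i], p[c_i], len(cis)))
    full = pd.DataFrame(rows, columns=["feature", "context", "snp", "beta",
                                       "se", "p", "n_cis"])
    if full.empty:
        leads = full.assign(p_feature=[], q=[], egene=[]).drop(columns="n_cis")
        return QtlMapping(full=full.drop(columns="n_cis"), leads=leads)
    lead_idx = full.groupby("feature")["p"].idxmin()
    leads = full.loc[lead_idx].copy()
    leads["p_feature"] = np.minimum(1.0, leads["p"] * leads["n_cis"])
    leads = leads.sort_values("feature").reset_index(drop=True)
    leads["q"] = bh_qvalues(leads["p_feature"].to_numpy())
    leads["egene"] = leads["q"] < 0.05
    return QtlMapping(full=full.drop(columns="n_cis"),
                      leads=leads.drop(columns="n_cis"))


# ---------------------------------------------------------------------------
# random-intercept LMM (REML) for interaction testing
# ---------------------------------------------------------------------------

def _whiten(y, X, donor_codes, counts, lam):
    """Transform (y, X) so the random-intercept GLS becomes OLS.

    For donor blocks of size m: subtract c * block mean with
    c = 1 - 1/sqrt(1 + lam*m), which maps cov = I + lam*J to I.
    """
    c = 1.0 - 1.0 / np.sqrt(1.0 + lam * counts)
    ymean = np.bincount(donor_codes, weights=y) / counts
    yt = y - c[donor_codes] * ymean[donor_codes]
    Xt = np.empty_like(X)
    for j in range(X.shape[1]):
        xm = np.bincount(donor_codes, weights=X[:, j]) / counts
        Xt[:, j] = X[:, j] - c[donor_codes] * xm[donor_codes]
    return yt, Xt


def _reml_neg2ll(lam, y, X, donor_codes, counts, n, p):
    yt, Xt = _whiten(y, X, donor_codes, counts, lam)
    XtX = Xt.T @ Xt
    try:
        beta = np.linalg.solve(XtX, Xt.T @ yt)
    except np.linalg.LinAlgError:
        return np.inf
    rss = float(((yt - Xt @ beta) ** 2).sum())
    if rss <= 0:
        return np.inf
    sign, logdet = np.linalg.slogdet(XtX)
    if sign <= 0:
        return np.inf
    return ((n - p) * np.log(rss) + np.sum(np.log1p(lam * counts)) + logdet)


@dataclass
class LmmFit:
    beta: np.ndarray
    cov: np.ndarray
    lam: float            # variance ratio sigma_u^2 / sigma_e^2
    sigma2_e: float
    df_within: int
    ols_fallback: bool
    columns: list[str]


def fit_random_intercept(y: np.ndarray, X: np.ndarray, donor_codes: np.ndarray,
                         columns: list[str]) -> LmmFit:
    """REML fit of y = X b + u_donor + e with a single random intercept.

    The variance ratio is profiled out and optimized on a log grid; a
    boundary fit (ratio ~ 0) falls back to plain OLS. Wald inference on
    within-donor columns uses the within-donor residual degrees of freedom
    (n_obs - n_donors - #within columns), which is exact for balanced
    designs.
    """
    n, p = X.shape
    counts = np.bincount(donor_codes).astype(float)
    res = optimize.minimize_scalar(
        lambda u: _reml_neg2ll(np.exp(u), y, X, donor_codes, counts, n, p),
        bounds=(-18.0, 10.0), method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(np.exp(res.x))
    ols_fallback = lam < 1e-6
    if ols_fallback:
        lam = 0.0
        logger.debug("variance ratio at boundary; OLS fallback")
    yt, Xt = _whiten(y, X, donor_codes, counts, lam)
    XtX = Xt.T @ Xt
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (Xt.T @ yt)
    rss = float(((yt - Xt @ beta) ** 2).sum())
    sigma2 = rss / (n - p)
    # within-donor columns: those varying within at least one donor
    within = []
    for j in range(p):
        xm = np.bincount(donor_codes, weights=X[:, j]) / counts
        within.append(bool(np.abs(X[:, j] - xm[donor_codes]).max() > 1e-10))
    n_within = int(sum(within))
    df = n - len(counts) - n_within if not ols_fallback else n - p
    df = max(df, 2)
    return LmmFit(beta=beta, cov=sigma2 * XtX_inv, lam=lam, sigma2_e=sigma2,
                  df_within=df, ols_fallback=ols_fallback, columns=columns)


def dynamic_test(pb: ContextPseudobulk, genotypes: GenotypeMatrix,
                 lead_snps: pd.DataFrame, cell_type: str, *,
                 scale: str = "log", alpha: float = 0.05) -> pd.DataFrame:
    """Genotype-by-time interaction test per feature within one cell type.

    ``lead_snps`` has columns (feature, snp), typically the per-context QTL
    leads. Observations from the cell type's time points are stacked; the
    model is ``y ~ G + time + G:time + (1 | donor)`` with 0h as reference.
    Wald tests on the two interaction contrasts (1h-0h, 6h-0h) and a joint
    2-df test are reported; a feature is "dynamic" when any contrast's BH q
    (per cell type) is below ``alpha``.

    The model runs on the log2-CPM scale: interaction contrasts are
    scale-dependent, and the per-context rank-based inverse-normal transform
    (the default for per-context mapping) forces identical marginals on
    every time point, which badly distorts the null distribution of
    genotype-by-time contrasts.
    """
    labels = [f"{cell_type}_{t}" for t in TIME_POINTS]
    missing = [l for l in labels if l not in pb.log]
    if missing:
        raise ValueError(f"missing contexts for {cell_type}: {missing}")
    mats = {l: pb.matrix(l, scale) for l in labels}
    # donors observed at >= 2 time points
    donor_count = pd.concat(
        [pd.Series(1, index=m.index) for m in mats.values()]
    ).groupby(level=0).sum()
    donors = sorted(donor_count[donor_count >= 2].index)
    if len(donors) < 10:
        raise ValueError(f"{cell_type}: fewer than 10 donors with >= 2 time points")
    dcode = {d: i for i, d in enumerate(donors)}

    rows = []
    for r in lead_snps.itertuples(index=False):
        feat, snp = r.feature, r.snp
        try:
            snp_j = genotypes.snp_idx(snp)
        except KeyError:
            logger.warning("lead SNP %s absent from genotypes; skipped", snp)
            continue
        ys, gs, t1, t6, codes = [], [], [], [], []
        for l, t in zip(labels, TIME_POINTS):
            m = mats[l]
            if feat not in m.columns:
                continue
            for d in m.index:
                if d not in dcode:
                    continue
                ys.append(m.at[d, feat])
                gs.append(float(genotypes.dosage[genotypes.donor_idx(d), snp_j]))
                t1.append(1.0 if t == "1h" else 0.0)
                t6.append(1.0 if t == "6h" else 0.0)
                codes.append(dcode[d])
        y = np.array(ys)
        g = np.array(gs)
        t1 = np.array(t1)
        t6 = np.array(t6)
        codes = np.array(codes)
        # re-code donors contiguously for this feature
        uniq, codes = np.unique(codes, return_inverse=True)
        if len(uniq) < 10 or g.std() == 0:
            continue
        X = np.column_stack([np.ones_like(y), g, t1, t6, g * t1, g * t6])
        cols = ["intercept", "G", "t1h", "t6h", "G:t1h", "G:t6h"]
        fit = fit_random_intercept(y, X, codes, cols)
        b = fit.beta
        se = np.sqrt(np.diag(fit.cov))
        tstats = b / se
        p1 = 2 * stats.t.sf(abs(tstats[4]), fit.df_within)
        p6 = 2 * stats.t.sf(abs(tstats[5]), fit.df_within)
        Cmat = np.zeros((2, 6))
        Cmat[0, 4] = 1.0
        Cmat[1, 5] = 1.0
        cb = Cmat @ b
        cvc = Cmat @ fit.cov @ Cmat.T
        fstat = float(cb @ np.linalg.solve(cvc, cb)) / 2.0
        p_joint = stats.f.sf(fstat, 2, fit.df_within)
        rows.append((feat, cell_type, snp, b[4], b[5], p1, p6, p_joint,
                     fit.lam, fit.ols_fallback))
    out = pd.DataFrame(rows, columns=["feature", "cell_type", "snp",
                                      "beta_gxt_1h", "beta_gxt_6h",
                                      "p_1h", "p_6h", "p_joint",
                                      "variance_ratio", "ols_fallback"])
    if out.empty:
        out["q_1h"] = out["q_6h"] = []
        out["dynamic"] = []
        return out
    out["q_1h"] = bh_qvalues(out["p_1h"].to_numpy())
    out["q_6h"] = bh_qvalues(out["p_6h"].to_numpy())
    out["dynamic"] = (out["q_1h"] < alpha) | (out["q_6h"] < alpha)
    return out


# ---------------------------------------------------------------------------
# sharing statistics
# ---------------------------------------------------------------------------

def pi1(pvalues: np.ndarray,
        lambda_grid: np.ndarray | None = None) -> dict:
    """Storey-style estimate of the non-null fraction of a p-value set.

    pi0(lambda) = #{p > lambda} / (n (1 - lambda)); a cubic polynomial
    smoother over the grid is evaluated at the largest lambda, and
    pi1 = 1 - pi0 clipped to [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size < 50:
        raise ValueError("pi1 needs at least 50 p-values")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    grid = (np.arange(0.05, 0.95, 0.05) if lambda_grid is None
            else np.asarray(lambda_grid, dtype=float))
    pi0_grid = np.array([(p > lam).mean() / (1 - lam) for lam in grid])
    coeff = np.polyfit(grid, pi0_grid, 3)
    pi0 = float(np.clip(np.polyval(coeff, grid.max()), 0.0, 1.0))
    return {"pi1": 1.0 - pi0, "pi0": pi0, "lambda_grid": grid, "n": p.size}


def concordance(qtl_a: pd.DataFrame, qtl_b: pd.DataFrame,
                match_on: tuple = ("feature", "snp")) -> dict:
    """Effect-size agreement between two QTL result sets.

    Both frames need columns ``match_on`` + beta; optional ref/alt columns
    trigger allele alignment (beta_b flipped where its effect allele is the
    other set's reference). Reports sign concordance, zero-intercept
    regression slope of beta_b on beta_a, and Pearson r.
    """
    merged = qtl_a.merge(qtl_b, on=list(match_on), suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("no overlapping pairs between result sets")
    beta_b = merged["beta_b"].to_numpy().copy()
    if {"ref_a", "alt_a", "ref_b", "alt_b"}.issubset(merged.columns):
        flipped = (merged["ref_a"] == merged["alt_b"]) & \
                  (merged["alt_a"] == merged["ref_b"])
        beta_b[flipped.to_numpy()] *= -1.0
    beta_a = merged["beta_a"].to_numpy()
    sign_conc = float((np.sign(beta_a) == np.sign(beta_b)).mean())
    slope = float((beta_a @ beta_b) / (beta_a @ beta_a))
    r = float(np.corrcoef(beta_a, beta_b)[0, 1]) if len(beta_a) > 1 else np.nan
    return {"sign_concordance": sign_conc, "slope": slope, "r": r,
            "n_pairs": len(beta_a)}


def sharing_matrix(qtl_by_context: dict[str, QtlMapping],
                   alpha: float = 0.05) -> dict:
    """Pairwise replication fractions and pi1 sharing between contexts.

    For each ordered pair (A, B): the fraction of A's significant features
    whose lead SNP is nominally replicated in B (p < alpha, same sign), and
    the pi1 of A's lead p-values evaluated in B.
    """
    labels = list(qtl_by_context)
    if len(labels) < 2:
        raise ValueError("need at least 2 contexts")
    rep = pd.DataFrame(np.nan, index=labels, columns=labels)
    pi1_mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for a in labels:
        leads_a = qtl_by_context[a].leads
        sig_a = leads_a[leads_a["q"] < alpha]
        for b in labels:
            full_b = qtl_by_context[b].full
            merged = sig_a.merge(full_b, on=["feature", "snp"],
                                 suffixes=("_a", "_b"))
            if merged.empty:
                rep.loc[a, b] = np.nan
                continue
            ok = (merged["p_b"] < alpha) & \
                 (np.sign(merged["beta_a"]) == np.sign(merged["beta_b"]))
            rep.loc[a, b] = float(ok.mean())
            all_pairs = leads_a.merge(full_b, on=["feature", "snp"],
                                      suffixes=("_a", "_b"))
            if len(all_pairs) >= 50:
                pi1_mat.loc[a, b] = pi1(all_pairs["p_b"].to_numpy())["pi1"]
    return {"replication": rep, "pi1": pi1_mat}
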