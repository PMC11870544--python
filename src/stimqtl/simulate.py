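"""Synthetic multiomic data generator with recorded ground truth.

Emulates a stimulation time-course experiment: three neuronal cell types
(GABA, nmglut, npglut) sampled at 0h/1h/6h after depolarization, ~tens of
donors, negative-binomial single-cell counts with donor random intercepts,
temporal gene modules (early pulse vs late induction) with chromatin priming,
planted static and dynamic cis-QTL, allelic read counts at heterozygous SNPs,
TF motif->peak maps, promoter contact maps, and GWAS z-scores generated from
planted causal gene/peak traits under block LD.

Every operation is deterministic given ``design.seed``: each draws from its
own PCG64 stream keyed as ``default_rng([seed, STREAM_CODE])`` so operations
can be called in any order or in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit
from scipy.stats import norm

from .core import (
    CELL_TYPES,
    TIME_POINTS,
    ContactMap,
    CountMatrix,
    Feature,
    GenotypeMatrix,
    GwasSummary,
    SNP,
    validate_cell_annotations,
)

LN2 = float(np.log(2.0))

# per-operation RNG stream codes
_S_LAYOUT, _S_GENO, _S_CELLS, _S_EXPR, _S_ATAC, _S_ALLELE = 0, 1, 2, 3, 4, 5
_S_GWAS, _S_CASE, _S_MOTIF, _S_CONTACT = 6, 7, 8, 9


# ---------------------------------------------------------------------------
# temporal archetypes (functions of pseudotime in [0, 1])
# ---------------------------------------------------------------------------

def _pulse_early(pt):
    return np.exp(-(((pt - 0.45) / 0.12) ** 2))


def _late(pt):
    return expit((pt - 0.65) / 0.08)


def _sustained(pt):
    # rises with the early wave but stays open -- the "primed"/"memory" shape
    return expit((pt - 0.35) / 0.08)


def _down(pt):
    return -expit((pt - 0.5) / 0.1)


def _flat(pt):
    return np.zeros_like(pt)


SHAPES: dict[str, Callable] = {
    "pulse_early": _pulse_early,
    "late": _late,
    "sustained": _sustained,
    "down": _down,
    "flat": _flat,
}


def shifted_shape(name: str, lead: float) -> Callable:
    """Archetype evaluated ``lead`` pseudotime units earlier (lead > 0 means
    the profile is shifted left, i.e. the signal appears earlier)."""
    base = SHAPES[name]
    return lambda pt: base(np.clip(pt + lead, 0.0, 1.0))


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class ModuleSpec:
    """A co-regulated temporal gene module."""

    name: str
    shape: str  # key into SHAPES, shared across cell types unless overridden
    n_genes: int
    amplitude: float = 1.5
    shape_by_celltype: dict | None = None  # optional per-cell-type override


@dataclass
class PlantedQtl:
    """A planted genetic effect on one feature in selected contexts.

    ``beta`` is the additive effect per alt allele on the log2 pseudobulk
    scale; ``contexts`` is a list of context labels (``"GABA_0h"``) or
    ``"all"``.
    """

    feature: str
    snp: str
    beta: float
    contexts: list[str] | str = "all"


@dataclass
class GwasSpec:
    """Which planted QTL features act as causal GWAS traits, by group."""

    causal_genes: list[str] = field(default_factory=list)
    causal_peaks: list[str] = field(default_factory=list)
    causal_snps: list[str] = field(default_factory=list)
    effect_sd_gene: float = 0.05
    effect_sd_peak: float = 0.05
    effect_sd_snp: float = 0.05
    n_gwas: int = 50_000
    fixed_effects: dict = field(default_factory=dict)  # variable id -> effect


@dataclass
class CaseSpec:
    n_cases: int = 0
    de_genes: list[str] = field(default_factory=list)
    de_lfc: float = 1.0  # log2 fold change, case vs control
    de_contexts: list[str] | str = "all"


@dataclass
class SimDesign:
    """Full description of a synthetic experiment (desk-scale defaults)."""

    n_donors: int = 24
    n_snps: int = 2000
    n_genes: int = 600
    n_peaks: int = 800
    cells_per_donor_context: int = 30
    maf_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.5
    ld_block_size: int = 20
    nb_dispersion: float | None = 10.0  # NB size; None => Poisson limit
    donor_sd: float = 0.3  # natural-log donor random-intercept SD
    donor_factor_share: float = 0.5  # fraction of donor variance from a shared factor
    size_factor_sd: float = 0.25
    base_log_mean: float = 0.0   # natural-log mean count per cell ~ exp(N(0, 0.8^2))
    base_log_sd: float = 0.8
    gene_spacing: int = 50_000
    peak_width: int = 500
    pseudotime_beta: dict = field(
        default_factory=lambda: {"0h": (2, 8), "1h": (5, 5), "6h": (8, 2)}
    )
    # None selects the default module set; an empty list disables modules
    module_spec: list | None = None
    peak_module_spec: list | None = None
    qtl_spec: list = field(default_factory=list)       # expression QTL
    caqtl_spec: list = field(default_factory=list)     # accessibility QTL
    asoc_in_peak_fraction: float = 1.0
    asoc_kappa: float = 1.0     # logit(alt fraction) = kappa * caQTL beta
    asoc_depth_factor: float = 0.5  # reads per unit of donor peak pseudobulk
    gwas_spec: GwasSpec = field(default_factory=GwasSpec)
    case_spec: CaseSpec = field(default_factory=CaseSpec)
    n_tfs: int = 30
    seed: int = 0

    def __post_init__(self):
        for name, v in (("n_donors", self.n_donors), ("n_snps", self.n_snps),
                        ("n_genes", self.n_genes), ("n_peaks", self.n_peaks),
                        ("cells_per_donor_context", self.cells_per_donor_context)):
            if v < 1:
                raise ValueError(f"{name} must be >= 1")
        if not abs(self.ld_rho) < 1:
            raise ValueError("|ld_rho| must be < 1")
        for q in list(self.qtl_spec) + list(self.caqtl_spec):
            if not np.isfinite(q.beta):
                raise ValueError("planted beta must be finite")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the data for parameter-recovery tests."""

    module_of: dict = field(default_factory=dict)       # gene -> module name
    peak_module_of: dict = field(default_factory=dict)  # peak -> module name
    qtl: pd.DataFrame | None = None       # feature, snp, context, beta
    caqtl: pd.DataFrame | None = None
    asoc: pd.DataFrame | None = None      # snp, peak, context, alt_fraction
    gwas_causal: pd.DataFrame | None = None  # variable, group, effect
    de_genes: list = field(default_factory=list)
    case_donors: list = field(default_factory=list)
    tf_targets: dict = field(default_factory=dict)      # tf -> [gene ids]

    def to_json(self, path) -> None:
        payload = {
            "module_of": self.module_of,
            "peak_module_of": self.peak_module_of,
            "qtl": self.qtl.to_dict("records") if self.qtl is not None else [],
            "caqtl": self.caqtl.to_dict("records") if self.caqtl is not None else [],
            "asoc": self.asoc.to_dict("records") if self.asoc is not None else [],
            "gwas_causal": (self.gwas_causal.to_dict("records")
                            if self.gwas_causal is not None else []),
            "de_genes": list(self.de_genes),
            "case_donors": list(self.case_donors),
            "tf_targets": {k: list(v) for k, v in self.tf_targets.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# genome layout (deterministic from seed)
# ---------------------------------------------------------------------------

@dataclass
class _Layout:
    genes: list[Feature]
    peaks: list[Feature]
    snp_meta: list[SNP]
    promoter_peak_of: dict  # gene id -> peak id (first n_genes peaks)


def layout(design: SimDesign) -> _Layout:
    """Genes spaced along one chromosome; one promoter peak per gene plus
    distal peaks; one SNP inside every peak, remainder uniform."""
    rng = np.random.default_rng([design.seed, _S_LAYOUT])
    span = (design.n_genes + 2) * design.gene_spacing
    genes = []
    for g in range(design.n_genes):
        tss = (g + 1) * design.gene_spacing
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Feature(id=f"gene{g:04d}", kind="gene", chrom="chr1",
                             tss=tss, strand=strand))
    peaks = []
    promoter_peak_of = {}
    w = design.peak_width
    for j in range(design.n_peaks):
        if j < design.n_genes:
            # promoter peak centred on the gene's TSS
            centre = genes[j].tss
            pid = f"peak{j:04d}"
            promoter_peak_of[genes[j].id] = pid
        else:
            centre = int(rng.integers(w, span - w))
            pid = f"peak{j:04d}"
        peaks.append(Feature(id=pid, kind="peak", chrom="chr1",
                             start=max(0, centre - w // 2),
                             end=max(0, centre - w // 2) + w))
    # SNPs: one inside each peak (up to n_snps), remainder uniform over span
    positions = []
    for p in peaks[: design.n_snps]:
        positions.append(int(rng.integers(p.start + 1, p.end + 1)))  # 1-based
    n_extra = design.n_snps - len(positions)
    if n_extra > 0:
        positions.extend(int(x) for x in rng.integers(1, span, size=n_extra))
    order = np.argsort(positions, kind="stable")
    mafs = rng.uniform(*design.maf_range, size=design.n_snps)
    snp_meta = []
    for rank, k in enumerate(order):
        snp_meta.append(SNP(id=f"rs{k:05d}", chrom="chr1", pos=positions[k],
                            ref="A", alt="G", maf=float(mafs[rank])))
    return _Layout(genes=genes, peaks=peaks, snp_meta=snp_meta,
                   promoter_peak_of=promoter_peak_of)


def snp_in_peak(lay: _Layout, peak_id: str) -> str | None:
    """Id of a SNP falling inside the peak interval, if any."""
    peak = next(p for p in lay.peaks if p.id == peak_id)
    for s in lay.snp_meta:
        if s.chrom == peak.chrom and peak.start < s.pos <= peak.end:
            return s.id
    return None


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(design: SimDesign) -> GenotypeMatrix:
    """Hardy-Weinberg dosages with AR(1) Gaussian-copula LD within blocks.

    Two latent haplotype vectors per donor follow an AR(1)(ld_rho) Gaussian
    within each block of ``ld_block_size`` consecutive SNPs; an allele is alt
    when its latent value falls below the ``Phi^{-1}(maf)`` threshold, so each
    SNP is marginally Binomial(2, maf).
    """
    rng = np.random.default_rng([design.seed, _S_GENO])
    lay = layout(design)
    n, m = design.n_donors, design.n_snps
    rho = design.ld_rho
    thresholds = norm.ppf([s.maf for s in lay.snp_meta])
    dosage = np.zeros((n, m), dtype=np.int8)
    for hap in range(2):
        latent = np.empty((n, m))
        eps = rng.standard_normal((n, m))
        for start in range(0, m, design.ld_block_size):
            stop = min(start + design.ld_block_size, m)
            latent[:, start] = eps[:, start]
            for j in range(start + 1, stop):
                latent[:, j] = rho * latent[:, j - 1] + np.sqrt(1 - rho**2) * eps[:, j]
        dosage += (latent < thresholds[None, :]).astype(np.int8)
    donors = [f"D{i:03d}" for i in range(n)]
    return GenotypeMatrix(donors=donors, snps=lay.snp_meta, dosage=dosage)


def ld_block_indices(design: SimDesign) -> list[np.ndarray]:
    return [np.arange(s, min(s + design.ld_block_size, design.n_snps))
            for s in range(0, design.n_snps, design.ld_block_size)]


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------

def simulate_cells(design: SimDesign) -> pd.DataFrame:
    """One row per cell: donor, cell type, time, pseudotime.

    Pseudotime is drawn per time point from Beta distributions whose means
    increase with stimulation time (defaults Beta(2,8) / Beta(5,5) /
    Beta(8,2)), so cells collected later sit further along the activation
    trajectory on average.
    """
    rng = np.random.default_rng([design.seed, _S_CELLS])
    rows = []
    k = 0
    for d in range(design.n_donors):
        for ct in CELL_TYPES:
            for t in TIME_POINTS:
                a, b = design.pseudotime_beta[t]
                pts = rng.beta(a, b, size=design.cells_per_donor_context)
                for pt in pts:
                    rows.append((f"cell{k:06d}", f"D{d:03d}", ct, t, float(pt)))
                    k += 1
    cells = pd.DataFrame(rows, columns=["cell_id", "donor_id", "cell_type",
                                        "time", "pseudotime"])
    return validate_cell_annotations(cells)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _assign_modules(spec: Sequence[ModuleSpec], n_features: int, prefix: str,
                    rng: np.random.Generator) -> tuple[np.ndarray, dict, list]:
    """Deterministically assign the first sum(n_genes) features to modules."""
    module_idx = np.full(n_features, -1)
    module_of = {}
    mods = list(spec)
    pos = 0
    for mi, mod in enumerate(mods):
        for j in range(pos, min(pos + mod.n_genes, n_features)):
            module_idx[j] = mi
            module_of[f"{prefix}{j:04d}"] = mod.name
        pos += mod.n_genes
    return module_idx, module_of, mods


def _shape_values(mod: ModuleSpec, pt: np.ndarray, cell_type: np.ndarray) -> np.ndarray:
    if mod.shape_by_celltype:
        out = np.zeros_like(pt)
        for ct in CELL_TYPES:
            mask = cell_type == ct
            fn = mod.shape_by_celltype.get(ct, mod.shape)
            fn = SHAPES[fn] if isinstance(fn, str) else fn
            out[mask] = fn(pt[mask])
        return out
    fn = SHAPES[mod.shape] if isinstance(mod.shape, str) else mod.shape
    return fn(pt)


def _nb_draw(mean: np.ndarray, dispersion: float | None,
             rng: np.random.Generator) -> np.ndarray:
    if dispersion is None or not np.isfinite(dispersion):
        return rng.poisson(mean).astype(np.int32)
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam).astype(np.int32)


def _simulate_counts(genotypes: GenotypeMatrix, cells: pd.DataFrame,
                     design: SimDesign, features: list[Feature],
                     module_spec: Sequence[ModuleSpec],
                     qtl_spec: Sequence[PlantedQtl], prefix: str,
                     stream: int, case_shift: bool = False):
    rng = np.random.default_rng([design.seed, stream])
    n_cells, n_feat = len(cells), len(features)
    feat_index = {f.id: j for j, f in enumerate(features)}
    snp_index = {s.id: j for j, s in enumerate(genotypes.snps)}
    donor_index = {d: i for i, d in enumerate(genotypes.donors)}

    mu = rng.normal(design.base_log_mean, design.base_log_sd, size=n_feat)
    module_idx, module_of, mods = _assign_modules(module_spec, n_feat, prefix, rng)
    # donor random intercepts: a factor shared across features (cell-line
    # quality/composition, what phenotype PCs absorb) plus feature-specific noise
    share = design.donor_factor_share
    n_don = len(genotypes.donors)
    factor = rng.standard_normal(n_don)[:, None] * rng.standard_normal(n_feat)[None, :]
    donor_u = design.donor_sd * (
        np.sqrt(share) * factor
        + np.sqrt(1 - share) * rng.standard_normal((n_don, n_feat))
    )
    size_factors = np.exp(rng.normal(0.0, design.size_factor_sd, size=n_cells))

    donor_idx = cells["donor_id"].map(donor_index).to_numpy()
    pt = cells["pseudotime"].to_numpy()
    ct = cells["cell_type"].to_numpy()
    time = cells["time"].to_numpy()
    ctx_label = np.char.add(np.char.add(ct.astype(str), "_"), time.astype(str))

    log_mean = donor_u[donor_idx, :].astype(np.float32)
    log_mean += mu.astype(np.float32)[None, :]
    for mi, mod in enumerate(mods):
        cols = np.where(module_idx == mi)[0]
        if cols.size == 0:
            continue
        vals = (mod.amplitude * _shape_values(mod, pt, ct)).astype(np.float32)
        log_mean[:, cols] += vals[:, None]

    truth_rows = []
    for q in qtl_spec:
        j = feat_index[q.feature]
        g = genotypes.dosage[:, snp_index[q.snp]].astype(float)[donor_idx]
        if q.contexts == "all":
            mask = np.ones(n_cells, dtype=bool)
            ctxs = [f"{c}_{t}" for c in CELL_TYPES for t in TIME_POINTS]
        else:
            mask = np.isin(ctx_label, q.contexts)
            ctxs = list(q.contexts)
        log_mean[mask, j] += np.float32(LN2 * q.beta) * g[mask].astype(np.float32)
        for c in ctxs:
            truth_rows.append((q.feature, q.snp, c, q.beta))

    mean = np.exp(log_mean, dtype=np.float64)
    mean *= size_factors[:, None]
    counts = _nb_draw(mean, design.nb_dispersion, rng)
    cm = CountMatrix(cells=cells["cell_id"].tolist(), features=features,
                     counts=sp.csr_matrix(counts))
    truth = pd.DataFrame(truth_rows, columns=["feature", "snp", "context", "beta"])
    return cm, truth, module_of


def default_gene_modules() -> list[ModuleSpec]:
    return [
        ModuleSpec("early", "pulse_early", 60),
        ModuleSpec("late", "late", 60),
        ModuleSpec("down", "down", 40, amplitude=1.0),
    ]


def default_peak_modules(design: SimDesign) -> list[ModuleSpec]:
    """Peaks mirror the gene modules but with primed (sustained) chromatin:
    accessibility of both early- and late-gene promoter peaks rises by 1h and
    persists, leading late genes (priming) and outlasting early ones (memory).
    """
    return [
        ModuleSpec("early_peaks", "sustained", 60),
        ModuleSpec("late_peaks", "sustained", 60),
        ModuleSpec("down_peaks", "down", 40, amplitude=1.0),
    ]


def simulate_expression(genotypes: GenotypeMatrix, cells: pd.DataFrame,
                        design: SimDesign):
    """Negative-binomial gene counts; returns (CountMatrix, truth table,
    gene -> module dict).

    Per-cell mean: ``s_i * exp(mu_g + amplitude * shape(pt_i) + u_{donor,g}
    + ln2 * beta * dosage)`` with lognormal size factor ``s_i`` and
    donor-by-gene random intercept ``u``. Planted effects (``design.qtl_spec``)
    enter only in their specified contexts; ``beta`` is therefore the additive
    allele effect on the log2 scale.
    """
    lay = layout(design)
    spec = (design.module_spec if design.module_spec is not None
            else default_gene_modules())
    for q in design.qtl_spec:
        if not q.feature.startswith("gene"):
            raise ValueError(f"qtl_spec references non-gene feature {q.feature}")
    cm, truth, module_of = _simulate_counts(
        genotypes, cells, design, lay.genes, spec, design.qtl_spec, "gene",
        _S_EXPR,
    )
    # case-control DE shift, applied post hoc as an extra log2 offset
    cs = design.case_spec
    if cs.n_cases and cs.de_genes:
        case_donors = set(simulate_case_labels(design)[0])
        donor_is_case = cells["donor_id"].isin(case_donors).to_numpy()
        ctx_label = (cells["cell_type"] + "_" + cells["time"]).to_numpy()
        in_ctx = (np.ones(len(cells), bool) if cs.de_contexts == "all"
                  else np.isin(ctx_label, cs.de_contexts))
        mask = donor_is_case & in_ctx
        counts = cm.counts.toarray().astype(float)
        rng = np.random.default_rng([design.seed, _S_CASE, 1])
        fid = {f.id: j for j, f in enumerate(cm.features)}
        for gid in cs.de_genes:
            j = fid[gid]
            extra = counts[mask, j] * (2.0 ** cs.de_lfc - 1.0)
            counts[mask, j] += rng.poisson(extra)
        cm = CountMatrix(cells=cm.cells, features=cm.features,
                         counts=sp.csr_matrix(counts.astype(np.int64)))
    return cm, truth, module_of


def simulate_accessibility(genotypes: GenotypeMatrix, cells: pd.DataFrame,
                           design: SimDesign):
    """Negative-binomial peak counts from the same generative family as
    expression; peak temporal modules implement chromatin priming (sustained
    accessibility from 1h for genes that are only induced at 6h)."""
    lay = layout(design)
    spec = (design.peak_module_spec if design.peak_module_spec is not None
            else default_peak_modules(design))
    cm, truth, module_of = _simulate_counts(
        genotypes, cells, design, lay.peaks, spec, design.caqtl_spec, "peak",
        _S_ATAC,
    )
    return cm, truth, module_of


# ---------------------------------------------------------------------------
# allelic counts
# ---------------------------------------------------------------------------

def simulate_allele_counts(genotypes: GenotypeMatrix, peak_counts: CountMatrix,
                           cells: pd.DataFrame, design: SimDesign) -> pd.DataFrame:
    """Ref/alt read counts at heterozygous donors for planted caQTL SNPs that
    fall inside their peak.

    For each (het donor, context): total reads n ~ Poisson(depth_factor x
    donor pseudobulk count of the peak); alt ~ Binomial(n, p_ctx) with
    logit(p_ctx) = kappa * beta_ctx of the colocated caQTL. Homozygous donors
    emit no rows; zero-read draws emit no rows. Returns the allele count table
    (snp, donor, context, ref_count, alt_count) and records truth in the
    caller's design-derived tables.
    """
    rng = np.random.default_rng([design.seed, _S_ALLELE])
    lay = layout(design)
    pid = {f.id: j for j, f in enumerate(peak_counts.features)}
    counts = peak_counts.counts
    cell_pos = {c: i for i, c in enumerate(peak_counts.cells)}
    ctx_label = (cells["cell_type"] + "_" + cells["time"]).to_numpy()

    # donor x context pseudobulk per relevant peak, computed on the fly
    rows = []
    truth_rows = []
    for q in design.caqtl_spec:
        peak = q.feature
        snp_id = q.snp
        if snp_id not in {s.id for s in lay.snp_meta}:
            continue
        snp_j = genotypes.snp_idx(snp_id)
        pk = next(p for p in lay.peaks if p.id == peak)
        snp = genotypes.snps[snp_j]
        if not (pk.start < snp.pos <= pk.end):
            continue  # ASoC only arises for variants inside the open region
        j = pid[peak]
        col = np.asarray(counts[:, j].todense()).ravel()
        for di, donor in enumerate(genotypes.donors):
            if genotypes.dosage[di, snp_j] != 1:
                continue
            donor_mask = (cells["donor_id"] == donor).to_numpy()
            for ctx in np.unique(ctx_label):
                in_ctx = (q.contexts == "all") or (ctx in q.contexts)
                beta_ctx = q.beta if in_ctx else 0.0
                p_alt = expit(design.asoc_kappa * beta_ctx)
                cmask = donor_mask & (ctx_label == ctx)
                idx = [cell_pos[c] for c in cells.loc[cmask, "cell_id"]]
                pb = float(col[idx].sum())
                n = int(rng.poisson(design.asoc_depth_factor * pb))
                if n == 0:
                    continue
                alt = int(rng.binomial(n, p_alt))
                rows.append((snp_id, donor, ctx, n - alt, alt))
                truth_rows.append((snp_id, peak, ctx, p_alt))
    table = pd.DataFrame(rows, columns=["snp", "donor", "context",
                                        "ref_count", "alt_count"])
    truth = (pd.DataFrame(truth_rows,
                          columns=["snp", "peak", "context", "alt_fraction"])
             .drop_duplicates())
    return table, truth


# ---------------------------------------------------------------------------
# GWAS
# ---------------------------------------------------------------------------

def empirical_block_ld(genotypes: GenotypeMatrix, blocks: list[np.ndarray],
                       shrink: float = 0.05) -> list[tuple[np.ndarray, np.ndarray]]:
    """Regularized dosage correlation per block: (1-shrink) R_hat + shrink I."""
    out = []
    X = genotypes.dosage.astype(float)
    for idx in blocks:
        sub = X[:, idx]
        sd = sub.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (sub - sub.mean(axis=0)) / sd
        R = (Z.T @ Z) / len(Z)
        R = (1 - shrink) * R + shrink * np.eye(len(idx))
        np.fill_diagonal(R, 1.0)
        out.append((idx, R))
    return out


def draw_gwas_z(b: np.ndarray, blocks: list[tuple[np.ndarray, np.ndarray]],
                n_gwas: int, rng: np.random.Generator) -> np.ndarray:
    """Summary z-scores per LD block: z = sqrt(n) R b + eps, eps ~ N(0, R).

    ``b`` holds standardized per-SNP effects; a singular block correlation is
    ridge-regularized before the Cholesky draw (declared jitter).
    """
    z = np.zeros(len(b))
    sqrt_n = np.sqrt(n_gwas)
    for idx, R in blocks:
        try:
            Lc = np.linalg.cholesky(R)
        except np.linalg.LinAlgError:
            Lc = np.linalg.cholesky(R + 1e-4 * np.eye(len(idx)))
        eps = Lc @ rng.standard_normal(len(idx))
        z[idx] = sqrt_n * (R @ b[idx]) + eps
    return z


def simulate_gwas(genotypes: GenotypeMatrix, design: SimDesign,
                  expr_truth: pd.DataFrame | None = None,
                  atac_truth: pd.DataFrame | None = None) -> tuple[GwasSummary, pd.DataFrame]:
    """GWAS z-scores under block LD: per block, z = sqrt(n) R b + eps,
    eps ~ N(0, R), where b holds standardized per-SNP effects induced by the
    planted causal traits (trait effect x normalized single-SNP weight) plus
    direct causal SNP effects."""
    rng = np.random.default_rng([design.seed, _S_GWAS])
    spec = design.gwas_spec
    blocks = empirical_block_ld(genotypes, ld_block_indices(design))
    m = design.n_snps
    b = np.zeros(m)
    causal_rows = []

    def _lead_snp(feature, truth):
        if truth is None:
            return None
        sub = truth[truth["feature"] == feature]
        return None if sub.empty else sub["snp"].iloc[0]

    for gid in spec.causal_genes:
        s = _lead_snp(gid, expr_truth)
        if s is None:
            continue
        eff = spec.fixed_effects.get(gid, rng.normal(0.0, spec.effect_sd_gene))
        b[genotypes.snp_idx(s)] += eff
        causal_rows.append((gid, "gene", eff))
    for pid_ in spec.causal_peaks:
        s = _lead_snp(pid_, atac_truth)
        if s is None:
            continue
        eff = spec.fixed_effects.get(pid_, rng.normal(0.0, spec.effect_sd_peak))
        b[genotypes.snp_idx(s)] += eff
        causal_rows.append((pid_, "peak", eff))
    for s in spec.causal_snps:
        eff = spec.fixed_effects.get(s, rng.normal(0.0, spec.effect_sd_snp))
        b[genotypes.snp_idx(s)] += eff
        causal_rows.append((s, "snp", eff))

    z = draw_gwas_z(b, blocks, spec.n_gwas, rng)
    gwas = GwasSummary(snp_ids=[s.id for s in genotypes.snps], z=z,
                       n_gwas=spec.n_gwas, ld_blocks=blocks)
    truth = pd.DataFrame(causal_rows, columns=["variable", "group", "effect"])
    return gwas, truth


# ---------------------------------------------------------------------------
# case/control labels, motif map, contacts
# ---------------------------------------------------------------------------

def simulate_case_labels(design: SimDesign) -> tuple[list[str], list[str]]:
    """Deterministic (case donors, control donors) split under the seed."""
    cs = design.case_spec
    if cs.n_cases > design.n_donors:
        raise ValueError("n_cases exceeds n_donors")
    rng = np.random.default_rng([design.seed, _S_CASE])
    donors = [f"D{i:03d}" for i in range(design.n_donors)]
    perm = rng.permutation(design.n_donors)
    cases = sorted(donors[i] for i in perm[: cs.n_cases])
    controls = sorted(set(donors) - set(cases))
    return cases, controls


def simulate_motif_map(design: SimDesign, gene_modules: dict,
                       peak_modules: dict,
                       planted_tf_targets: dict | None = None) -> tuple[pd.DataFrame, dict]:
    """TF -> peak assignments.

    Planted regulator TFs get the promoter peaks of their target genes (so
    their motif activity tracks the targets' chromatin program). The
    remaining TFs model factors without a role in the activation response:
    their motifs land in constitutive (non-module) peaks, so their motif
    activity carries no temporal signal.
    """
    rng = np.random.default_rng([design.seed, _S_MOTIF])
    lay = layout(design)
    rows = []
    tf_targets = dict(planted_tf_targets or {})
    for tf, targets in tf_targets.items():
        for g in targets:
            pk = lay.promoter_peak_of.get(g)
            if pk is not None:
                rows.append((tf, pk))
    sizes = [len(v) for v in tf_targets.values()] or [50]
    n_null = design.n_tfs - len(tf_targets)
    module_peaks = set(peak_modules or ())
    null_pool = [p.id for p in lay.peaks if p.id not in module_peaks]
    for t in range(max(0, n_null)):
        tf = f"TFnull{t:03d}"
        size = min(int(rng.choice(sizes)), len(null_pool))
        for pk in rng.choice(null_pool, size=size, replace=False):
            rows.append((tf, pk))
        tf_targets.setdefault(tf, [])
    return pd.DataFrame(rows, columns=["tf", "peak"]), tf_targets


def simulate_contacts(design: SimDesign, bin_size: int = 5000,
                      decay_bp: float = 50_000,
                      enhancer_boost: float = 5.0,
                      max_dist: int = 500_000) -> ContactMap:
    """Promoter-anchored contact records per time point.

    Contact frequency decays exponentially with genomic distance; the contact
    between a gene's TSS bin and its own promoter peak bin (and any planted
    enhancer) is boosted, mimicking focal promoter-enhancer loops.
    """
    rng = np.random.default_rng([design.seed, _S_CONTACT])
    lay = layout(design)
    rows = []

    def _bin(pos: int) -> tuple[int, int]:
        b = (pos // bin_size) * bin_size
        return b, b + bin_size

    for g in lay.genes:
        tss_bin = _bin(g.tss)
        for p in lay.peaks:
            centre = (p.start + p.end) // 2
            dist = abs(centre - g.tss)
            if dist > max_dist:
                continue
            peak_bin = _bin(centre)
            base = np.exp(-dist / decay_bp)
            boost = enhancer_boost if lay.promoter_peak_of.get(g.id) == p.id else 1.0
            for t in TIME_POINTS:
                freq = base * boost * float(rng.lognormal(0, 0.1))
                rows.append(("chr1", *tss_bin, "chr1", *peak_bin, freq, t))
    df = pd.DataFrame(rows, columns=["chrom_a", "start_a", "end_a", "chrom_b",
                                     "start_b", "end_b", "freq", "time"])
    return ContactMap(df)


# ---------------------------------------------------------------------------
# whole-experiment driver
# ---------------------------------------------------------------------------

def simulate_all(design: SimDesign, out_dir=None):
    """Generate every input the pipeline consumes, plus ground truth.

    Returns a dict of in-memory objects; when ``out_dir`` is given, also
    writes the standard on-disk formats (MTX + TSV sidecars, genotype TSV,
    BED peaks, gene model TSV, cell annotation TSV, allele counts TSV, motif
    map TSV, contact TSV, GWAS TSV + LD TSV, truth.json).
    """
    from . import io as sio

    genotypes = simulate_genotypes(design)
    cells = simulate_cells(design)
    expr, expr_truth, gene_modules = simulate_expression(genotypes, cells, design)
    atac, atac_truth, peak_modules = simulate_accessibility(genotypes, cells, design)
    allele_counts, asoc_truth = simulate_allele_counts(genotypes, atac, cells, design)
    gwas, gwas_truth = simulate_gwas(genotypes, design, expr_truth, atac_truth)
    cases, controls = simulate_case_labels(design)
    motif_map, tf_targets = simulate_motif_map(design, gene_modules, peak_modules)
    contacts = simulate_contacts(design)

    truth = SimTruth(
        module_of=gene_modules, peak_module_of=peak_modules,
        qtl=expr_truth, caqtl=atac_truth, asoc=asoc_truth,
        gwas_causal=gwas_truth, de_genes=list(design.case_spec.de_genes),
        case_donors=cases, tf_targets=tf_targets,
    )
    result = {
        "genotypes": genotypes, "cells": cells, "expression": expr,
        "accessibility": atac, "allele_counts": allele_counts, "gwas": gwas,
        "cases": cases, "controls": controls, "motif_map": motif_map,
        "contacts": contacts, "truth": truth,
    }
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sio.write_count_matrix(expr, out / "expression.mtx",
                               out / "expression_features.tsv",
                               out / "barcodes.tsv")
        sio.write_count_matrix(atac, out / "accessibility.mtx",
                               out / "accessibility_features.tsv",
                               out / "barcodes_atac.tsv")
        sio.write_genotypes_tsv(genotypes, out / "genotypes.tsv")
        lay = layout(design)
        sio.write_bed(lay.peaks, out / "peaks.bed")
        sio.write_gene_models(lay.genes, out / "genes.tsv")
        sio.write_cell_annotations(cells, out / "cells.tsv")
        allele_counts.to_csv(out / "allele_counts.tsv", sep="\t", index=False)
        sio.write_motif_map(motif_map, out / "motif_map.tsv")
        sio.write_contacts(contacts, out / "contacts.tsv")
        sio.write_gwas(gwas, out / "gwas.tsv", out / "gwas_ld.tsv")
        pd.DataFrame({"donor": cases + controls,
                      "status": ["case"] * len(cases) + ["control"] * len(controls)}
                     ).to_csv(out / "case_labels.tsv", sep="\t", index=False)
        truth.to_json(out / "truth.json")
    return result


# ---------------------------------------------------------------------------
# stand-alone fine-mapping block generator
# ---------------------------------------------------------------------------

def simulate_finemap_blocks(n_blocks: int, *, snps_per_block: int = 20,
                            genes_per_block: int = 2, peaks_per_block: int = 0,
                            pi_snp: float = 0.01, pi_gene: float = 0.3,
                            pi_peak: float = 0.0, sigma2: float = 25.0,
                            rho: float = 0.4, seed: int = 0):
    """Synthetic GWAS fine-mapping blocks with known causal status.

    Each block holds AR(1)(rho)-correlated SNPs plus molecular traits whose
    single-SNP weights point at distinct SNPs of the block. Every variable is
    causal independently with its group's prior probability pi_k; causal
    standardized z-effects are N(0, sigma2) (on the z scale, so a causal
    variable contributes z ~ N(0, 1 + sigma2) marginally). Returns a list of
    dicts with keys: ids, groups, z, R, causal (bool array).
    """
    rng = np.random.default_rng([seed, 17])
    blocks = []
    for bi in range(n_blocks):
        p_snp = snps_per_block
        R = rho ** np.abs(np.subtract.outer(np.arange(p_snp), np.arange(p_snp)))
        n_traits = genes_per_block + peaks_per_block
        # traits are perfect single-SNP proxies of distinct anchor SNPs
        anchors = rng.choice(p_snp, size=n_traits, replace=False)
        groups = (["snp"] * p_snp + ["gene"] * genes_per_block
                  + ["peak"] * peaks_per_block)
        p_all = p_snp + n_traits
        # augmented correlation: trait == its anchor SNP
        R_aug = np.eye(p_all)
        R_aug[:p_snp, :p_snp] = R
        for t, a in enumerate(anchors):
            R_aug[p_snp + t, :p_snp] = R[a, :]
            R_aug[:p_snp, p_snp + t] = R[:, a]
            for t2, a2 in enumerate(anchors[:t]):
                R_aug[p_snp + t, p_snp + t2] = R[a, a2]
                R_aug[p_snp + t2, p_snp + t] = R[a, a2]
        pis = np.array([{"snp": pi_snp, "gene": pi_gene, "peak": pi_peak}[g]
                        for g in groups])
        causal = rng.random(p_all) < pis
        b = np.zeros(p_all)
        b[causal] = rng.normal(0.0, np.sqrt(sigma2), size=int(causal.sum()))
        # fold trait effects onto their anchor SNPs for the z draw
        b_snp = b[:p_snp].copy()
        for t, a in enumerate(anchors):
            b_snp[a] += b[p_snp + t]
        Lc = np.linalg.cholesky(R + 1e-9 * np.eye(p_snp))
        z_snp = R @ b_snp + Lc @ rng.standard_normal(p_snp)
        z_trait = np.array([z_snp[a] for a in anchors])
        z = np.concatenate([z_snp, z_trait])
        ids = [f"b{bi}_snp{j}" for j in range(p_snp)] + \
              [f"b{bi}_trait{t}" for t in range(n_traits)]
        blocks.append({"ids": ids, "groups": groups, "z": z, "R": R_aug,
                       "causal": causal, "anchors": anchors})
    return blocks
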