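"""Peak-gene linkage by co-activation correlation and activity-by-contact
(ABC) scoring, plus the overlap enrichment between the two.

Co-activation links correlate a peak's accessibility with a gene's expression
across pseudotime-ordered metacells of one cell type. ABC scores combine a
peak's accessibility (activity) with its chromatin contact frequency to the
gene's TSS, normalized per gene so candidate scores sum to one.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core import ContactMap, CountMatrix, Feature, bh_qvalues
from .differential import geneset_enrichment  # shared fold/Fisher machinery

logger = logging.getLogger("stimqtl")

DEFAULT_LINK_WINDOW_BP = 250_000
DEFAULT_ABC_WINDOW_BP = 500_000
DEFAULT_ABC_THRESHOLD = 0.02


def _metacell_matrix(counts: CountMatrix, order: np.ndarray,
                     n_metacells: int) -> np.ndarray:
    """Sum counts over contiguous equal-size pseudotime-ordered groups, then
    log1p CPM-normalize per metacell."""
    groups = np.array_split(order, n_metacells)
    X = counts.counts.tocsr()
    mat = np.vstack([np.asarray(X[g, :].sum(axis=0)).ravel() for g in groups])
    lib = mat.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    return np.log1p(mat / lib * 1e6)


def link_peaks(expr: CountMatrix, peaks: CountMatrix, cells: pd.DataFrame,
               genes: list[Feature], cell_type: str, *,
               window_bp: int = DEFAULT_LINK_WINDOW_BP,
               n_metacells: int = 50, alpha: float = 0.05,
               keep_all: bool = False) -> pd.DataFrame:
    """Co-activation peak-gene pairs for one cell type.

    Cells are ordered by pseudotime and aggregated into ``n_metacells``
    contiguous groups; Pearson r between log1p-CPM metacell vectors is
    computed for every candidate (peak within ``window_bp`` of the gene TSS),
    with p from the t approximation and BH q per cell type. Only pairs with
    q < ``alpha`` are returned unless ``keep_all``.
    """
    if n_metacells < 5:
        raise ValueError("n_metacells must be >= 5")
    sub = cells[cells["cell_type"] == cell_type]
    if sub.empty:
        raise ValueError(f"no cells of type {cell_type}")
    cell_pos_e = {c: i for i, c in enumerate(expr.cells)}
    cell_pos_p = {c: i for i, c in enumerate(peaks.cells)}
    ordered = sub.sort_values("pseudotime", kind="stable")
    rows_e = ordered["cell_id"].map(cell_pos_e).to_numpy()
    rows_p = ordered["cell_id"].map(cell_pos_p).to_numpy()
    E = _metacell_matrix(expr, rows_e, n_metacells)
    P = _metacell_matrix(peaks, rows_p, n_metacells)

    Ez = E - E.mean(axis=0)
    Pz = P - P.mean(axis=0)
    Esd = Ez.std(axis=0)
    Psd = Pz.std(axis=0)

    gid = {f.id: j for j, f in enumerate(expr.features)}
    peak_feats = peaks.features
    starts = np.array([p.start for p in peak_feats])
    ends = np.array([p.end for p in peak_feats])
    chroms = np.array([p.chrom for p in peak_feats])

    n = n_metacells
    out_rows = []
    for g in genes:
        j = gid.get(g.id)
        if j is None or Esd[j] == 0:
            continue
        lo, hi = g.tss - window_bp, g.tss + window_bp
        cand = np.where((chroms == g.chrom) & (starts < hi) & (ends > lo - 1))[0]
        for k in cand:
            if Psd[k] == 0:
                continue
            r = float((Ez[:, j] @ Pz[:, k]) / (n * Esd[j] * Psd[k]))
            r = max(min(r, 1.0), -1.0)
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1 - r * r))
                p = 2 * stats.t.sf(abs(t), n - 2)
            out_rows.append((peak_feats[k].id, g.id, cell_type, r, p))
    out = pd.DataFrame(out_rows, columns=["peak", "gene", "cell_type", "r", "p"])
    if out.empty:
        return out.assign(q=[])
    out["q"] = bh_qvalues(out["p"].to_numpy())
    return out if keep_all else out[out["q"] < alpha].reset_index(drop=True)


def abc_scores(peak_pseudobulk: pd.Series, peaks: list[Feature],
               contacts: ContactMap, genes: list[Feature], time: str, *,
               candidate_window_bp: int = DEFAULT_ABC_WINDOW_BP,
               contact_pseudocount: float = 0.1,
               bin_size: int = 5000) -> pd.DataFrame:
    """Activity-by-contact enhancer-gene scores at one time point.

    activity A = mean normalized accessibility of the peak (``peak_pseudobulk``
    indexed by peak id); contact C = contact frequency between the peak's bin
    and the TSS bin plus a pseudocount; score = A*C / sum over the gene's
    candidate peaks. Genes with no candidate peak are omitted.
    """

    def _bin(pos: int) -> tuple[int, int]:
        b = (pos // bin_size) * bin_size
        return b, b + bin_size

    rows = []
    for g in genes:
        tss_bin = _bin(g.tss)
        cand = []
        for p in peaks:
            centre = (p.start + p.end) // 2
            if p.chrom != g.chrom or abs(centre - g.tss) > candidate_window_bp:
                continue
            A = float(peak_pseudobulk.get(p.id, 0.0))
            C = contacts.query((g.chrom, *tss_bin), (g.chrom, *_bin(centre)),
                               time) + contact_pseudocount
            cand.append((p.id, A, max(C, 0.0)))
        if not cand:
            logger.debug("%s: no ABC candidates", g.id)
            continue
        total = sum(a * c for _, a, c in cand)
        for pid, a, c in cand:
            score = a * c / total if total > 0 else 0.0
            rows.append((pid, g.id, time, a, c, score))
    return pd.DataFrame(rows, columns=["peak", "gene", "time", "activity",
                                       "contact", "score"])


def overlap_enrichment(linked: pd.DataFrame, abc: pd.DataFrame,
                       score_threshold: float = DEFAULT_ABC_THRESHOLD) -> dict:
    """Enrichment of co-activation links among ABC-supported pairs.

    The universe is all ABC candidate pairs; a pair is "linked" when present
    in ``linked`` and "ABC-positive" when its score >= threshold. Reports the
    overlap fraction among linked pairs, the fold enrichment and the
    two-sided Fisher p.
    """
    if linked.empty or abc.empty:
        raise ValueError("empty linked or ABC input")
    universe = set(zip(abc["peak"], abc["gene"]))
    linked_pairs = set(zip(linked["peak"], linked["gene"])) & universe
    abc_pos = set(zip(abc.loc[abc["score"] >= score_threshold, "peak"],
                      abc.loc[abc["score"] >= score_threshold, "gene"]))
    if not linked_pairs:
        raise ValueError("no linked pairs inside the ABC candidate universe")
    enr = geneset_enrichment(
        hit_genes=linked_pairs, set_genes=abc_pos & universe,
        background_genes=universe,
    )
    overlap_fraction = len(linked_pairs & abc_pos) / len(linked_pairs)
    return {"overlap_fraction": overlap_fraction, "fold": enr["fold"],
            "odds_ratio": enr["odds_ratio"], "p": enr["p"],
            "n_linked": len(linked_pairs), "n_abc_positive": len(abc_pos)}
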