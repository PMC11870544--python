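"""Pseudotime binning, temporal module clustering, and expression-chromatin
concordance (priming / memory detection).

Cells are ordered along an activation pseudotime in [0, 1]; per-feature
profiles are bin means of library-normalized log1p counts over uniform
pseudotime bins, z-scored across bins. Genes are clustered on their
concatenated per-cell-type profiles with k-means. Accessibility-vs-expression
cross-correlation at signed lags classifies genes as concordant, primed
(chromatin leads expression) or carrying chromatin memory (accessibility
persists after expression has returned to baseline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .core import CELL_TYPES, CountMatrix, Feature

logger = logging.getLogger("stimqtl")

DEFAULT_N_BINS = 100


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_pseudotime(counts: CountMatrix, cells: pd.DataFrame, cell_type: str,
                   n_bins: int = DEFAULT_N_BINS,
                   max_empty_fraction: float = 0.5,
                   normalize: str = "cpm") -> pd.DataFrame:
    """Per-feature z-scored mean profile over uniform pseudotime bins.

    Bin i covers [i/n, (i+1)/n) with the last bin closed at 1. Values are
    log1p of counts scaled to a common library size of 1e4 per cell
    (``normalize="cpm"``). With ``normalize="none"`` raw log1p counts are
    binned instead: per-cell totals on a stimulation trajectory carry the
    activation program itself, and dividing by them shifts the apparent
    timing of every profile, so timing-sensitive analyses (chromatin-lead
    estimation) should bin unscaled counts and let the within-bin averaging
    absorb depth noise. Empty bins are linearly interpolated from their
    neighbours (edge empties carry the nearest value). Returns a feature x
    bin DataFrame.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if normalize not in ("cpm", "none"):
        raise ValueError("normalize must be 'cpm' or 'none'")
    sub = cells[cells["cell_type"] == cell_type]
    if sub.empty:
        raise ValueError(f"no cells of type {cell_type}")
    cell_pos = {c: i for i, c in enumerate(counts.cells)}
    rows = sub["cell_id"].map(cell_pos).to_numpy()
    pt = sub["pseudotime"].to_numpy()
    bins = np.minimum((pt * n_bins).astype(int), n_bins - 1)

    X = counts.counts[rows, :].toarray().astype(float)
    if normalize == "cpm":
        lib = X.sum(axis=1, keepdims=True)
        lib[lib == 0] = 1.0
        X = np.log1p(X / lib * 1e4)
    else:
        X = np.log1p(X)

    n_feat = X.shape[1]
    profile = np.zeros((n_bins, n_feat))
    occupancy = np.bincount(bins, minlength=n_bins).astype(float)
    empty = occupancy == 0
    if empty.mean() > max_empty_fraction:
        raise ValueError(
            f"{cell_type}: {empty.mean():.0%} of pseudotime bins are empty"
        )
    for b in range(n_bins):
        if occupancy[b]:
            profile[b] = X[bins == b].mean(axis=0)
    if empty.any():
        filled = np.where(~empty)[0]
        for j in range(n_feat):
            profile[empty, j] = np.interp(np.where(empty)[0], filled,
                                          profile[filled, j])
        logger.info("%s: interpolated %d empty bins", cell_type, int(empty.sum()))
    mean = profile.mean(axis=0)
    sd = profile.std(axis=0)
    ok = sd > 1e-9 * (np.abs(mean) + 1.0)  # constant profiles -> all zeros
    z = np.where(ok, (profile - mean) / np.where(ok, sd, 1.0), 0.0)
    return pd.DataFrame(z.T, index=counts.feature_ids,
                        columns=[f"bin{b:03d}" for b in range(n_bins)])


# ---------------------------------------------------------------------------
# variable DEG selection and module clustering
# ---------------------------------------------------------------------------

def select_variable_degs(diff_results: pd.DataFrame,
                         fc_threshold: float = 2.0,
                         alpha: float = 0.05) -> list[str]:
    """Genes with |log2FC| > log2(fc_threshold) and q < alpha in >= 1 contrast."""
    if diff_results.empty:
        return []
    hits = diff_results[
        (diff_results["lfc"].abs() > np.log2(fc_threshold))
        & (diff_results["q"] < alpha)
    ]
    return sorted(hits["feature"].unique())


@dataclass
class ModuleAssignment:
    assignment: pd.Series      # gene -> cluster id (1..k)
    cluster_means: pd.DataFrame  # cluster x (3 * n_bins)
    inertia: float

    def ari(self, truth: dict[str, object]) -> float:
        common = [g for g in self.assignment.index if g in truth]
        return adjusted_rand_score(
            [truth[g] for g in common], self.assignment.loc[common].to_list()
        )


def cluster_modules(profiles_by_celltype: dict[str, pd.DataFrame],
                    genes: list[str], k: int = 15, n_init: int = 20,
                    seed: int = 0) -> ModuleAssignment:
    """K-means over concatenated per-cell-type z-profiles (3 x n_bins).

    Genes lacking a profile in any cell type are dropped with a log note.
    The default k mirrors the characteristic count of temporal programs in
    stimulated neuron types; it is a parameter, not an estimate.
    """
    missing_ct = [ct for ct in CELL_TYPES if ct not in profiles_by_celltype]
    if missing_ct:
        raise ValueError(f"profiles missing for cell types {missing_ct}")
    kept, mat = [], []
    for g in genes:
        parts = []
        for ct in CELL_TYPES:
            prof = profiles_by_celltype[ct]
            if g not in prof.index:
                break
            parts.append(prof.loc[g].to_numpy())
        else:
            kept.append(g)
            mat.append(np.concatenate(parts))
    dropped = len(genes) - len(kept)
    if dropped:
        logger.info("cluster_modules: dropped %d genes without full profiles",
                    dropped)
    if k > len(kept):
        raise ValueError(f"k={k} exceeds {len(kept)} genes with profiles")
    M = np.vstack(mat)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(M)
    assignment = pd.Series(km.labels_ + 1, index=kept, name="cluster")
    means = pd.DataFrame(km.cluster_centers_,
                         index=np.arange(1, k + 1))
    return ModuleAssignment(assignment=assignment, cluster_means=means,
                            inertia=float(km.inertia_))


# ---------------------------------------------------------------------------
# gene activity from peak counts
# ---------------------------------------------------------------------------

def gene_activity_score(peak_counts: CountMatrix, genes: list[Feature],
                        promoter_bp: int = 2000,
                        body: bool = False,
                        gene_spans: dict[str, tuple[int, int]] | None = None
                        ) -> CountMatrix:
    """Per-cell gene activity: summed counts of peaks overlapping the
    promoter window [tss - promoter_bp, tss + promoter_bp] (1-based,
    inclusive) and optionally the gene body span (0-based half-open,
    via ``gene_spans``). Overlap means any shared base."""
    peaks = peak_counts.features
    starts = np.array([p.start for p in peaks])
    ends = np.array([p.end for p in peaks])
    chroms = np.array([p.chrom for p in peaks])
    X = peak_counts.counts.tocsc()
    cols = []
    import scipy.sparse as sp

    for g in genes:
        # promoter window converted to 0-based half-open
        win_lo = max(0, g.tss - promoter_bp - 1)
        win_hi = g.tss + promoter_bp
        hit = (chroms == g.chrom) & (starts < win_hi) & (ends > win_lo)
        if body and gene_spans and g.id in gene_spans:
            b_lo, b_hi = gene_spans[g.id]
            hit |= (chroms == g.chrom) & (starts < b_hi) & (ends > b_lo)
        idx = np.where(hit)[0]
        if idx.size:
            cols.append(np.asarray(X[:, idx].sum(axis=1)).ravel())
        else:
            cols.append(np.zeros(len(peak_counts.cells)))
    out_feats = [Feature(id=g.id, kind="gene", chrom=g.chrom, tss=g.tss,
                         strand=g.strand) for g in genes]
    mat = sp.csr_matrix(np.column_stack(cols) if cols
                        else np.zeros((len(peak_counts.cells), 0)))
    return CountMatrix(cells=list(peak_counts.cells), features=out_feats,
                       counts=mat)


# ---------------------------------------------------------------------------
# expression / accessibility concordance
# ---------------------------------------------------------------------------

def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="same")[pad:pad + x.size]


def concordance(expr_profile: np.ndarray, activity_profile: np.ndarray,
                max_lag: int = 20, lag_min: int = 5,
                tail_bins: int = 20, tail_level: float = 0.5,
                smooth_window: int = 7, curve_window: int = 7) -> dict:
    """Lag between a gene's chromatin and expression profiles, and its class.

    lag = argmax over shifts s in [-max_lag, max_lag] of the correlation
    between activity shifted by s and expression; negative lag means
    chromatin leads. Profiles are boxcar-smoothed over ``smooth_window``
    bins before the lag scan, which stabilizes the argmax against bin noise
    without moving it for shapes that vary over more bins than the window.
    Classes: "memory" when expression has decayed in the final
    ``tail_bins`` (tail z < 0) while activity stays above ``tail_level``
    SD; else "priming" when lag <= -lag_min; else "concordant". Inputs must
    be equal-length z-scored profiles.
    """
    e = np.atleast_2d(np.asarray(expr_profile, dtype=float))
    a = np.atleast_2d(np.asarray(activity_profile, dtype=float))
    if e.shape != a.shape:
        raise ValueError("profiles must have equal length")
    e = np.vstack([_smooth(row, smooth_window) for row in e])
    a = np.vstack([_smooth(row, smooth_window) for row in a])
    n = e.shape[1]
    shifts = np.arange(-max_lag, max_lag + 1)
    curve = np.empty(shifts.size)
    for si, s in enumerate(shifts):
        # lag s compares a(t) with e(t - s): s = -10 is maximal when the
        # activity profile anticipates expression by 10 bins; 2-d inputs are
        # replicate profile pairs (e.g. per cell type) whose correlations are
        # averaged per lag
        if s < 0:
            av, ev = a[:, : n + s], e[:, -s:]
        elif s > 0:
            av, ev = a[:, s:], e[:, : n - s]
        else:
            av, ev = a, e
        rs = []
        for av_r, ev_r in zip(av, ev):
            if av_r.std() == 0 or ev_r.std() == 0:
                rs.append(0.0)
            else:
                rs.append(float(np.corrcoef(av_r, ev_r)[0, 1]))
        curve[si] = float(np.mean(rs))
    # the correlation-vs-lag curve is smooth for binned profiles; a light
    # boxcar over it stabilizes the argmax against per-lag noise wiggles
    smoothed = _smooth(curve, curve_window)
    best_i = int(np.argmax(smoothed))
    best_lag = int(shifts[best_i])
    best_r = float(curve[best_i])
    tail_e = float(e[:, -tail_bins:].mean())
    tail_a = float(a[:, -tail_bins:].mean())
    if tail_e < 0 and tail_a > tail_level:
        cls = "memory"
    elif best_lag <= -lag_min:
        cls = "priming"
    else:
        cls = "concordant"
    return {"lag": best_lag, "r_at_lag": best_r, "class": cls,
            "tail_expression": tail_e, "tail_activity": tail_a}
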