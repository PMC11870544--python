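"""TF motif activity, response-TF calling, and pseudotime GRN inference.

Motif activity is a background-standardized accessibility deviation: the mean
binned accessibility of a TF's motif-bearing peaks, z-scored against random
peak sets matched on overall mean accessibility (decile-matched sampling).
Candidate TF->gene edges require the TF's motif in an open region linked to
the target; edge significance comes from correlating motif activity with the
target's binned expression, with a circular-shift permutation null that
respects the autocorrelation of pseudotime profiles.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core import bh_qvalues
from .differential import geneset_enrichment

logger = logging.getLogger("stimqtl")

MIN_MOTIF_PEAKS = 5


def motif_activity(peak_profiles: pd.DataFrame, motif_map: pd.DataFrame,
                   n_background: int = 50, seed: int = 0,
                   mean_accessibility: pd.Series | None = None) -> pd.DataFrame:
    """Background-standardized motif activity per TF per pseudotime bin.

    ``peak_profiles``: peak x bin z-scored accessibility profiles (from
    :func:`stimqtl.trajectory.bin_pseudotime` on the peak matrix) for one
    cell type. For each TF, raw activity per bin is the mean profile over its
    peaks; the background is ``n_background`` random peak sets of equal size
    drawn within deciles of overall mean accessibility, and the reported
    activity is (raw - bg mean) / bg SD per bin (0 where the bg SD is 0).
    TFs with fewer than 5 assigned peaks are dropped.
    """
    rng = np.random.default_rng(seed)
    peaks = list(peak_profiles.index)
    peak_pos = {p: i for i, p in enumerate(peaks)}
    P = peak_profiles.to_numpy()
    if mean_accessibility is None:
        mean_acc = P.mean(axis=1)
    else:
        mean_acc = mean_accessibility.reindex(peaks).to_numpy()
    deciles = np.quantile(mean_acc, np.linspace(0, 1, 11)[1:-1])
    bin_of = np.digitize(mean_acc, deciles)
    pool_by_bin = {b: np.where(bin_of == b)[0] for b in range(10)}

    out = {}
    for tf, grp in motif_map.groupby("tf", sort=True):
        idx = np.array([peak_pos[p] for p in grp["peak"] if p in peak_pos])
        if idx.size < MIN_MOTIF_PEAKS:
            logger.info("TF %s has %d peaks (< %d); dropped", tf, idx.size,
                        MIN_MOTIF_PEAKS)
            continue
        raw = P[idx].mean(axis=0)
        counts = np.bincount(bin_of[idx], minlength=10)
        bg = np.empty((n_background, P.shape[1]))
        for b_i in range(n_background):
            sel = []
            for dec, c in enumerate(counts):
                if c == 0:
                    continue
                pool = pool_by_bin[dec]
                sel.append(rng.choice(pool, size=c,
                                      replace=len(pool) < c))
            sel = np.concatenate(sel)
            bg[b_i] = P[sel].mean(axis=0)
        mu = bg.mean(axis=0)
        sd = bg.std(axis=0)
        z = np.where(sd > 0, (raw - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        out[tf] = z
    return pd.DataFrame(out, index=peak_profiles.columns).T


def call_response_tfs(da_results: pd.DataFrame, motif_map: pd.DataFrame,
                      tf_de: pd.DataFrame, phase: str,
                      alpha: float = 0.05, lfc_threshold: float = 0.0
                      ) -> pd.DataFrame:
    """Early/late response TFs: motif enrichment in up-DA peaks AND TF gene DE.

    ``phase`` selects the contrast: "early" uses the 1h-vs-0h DA result and
    the TF gene's 1h DE; "late" the 6h analogues. ``da_results`` and
    ``tf_de`` are single-contrast frames (feature, lfc, p, q). Both gates are
    conjunctive: motif-peak Fisher enrichment among up-DA peaks with BH
    q < alpha, and TF gene q < alpha.
    """
    if phase not in ("early", "late"):
        raise ValueError("phase must be 'early' or 'late'")
    up = set(da_results.loc[(da_results["q"] < alpha)
                            & (da_results["lfc"] > lfc_threshold), "feature"])
    background = set(da_results["feature"])
    de_q = tf_de.set_index("feature")["q"]
    rows = []
    for tf, grp in motif_map.groupby("tf", sort=True):
        tf_peaks = set(grp["peak"]) & background
        if not tf_peaks:
            continue
        enr = geneset_enrichment(hit_genes=up & background, set_genes=tf_peaks,
                                 background_genes=background)
        rows.append((tf, enr["odds_ratio"], enr["p"],
                     float(de_q.get(tf, np.nan))))
    out = pd.DataFrame(rows, columns=["tf", "odds_ratio", "p_enrich", "q_de"])
    if out.empty:
        return out.assign(q_enrich=[], called=[], phase=phase)
    out["q_enrich"] = bh_qvalues(out["p_enrich"].to_numpy())
    out["called"] = ((out["q_enrich"] < alpha) & (out["odds_ratio"] > 1)
                     & (out["q_de"] < alpha))
    out["phase"] = phase
    return out


def _circular_shift_pvalue(x: np.ndarray, y: np.ndarray,
                           shifts: np.ndarray) -> tuple[float, float]:
    """Pearson r and its circular-shift permutation p (autocorrelation-safe).

    ``shifts`` are circular offsets in bins and may be fractional: a shift by
    s rotates x by s bins via its Fourier phases, which interpolates the
    profile on the circle and gives arbitrarily many distinct permutations
    while preserving the power spectrum (hence the autocorrelation) exactly.
    """
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return 0.0, 1.0
    r_obs = float(xc @ yc / denom)
    fx = np.fft.rfft(xc)
    fy = np.fft.rfft(yc)
    k = np.arange(fx.size)
    # corr of (x rotated by s) with y = irfft at phase ramp; vectorized over shifts
    phase = np.exp(-2j * np.pi * np.outer(shifts, k) / n)
    cross = (phase * (fx.conj() * fy)[None, :])
    # inverse rfft summed over frequencies: real part, doubling non-edge bins
    weights = np.full(fx.size, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    cc = (cross.real * weights[None, :]).sum(axis=1) / n
    # rotated-x variance is preserved by the phase ramp, so denom is unchanged
    r_perm = cc / denom
    p = (1.0 + np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12)) / (len(shifts) + 1.0)
    return r_obs, float(p)


def infer_grn(motif_act: pd.DataFrame, gene_profiles: pd.DataFrame,
              linked_pairs: pd.DataFrame, motif_map: pd.DataFrame,
              cell_type: str, target_genes: list[str] | None = None,
              n_perm: int = 1000, seed: int = 0, alpha: float = 0.05,
              smooth_window: int = 5, keep_all: bool = False) -> pd.DataFrame:
    """TF -> target edges for one cell type.

    Candidacy gate: the TF has a motif in at least one open region linked to
    the target (``linked_pairs`` with columns peak, gene). Edge statistic:
    Pearson r between the TF's motif-activity z-profile and the target's
    binned expression z-profile (both boxcar-smoothed over
    ``smooth_window`` bins to suppress bin noise), with a circular-shift
    permutation p (valid and exchangeable under the smooth-profile null);
    BH q per cell type; edges with q < alpha returned unless ``keep_all``.
    """
    from .trajectory import _smooth

    rng = np.random.default_rng(seed)
    n_bins = gene_profiles.shape[1]
    if smooth_window > 1:
        gene_profiles = pd.DataFrame(
            np.vstack([_smooth(r, smooth_window)
                       for r in gene_profiles.to_numpy()]),
            index=gene_profiles.index, columns=gene_profiles.columns)
        motif_act = pd.DataFrame(
            np.vstack([_smooth(r, smooth_window)
                       for r in motif_act.to_numpy()]),
            index=motif_act.index, columns=motif_act.columns)
    shifts = rng.uniform(1.0, n_bins - 1.0, size=n_perm)
    peaks_of_tf = motif_map.groupby("tf")["peak"].apply(set).to_dict()
    links_of_gene = linked_pairs.groupby("gene")["peak"].apply(set).to_dict()
    targets = (list(gene_profiles.index) if target_genes is None
               else [g for g in target_genes if g in gene_profiles.index])
    rows = []
    for tf in motif_act.index:
        tf_peaks = peaks_of_tf.get(tf, set())
        if not tf_peaks:
            continue
        x = motif_act.loc[tf].to_numpy()
        for g in targets:
            if g == tf:
                continue
            if not (tf_peaks & links_of_gene.get(g, set())):
                continue
            y = gene_profiles.loc[g].to_numpy()
            r, p = _circular_shift_pvalue(x, y, shifts)
            rows.append((tf, g, cell_type, r, p))
    out = pd.DataFrame(rows, columns=["tf", "target", "cell_type", "r", "p"])
    if out.empty:
        return out.assign(q=[])
    out["q"] = bh_qvalues(out["p"].to_numpy())
    return out if keep_all else out[out["q"] < alpha].reset_index(drop=True)


def target_enrichment(grn_edges: pd.DataFrame, risk_genes: list[str],
                      background: list[str], alpha: float = 0.05
                      ) -> pd.DataFrame:
    """Per-TF Fisher enrichment of its targets in a risk-gene set.

    Runs over (tf, cell_type) with BH across all of them; TFs with no target
    in the background are skipped with a log note.
    """
    bg = set(background)
    risk = set(risk_genes) & bg
    if not risk:
        raise ValueError("no risk genes inside the background")
    rows = []
    for (tf, ct), grp in grn_edges.groupby(["tf", "cell_type"], sort=True):
        targets = set(grp["target"]) & bg
        if not targets:
            logger.info("TF %s (%s): empty target set, skipped", tf, ct)
            continue
        enr = geneset_enrichment(hit_genes=targets, set_genes=risk,
                                 background_genes=bg)
        rows.append((tf, ct, len(targets), enr["odds_ratio"], enr["p"]))
    out = pd.DataFrame(rows, columns=["tf", "cell_type", "n_targets",
                                      "odds_ratio", "p"])
    if out.empty:
        return out.assign(q=[], enriched=[])
    out["q"] = bh_qvalues(out["p"].to_numpy())
    out["enriched"] = (out["q"] < alpha) & (out["odds_ratio"] > 1)
    return out


def subnetwork(grn_edges: pd.DataFrame, tfs: list[str],
               gene_list: list[str]) -> pd.DataFrame:
    """Edge list restricted to selected TFs and a target gene list (e.g. a
    risk-gene subnetwork export)."""
    sel = grn_edges[grn_edges["tf"].isin(set(tfs))
                    & grn_edges["target"].isin(set(gene_list))]
    return sel.reset_index(drop=True)
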