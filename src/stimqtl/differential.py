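"""Stimulation-response and case-control differential analysis on pseudobulk.

Response DE between time points within a cell type is a paired (donor-blocked)
linear model on log2 pseudobulk; the same estimator serves genes and peaks.
Case-control DE is an OLS per gene per context with case status plus
covariates. Gene-set enrichment is a two-sided Fisher exact test on the 2x2
hit/set table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CELL_TYPES, TIME_POINTS, CountMatrix, bh_qvalues
from .qtl import ContextPseudobulk

logger = logging.getLogger("stimqtl")


def response_de(pb: ContextPseudobulk, cell_type: str,
                time_pair: tuple[str, str] = ("1h", "0h"),
                scale: str = "log") -> pd.DataFrame:
    """Paired donor-blocked DE between two time points of one cell type.

    With donor as a blocking factor and a single contrast, the estimator
    reduces exactly to a paired t-test on per-donor differences of log2
    pseudobulk. Returns (feature, contrast, lfc, p, q); BH across features.
    """
    t_a, t_b = time_pair
    lab_a, lab_b = f"{cell_type}_{t_a}", f"{cell_type}_{t_b}"
    for lab in (lab_a, lab_b):
        if lab not in pb.log:
            raise ValueError(f"context {lab} absent from pseudobulk")
    A, B = pb.matrix(lab_a, scale), pb.matrix(lab_b, scale)
    donors = sorted(set(A.index) & set(B.index))
    if len(donors) < 3:
        raise ValueError(f"{cell_type} {time_pair}: fewer than 3 paired donors")
    D = A.loc[donors].to_numpy() - B.loc[donors].to_numpy()
    n = len(donors)
    lfc = D.mean(axis=0)
    sd = D.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    degenerate = sd <= 1e-10 * np.maximum(1.0, np.abs(lfc))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    p = np.where(~degenerate, 2 * stats.t.sf(np.abs(t), n - 1), 1.0)
    out = pd.DataFrame({
        "feature": pb.feature_ids,
        "contrast": f"{cell_type}:{t_a}-vs-{t_b}",
        "lfc": lfc, "p": p,
    })
    out["q"] = bh_qvalues(out["p"].to_numpy())
    return out


def da_peaks(pb_peaks: ContextPseudobulk, cell_type: str,
             time_pair: tuple[str, str] = ("1h", "0h"),
             scale: str = "log") -> pd.DataFrame:
    """Differential accessibility: the response DE estimator on peak pseudobulk."""
    return response_de(pb_peaks, cell_type, time_pair, scale)


def response_de_all(pb: ContextPseudobulk, scale: str = "log") -> pd.DataFrame:
    """Both stimulated-vs-rest contrasts for every cell type, concatenated."""
    frames = []
    for ct in CELL_TYPES:
        for t in ("1h", "6h"):
            if f"{ct}_{t}" in pb.log and f"{ct}_0h" in pb.log:
                frames.append(response_de(pb, ct, (t, "0h"), scale))
    return pd.concat(frames, ignore_index=True)


def peak_presence(peak_counts: CountMatrix, cells: pd.DataFrame,
                  min_cell_fraction: float = 0.02) -> pd.DataFrame:
    """Presence calls per peak per context plus a stimulation-specific flag.

    A peak is present in a context when at least ``min_cell_fraction`` of
    that context's cells carry a nonzero count; it is stimulation-specific
    in a cell type when absent at 0h but present at 1h or 6h.
    """
    if not 0 < min_cell_fraction < 1:
        raise ValueError("min_cell_fraction must be in (0, 1)")
    X = peak_counts.counts.tocsc()
    cell_pos = {c: i for i, c in enumerate(peak_counts.cells)}
    present = {}
    for (ct, t), grp in cells.groupby(["cell_type", "time"], sort=True):
        rows = grp["cell_id"].map(cell_pos).to_numpy()
        frac = np.asarray((X[rows, :] > 0).sum(axis=0)).ravel() / len(rows)
        present[f"{ct}_{t}"] = frac >= min_cell_fraction
    out = pd.DataFrame(present, index=peak_counts.feature_ids)
    out.index.name = "peak"
    stim_specific = np.zeros(len(out), dtype=bool)
    for ct in CELL_TYPES:
        cols = [f"{ct}_{t}" for t in TIME_POINTS]
        if not all(c in out.columns for c in cols):
            continue
        stim = out[f"{ct}_1h"].to_numpy() | out[f"{ct}_6h"].to_numpy()
        stim_specific |= stim & ~out[f"{ct}_0h"].to_numpy()
    out["stimulation_specific"] = stim_specific
    return out.reset_index()


def geneset_enrichment(hit_genes, set_genes, background_genes) -> dict:
    """Fold enrichment and two-sided Fisher exact p of hits in a gene set.

    fold = (|hit & set| / |set|) / (|hit \\ set| / |background \\ set|).
    """
    bg = set(background_genes)
    s = set(set_genes)
    h = set(hit_genes)
    if not s or not bg:
        raise ValueError("empty gene set or background")
    if not s <= bg or not h <= bg:
        raise ValueError("set and hits must be subsets of the background")
    a = len(h & s)            # hits in set
    b = len(s - h)            # set, not hit
    c = len(h - s)            # hits outside set
    d = len(bg - s - h)       # neither
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    rate_in = a / len(s)
    denom = len(bg - s)
    rate_out = c / denom if denom else np.nan
    fold = rate_in / rate_out if rate_out else np.inf
    return {"fold": fold, "odds_ratio": odds, "p": p,
            "table": ((a, b), (c, d))}


def case_control_de(pb: ContextPseudobulk, case_labels: dict[str, str],
                    context: str, covariates: pd.DataFrame | None = None,
                    scale: str = "log") -> pd.DataFrame:
    """Per-gene OLS of log2 pseudobulk on case status (+ covariates) in one
    context. Zero-variance genes get p = 1. BH q per context."""
    mat = pb.matrix(context, scale)
    donors = [d for d in mat.index if d in case_labels]
    status = np.array([1.0 if case_labels[d] == "case" else 0.0 for d in donors])
    if min((status == 1).sum(), (status == 0).sum()) < 3:
        raise ValueError(f"{context}: fewer than 3 donors in one arm")
    X = [np.ones(len(donors)), status]
    if covariates is not None:
        X.append(covariates.loc[donors].to_numpy().T)
    X = np.column_stack([np.atleast_2d(x).reshape(len(donors), -1) for x in X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("confounded covariates: design is rank-deficient")
    Y = mat.loc[donors].to_numpy()
    n, p_cols = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ (X.T @ Y)
    resid = Y - X @ B
    dof = n - p_cols
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    beta = B[1, :]
    degenerate = Y.var(axis=0) <= 1e-20  # constant pseudobulk column
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    pvals = np.where((se > 0) & ~degenerate,
                     2 * stats.t.sf(np.abs(t), dof), 1.0)
    beta = np.where(degenerate, 0.0, beta)
    out = pd.DataFrame({"feature": pb.feature_ids, "contrast": f"{context}:case-vs-control",
                        "lfc": beta, "p": pvals})
    out["q"] = bh_qvalues(out["p"].to_numpy())
    return out


def activity_dependent_de(pb: ContextPseudobulk, case_labels: dict[str, str],
                          cell_type: str,
                          covariates: pd.DataFrame | None = None,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Case-control DE across a cell type's time points with the
    activity-dependent flag: significant in a stimulated context (q < alpha)
    while not significant at 0h."""
    frames = {t: case_control_de(pb, case_labels, f"{cell_type}_{t}", covariates)
              for t in TIME_POINTS}
    base_sig = frames["0h"].set_index("feature")["q"] < alpha
    rows = []
    for t in TIME_POINTS:
        df = frames[t].copy()
        df["time"] = t
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    sig_any_stim = (
        out[out["time"].isin(["1h", "6h"]) & (out["q"] < alpha)]
        .groupby("feature").size() > 0
    )
    out["activity_dependent"] = [
        bool(sig_any_stim.get(f, False)) and not bool(base_sig.get(f, False))
        for f in out["feature"]
    ]
    return out
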