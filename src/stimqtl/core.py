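"""Shared domain types and coordinate conventions.

Coordinate conventions, used everywhere outside of I/O:

* SNP positions and gene TSS are 1-based (VCF convention).
* Peak intervals are 0-based half-open (BED convention).
* A cis window is a 1-based inclusive interval of SNP positions.

Conversion between conventions happens only at I/O boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("stimqtl")

CELL_TYPES = ("GABA", "nmglut", "npglut")
TIME_POINTS = ("0h", "1h", "6h")


@dataclass(frozen=True, order=True)
class Context:
    """A (cell type, time point) pair; exactly nine exist."""

    cell_type: str
    time: str

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        if self.time not in TIME_POINTS:
            raise ValueError(f"unknown time point {self.time!r}")

    @property
    def label(self) -> str:
        return f"{self.cell_type}_{self.time}"

    @classmethod
    def from_label(cls, label: str) -> "Context":
        cell_type, time = label.rsplit("_", 1)
        return cls(cell_type, time)


#: The nine stimulation contexts, in canonical order.
CONTEXTS: tuple[Context, ...] = tuple(
    Context(ct, t) for ct in CELL_TYPES for t in TIME_POINTS
)


@dataclass(frozen=True)
class SNP:
    """A biallelic variant; ``pos`` is 1-based and ``maf`` refers to ``alt``-vs-``ref``
    minor allele frequency in (0, 0.5]."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.id}: pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError(f"SNP {self.id}: ref == alt")
        if not 0 < self.maf <= 0.5:
            raise ValueError(f"SNP {self.id}: maf {self.maf} outside (0, 0.5]")


@dataclass(frozen=True)
class Feature:
    """A gene (1-based TSS, strand) or an ATAC peak (BED half-open interval)."""

    id: str
    kind: str  # "gene" | "peak"
    chrom: str
    tss: int | None = None
    strand: str | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "gene":
            if self.tss is None or self.tss < 1:
                raise ValueError(f"gene {self.id}: tss must be >= 1")
        elif self.kind == "peak":
            if self.start is None or self.end is None or self.start >= self.end:
                raise ValueError(f"peak {self.id}: need start < end")
        else:
            raise ValueError(f"feature {self.id}: kind must be 'gene' or 'peak'")


class GenotypeMatrix:
    """Donor x SNP dosage matrix (entries in {0, 1, 2}) plus SNP metadata."""

    def __init__(self, donors: Sequence[str], snps: Sequence[SNP], dosage: np.ndarray):
        dosage = np.asarray(dosage)
        if dosage.shape != (len(donors), len(snps)):
            raise ValueError(
                f"dosage shape {dosage.shape} != ({len(donors)}, {len(snps)})"
            )
        if not np.isin(dosage, (0, 1, 2)).all():
            raise ValueError("dosage entries must be in {0, 1, 2}")
        self.donors = list(donors)
        self.snps = list(snps)
        self.dosage = dosage.astype(np.int8)
        self._snp_index = {s.id: i for i, s in enumerate(self.snps)}
        self._donor_index = {d: i for i, d in enumerate(self.donors)}

    @property
    def n_donors(self) -> int:
        return len(self.donors)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_idx(self, snp_id: str) -> int:
        return self._snp_index[snp_id]

    def donor_idx(self, donor_id: str) -> int:
        return self._donor_index[donor_id]

    def empirical_maf(self) -> np.ndarray:
        """Alt-allele frequency folded to the minor side."""
        af = self.dosage.mean(axis=0) / 2.0
        return np.minimum(af, 1.0 - af)

    def het_mask(self, snp_id: str) -> np.ndarray:
        """Boolean donor mask of heterozygous carriers."""
        return self.dosage[:, self.snp_idx(snp_id)] == 1


@dataclass
class CountMatrix:
    """Sparse nonnegative integer cell x feature count matrix."""

    cells: list[str]
    features: list[Feature]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cells), len(self.features)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.cells)}, {len(self.features)})"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def feature_ids(self) -> list[str]:
        return [f.id for f in self.features]


# Cell annotations are carried as a DataFrame with these columns; pseudotime in [0, 1].
CELL_ANNOTATION_COLUMNS = ("cell_id", "donor_id", "cell_type", "time", "pseudotime")


def validate_cell_annotations(cells: pd.DataFrame) -> pd.DataFrame:
    missing = set(CELL_ANNOTATION_COLUMNS) - set(cells.columns)
    if missing:
        raise ValueError(f"cell annotation missing columns: {sorted(missing)}")
    if cells["cell_id"].duplicated().any():
        raise ValueError("duplicate cell ids")
    pt = cells["pseudotime"].to_numpy()
    if np.isnan(pt).any() or (pt < 0).any() or (pt > 1).any():
        raise ValueError("pseudotime must be defined and in [0, 1] for every cell")
    bad_ct = set(cells["cell_type"]) - set(CELL_TYPES)
    bad_t = set(cells["time"]) - set(TIME_POINTS)
    if bad_ct or bad_t:
        raise ValueError(f"unknown cell type/time labels: {bad_ct | bad_t}")
    return cells


class ContactMap:
    """Chromatin contact records per time point with symmetric (a, b) lookup."""

    def __init__(self, records: pd.DataFrame):
        required = {"chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
                    "freq", "time"}
        if not required.issubset(records.columns):
            raise ValueError(f"contact records need columns {sorted(required)}")
        if (records["freq"] < 0).any():
            raise ValueError("contact frequency must be nonnegative")
        self.records = records.reset_index(drop=True)
        self._index: dict[tuple, float] = {}
        for r in self.records.itertuples(index=False):
            key = self._key(r.chrom_a, r.start_a, r.end_a, r.chrom_b, r.start_b,
                            r.end_b, r.time)
            self._index[key] = self._index.get(key, 0.0) + float(r.freq)

    @staticmethod
    def _key(ca, sa, ea, cb, sb, eb, time) -> tuple:
        a, b = (ca, int(sa), int(ea)), (cb, int(sb), int(eb))
        if b < a:
            a, b = b, a
        return (*a, *b, time)

    def query(self, bin_a: tuple[str, int, int], bin_b: tuple[str, int, int],
              time: str) -> float:
        return self._index.get(self._key(*bin_a, *bin_b, time), 0.0)


@dataclass
class GwasSummary:
    """GWAS z-scores over a SNP panel partitioned into LD blocks.

    ``ld_blocks`` holds (index array into ``snp_ids``, correlation matrix) pairs;
    every SNP belongs to exactly one block.
    """

    snp_ids: list[str]
    z: np.ndarray
    n_gwas: int
    ld_blocks: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (len(self.snp_ids),):
            raise ValueError("z length != number of SNPs")
        seen = np.zeros(len(self.snp_ids), dtype=int)
        for idx, R in self.ld_blocks:
            idx = np.asarray(idx)
            seen[idx] += 1
            R = np.asarray(R)
            if R.shape != (len(idx), len(idx)):
                raise ValueError("block correlation matrix shape mismatch")
            if not np.allclose(R, R.T, atol=1e-8):
                raise ValueError("block correlation matrix not symmetric")
            if not np.allclose(np.diag(R), 1.0, atol=1e-6):
                raise ValueError("block correlation matrix diagonal != 1")
        if self.ld_blocks and (seen != 1).any():
            raise ValueError("each SNP must belong to exactly one LD block")


def cis_window(feature: Feature, half_width_bp: int) -> tuple[str, int, int]:
    """1-based inclusive interval of SNP positions in cis of ``feature``.

    For a gene the window is ``[tss - w, tss + w]``; for a peak it is the peak
    interval extended by ``w`` on both sides (converted to 1-based). The lower
    bound is clipped at 1.
    """
    if half_width_bp < 0:
        raise ValueError("half_width_bp must be >= 0")
    if feature.kind == "gene":
        lo, hi = feature.tss - half_width_bp, feature.tss + half_width_bp
    else:
        lo, hi = feature.start + 1 - half_width_bp, feature.end + half_width_bp
    return feature.chrom, max(1, lo), hi


def snp_in_cis(snp: SNP, feature: Feature, half_width_bp: int) -> bool:
    chrom, lo, hi = cis_window(feature, half_width_bp)
    return snp.chrom == chrom and lo <= snp.pos <= hi


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out
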