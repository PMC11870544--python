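"""Readers and writers for the on-disk formats.

Formats: MatrixMarket count matrices with feature/barcode TSV sidecars, BED3/4
peak intervals, minimal VCF v4 / TSV genotype dialects, gene model TSV, GWAS
summary TSV, contact TSV, cell annotation TSV, and a flat YAML config. All
readers and writers are exact round-trip inverses on valid files.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .core import (
    ContactMap,
    CountMatrix,
    Feature,
    GenotypeMatrix,
    SNP,
    validate_cell_annotations,
)

logger = logging.getLogger("stimqtl")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# count matrices (MatrixMarket + TSV sidecars)
# ---------------------------------------------------------------------------

def read_count_matrix(mtx_path, features_path, barcodes_path) -> CountMatrix:
    """Read a feature x cell MatrixMarket file with TSV sidecars.

    The MTX file is stored features-as-rows, cells-as-columns (the 10x
    convention); the returned :class:`CountMatrix` is cells x features.
    """
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise FormatError(f"cannot parse MatrixMarket file {mtx_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.nnz and (mat.data < 0).any():
        raise FormatError("negative entries in count matrix")
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError("non-integer entries in count matrix")
    features = read_features_tsv(features_path)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    if mat.shape[0] != len(features):
        raise FormatError(
            f"MTX has {mat.shape[0]} rows but {len(features)} features listed"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"MTX has {mat.shape[1]} columns but {len(barcodes)} barcodes listed"
        )
    counts = sp.csr_matrix(mat.T.astype(np.int64))
    return CountMatrix(cells=barcodes, features=features, counts=counts)


def write_count_matrix(cm: CountMatrix, mtx_path, features_path, barcodes_path) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(cm.counts.T), field="integer")
    write_features_tsv(cm.features, features_path)
    pd.Series(cm.cells).to_csv(barcodes_path, sep="\t", header=False, index=False)


_FEATURE_COLS = ["id", "kind", "chrom", "tss", "strand", "start", "end"]


def read_features_tsv(path) -> list[Feature]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    if not set(_FEATURE_COLS).issubset(df.columns):
        raise FormatError(f"feature TSV needs columns {_FEATURE_COLS}")
    out = []
    for r in df.itertuples(index=False):
        if r.kind == "gene":
            out.append(Feature(id=r.id, kind="gene", chrom=r.chrom,
                               tss=int(r.tss), strand=r.strand))
        else:
            out.append(Feature(id=r.id, kind="peak", chrom=r.chrom,
                               start=int(r.start), end=int(r.end)))
    return out


def write_features_tsv(features: Sequence[Feature], path) -> None:
    df = pd.DataFrame(
        [
            {
                "id": f.id, "kind": f.kind, "chrom": f.chrom,
                "tss": f.tss if f.tss is not None else "",
                "strand": f.strand or "",
                "start": f.start if f.start is not None else "",
                "end": f.end if f.end is not None else "",
            }
            for f in features
        ],
        columns=_FEATURE_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_models(path) -> list[Feature]:
    """Gene model TSV: columns id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    return [Feature(id=r.id, kind="gene", chrom=r.chrom, tss=int(r.tss),
                    strand=r.strand) for r in df.itertuples(index=False)]


def write_gene_models(genes: Sequence[Feature], path) -> None:
    pd.DataFrame(
        [{"id": g.id, "chrom": g.chrom, "tss": g.tss, "strand": g.strand}
         for g in genes]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, impute_missing: bool = False) -> GenotypeMatrix:
    """Read a minimal VCF (``.vcf``) or the TSV dosage dialect (anything else).

    The TSV dialect has SNP metadata columns (snp, chrom, pos, ref, alt) and
    one 0/1/2 dosage column per donor. Missing genotypes ("./." in VCF) are
    rejected unless ``impute_missing`` is set, in which case they are filled
    with the rounded per-SNP mean dosage.
    """
    path = Path(path)
    if path.suffix == ".vcf":
        return _read_vcf(path, impute_missing)
    return _read_genotype_tsv(path, impute_missing)


def _read_vcf(path: Path, impute_missing: bool) -> GenotypeMatrix:
    donors: list[str] = []
    snps: list[SNP] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                donors = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise FormatError(f"VCF record with <10 fields: {line[:60]}")
            chrom, pos, vid, ref, alt = fields[:5]
            fmt = fields[8].split(":")
            try:
                gt_i = fmt.index("GT")
            except ValueError as exc:
                raise FormatError("VCF record without GT field") from exc
            dose_row: list[float] = []
            for sample in fields[9:]:
                gt = sample.split(":")[gt_i].replace("|", "/")
                if gt in ("./.", "."):
                    dose_row.append(np.nan)
                else:
                    alleles = gt.split("/")
                    if not all(a in ("0", "1") for a in alleles):
                        raise FormatError(f"unsupported genotype {gt!r}")
                    dose_row.append(float(sum(int(a) for a in alleles)))
            rows.append(dose_row)
            snps.append((chrom, int(pos), vid, ref, alt))
    dosage = np.array(rows, dtype=float).T if rows else np.zeros((len(donors), 0))
    dosage = _handle_missing(dosage, impute_missing)
    snp_objs = _finalize_snps(snps, dosage)
    return GenotypeMatrix(donors=donors, snps=snp_objs, dosage=dosage)


def _read_genotype_tsv(path: Path, impute_missing: bool) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "snp": str})
    meta_cols = ["snp", "chrom", "pos", "ref", "alt"]
    if not set(meta_cols).issubset(df.columns):
        raise FormatError(f"genotype TSV needs columns {meta_cols}")
    donors = [c for c in df.columns if c not in meta_cols]
    dosage = df[donors].to_numpy(dtype=float).T
    ok = np.isnan(dosage) | np.isin(dosage, (0.0, 1.0, 2.0))
    if not ok.all():
        raise FormatError("genotype TSV entries must be 0/1/2 (or empty)")
    dosage = _handle_missing(dosage, impute_missing)
    snps = [(r.chrom, int(r.pos), r.snp, r.ref, r.alt)
            for r in df.itertuples(index=False)]
    return GenotypeMatrix(donors=donors, snps=_finalize_snps(snps, dosage),
                          dosage=dosage)


def _handle_missing(dosage: np.ndarray, impute: bool) -> np.ndarray:
    miss = np.isnan(dosage)
    if miss.any():
        if not impute:
            raise FormatError(
                "missing genotypes present; pass impute_missing=True to fill "
                "with rounded per-SNP mean dosage"
            )
        col_mean = np.nanmean(dosage, axis=0)
        fill = np.broadcast_to(np.round(col_mean), dosage.shape)
        dosage = np.where(miss, fill, dosage)
        logger.info("imputed %d missing genotype entries", int(miss.sum()))
    return dosage.astype(np.int8)


def _finalize_snps(meta: list[tuple], dosage: np.ndarray) -> list[SNP]:
    out = []
    for j, (chrom, pos, vid, ref, alt) in enumerate(meta):
        af = float(dosage[:, j].mean() / 2.0) if dosage.shape[0] else 0.25
        maf = min(af, 1.0 - af)
        maf = min(max(maf, 1e-6), 0.5)  # keep maf in (0, 0.5] for monomorphic edge
        out.append(SNP(id=vid, chrom=chrom, pos=pos, ref=ref, alt=alt, maf=maf))
    return out


def write_genotypes_tsv(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        {
            "snp": [s.id for s in gm.snps],
            "chrom": [s.chrom for s in gm.snps],
            "pos": [s.pos for s in gm.snps],
            "ref": [s.ref for s in gm.snps],
            "alt": [s.alt for s in gm.snps],
        }
    )
    for i, d in enumerate(gm.donors):
        df[d] = gm.dosage[i, :]
    df.to_csv(path, sep="\t", index=False)


def write_genotypes_vcf(gm: GenotypeMatrix, path) -> None:
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.donors) + "\n")
        for j, s in enumerate(gm.snps):
            gts = "\t".join(gt_map[int(v)] for v in gm.dosage[:, j])
            fh.write(f"{s.chrom}\t{s.pos}\t{s.id}\t{s.ref}\t{s.alt}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# BED peaks
# ---------------------------------------------------------------------------

def read_bed(path) -> list[Feature]:
    """Read 3+ column BED into peak Features (0-based half-open preserved)."""
    peaks = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"{path}:{ln}: start {start} >= end {end}")
            pid = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            peaks.append(Feature(id=pid, kind="peak", chrom=chrom,
                                 start=start, end=end))
    return peaks


def write_bed(peaks: Sequence[Feature], path, with_names: bool = True) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            cols = [p.chrom, str(p.start), str(p.end)]
            if with_names:
                cols.append(p.id)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# cell annotations, contacts, GWAS, config
# ---------------------------------------------------------------------------

def read_cell_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "donor_id": str})
    return validate_cell_annotations(df)


def write_cell_annotations(cells: pd.DataFrame, path) -> None:
    validate_cell_annotations(cells).to_csv(path, sep="\t", index=False)


def read_contacts(path) -> ContactMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom_a": str, "chrom_b": str})
    return ContactMap(df)


def write_contacts(cm: ContactMap, path) -> None:
    cm.records.to_csv(path, sep="\t", index=False)


def read_gwas(path, ld_path=None):
    """GWAS TSV (snp, z, n[, block]); LD matrices from an optional .npz-free TSV.

    ``ld_path`` is a TSV of the long form (block, snp_a, snp_b, r) from which
    per-block correlation matrices are reassembled in panel order.
    """
    from .core import GwasSummary

    df = pd.read_csv(path, sep="\t", dtype={"snp": str})
    snp_ids = df["snp"].tolist()
    z = df["z"].to_numpy(dtype=float)
    n_gwas = int(df["n"].iloc[0])
    blocks = []
    if "block" in df.columns and ld_path is not None:
        ld = pd.read_csv(ld_path, sep="\t", dtype={"snp_a": str, "snp_b": str})
        pos = {s: i for i, s in enumerate(snp_ids)}
        for b, sub in ld.groupby("block", sort=True):
            members = sorted(set(sub["snp_a"]) | set(sub["snp_b"]), key=pos.get)
            idx = np.array([pos[s] for s in members])
            loc = {s: i for i, s in enumerate(members)}
            R = np.eye(len(members))
            for r in sub.itertuples(index=False):
                R[loc[r.snp_a], loc[r.snp_b]] = r.r
                R[loc[r.snp_b], loc[r.snp_a]] = r.r
            blocks.append((idx, R))
    return GwasSummary(snp_ids=snp_ids, z=z, n_gwas=n_gwas, ld_blocks=blocks)


def write_gwas(gwas, path, ld_path=None) -> None:
    block_of = np.full(len(gwas.snp_ids), -1)
    for b, (idx, _) in enumerate(gwas.ld_blocks):
        block_of[idx] = b
    df = pd.DataFrame({"snp": gwas.snp_ids, "z": gwas.z, "n": gwas.n_gwas,
                       "block": block_of})
    df.to_csv(path, sep="\t", index=False)
    if ld_path is not None:
        rows = []
        for b, (idx, R) in enumerate(gwas.ld_blocks):
            ids = [gwas.snp_ids[i] for i in idx]
            for i in range(len(ids)):
                for j in range(i, len(ids)):
                    rows.append((b, ids[i], ids[j], R[i, j]))
        pd.DataFrame(rows, columns=["block", "snp_a", "snp_b", "r"]).to_csv(
            ld_path, sep="\t", index=False
        )


def read_motif_map(path) -> pd.DataFrame:
    """TF motif -> peak assignment TSV with columns (tf, peak)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"tf", "peak"}.issubset(df.columns):
        raise FormatError("motif map TSV needs columns (tf, peak)")
    return df


def write_motif_map(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError("config must be a YAML mapping")
    return cfg


def setup_logging(level=logging.INFO) -> None:
    """Structured logging to stderr (idempotent)."""
    root = logging.getLogger("stimqtl")
    if not root.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        root.addHandler(handler)
    root.setLevel(level)
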