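"""File I/O: PLINK bed/bim/fam, TSV dosage tables, annotations, phenotypes, kinship.

The PLINK codec handles the SNP-major binary .bed layout (magic bytes
``6c 1b 01``, two bits per genotype, four genotypes per byte, LSB first).
Dosages count copies of the A1 allele: code 00 -> 2, 10 -> 1, 11 -> 0 and
01 -> missing.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeError, GenotypeMatrix, KinshipMatrix

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK code -> dosage of A1 (NaN = missing)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def write_plink(G: GenotypeMatrix, prefix: str | Path) -> None:
    """Write bed/bim/fam files for ``prefix``. Missing dosages become code 01."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, p = G.n, G.p
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in G.sample_ids:
            fh.write(f"{s}\t{s}\t0\t0\t0\t-9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(p):
            fh.write(f"{G.chrom[j]}\t{G.snp_ids[j]}\t0\t{G.pos[j]}\tA\tB\n")
    X = G.dosages
    codes = np.full((p, n), 1, dtype=np.uint8)  # 01 = missing
    for dose, code in ((2.0, 0), (1.0, 2), (0.0, 3)):
        codes[(X.T == dose)] = code
    n_bytes = (n + 3) // 4
    padded = np.zeros((p, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a SNP-major PLINK bed/bim/fam triplet into a GenotypeMatrix."""
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      dtype=str, comment=None)
    if fam.shape[1] < 2:
        raise GenotypeError(f"malformed fam file {prefix.with_suffix('.fam')}")
    sample_ids = fam.iloc[:, 1].tolist()
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None, dtype=str)
    if bim.shape[1] < 4:
        raise GenotypeError(f"malformed bim file {prefix.with_suffix('.bim')}")
    snp_ids = bim.iloc[:, 1].tolist()
    chrom = bim.iloc[:, 0].astype(int).to_numpy()
    pos = bim.iloc[:, 3].astype(int).to_numpy()
    n, p = len(sample_ids), len(snp_ids)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise GenotypeError(
            f"{prefix.with_suffix('.bed')}: bad magic bytes (not SNP-major PLINK bed)"
        )
    n_bytes = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != p * n_bytes:
        raise GenotypeError(
            f"{prefix.with_suffix('.bed')}: expected {p * n_bytes} body bytes, "
            f"found {body.size}"
        )
    body = body.reshape(p, n_bytes)
    codes = np.empty((p, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0x03
    codes[:, 1::4] = (body >> 2) & 0x03
    codes[:, 2::4] = (body >> 4) & 0x03
    codes[:, 3::4] = (body >> 6) & 0x03
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T
    return _finalize_read(dosages, sample_ids, snp_ids, chrom, pos)


def write_dosage_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    """Plain-text fallback: SNP metadata columns then one dosage column per sample."""
    df = pd.DataFrame(
        {"snp_id": G.snp_ids, "chrom": G.chrom, "pos": G.pos}
    )
    dos = pd.DataFrame(G.dosages.T, columns=G.sample_ids)
    pd.concat([df, dos], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    meta_cols = ["snp_id", "chrom", "pos"]
    if df.columns[:3].tolist() != meta_cols:
        raise GenotypeError(
            f"{path}: dosage TSV must start with columns {meta_cols}, "
            f"found {df.columns[:3].tolist()}"
        )
    sample_ids = df.columns[3:].tolist()
    dosages = df[sample_ids].to_numpy(dtype=float).T
    return _finalize_read(
        dosages,
        sample_ids,
        df["snp_id"].astype(str).tolist(),
        df["chrom"].to_numpy(int),
        df["pos"].to_numpy(int),
    )


def _finalize_read(dosages, sample_ids, snp_ids, chrom, pos) -> GenotypeMatrix:
    """Drop all-missing SNPs (with a warning); leave imputation to callers."""
    all_missing = np.all(np.isnan(dosages), axis=0)
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} SNP(s) with no called genotypes",
            stacklevel=2,
        )
        keep = ~all_missing
        dosages = dosages[:, keep]
        snp_ids = [s for s, k in zip(snp_ids, keep) if k]
        chrom, pos = chrom[keep], pos[keep]
    return GenotypeMatrix(dosages, list(sample_ids), list(snp_ids), chrom, pos)


def read_genotypes(path: str | Path, fmt: str = "auto") -> GenotypeMatrix:
    """Read genotypes from PLINK (bed/bim/fam prefix) or a dosage TSV."""
    path = Path(path)
    if fmt == "auto":
        fmt = "plink" if path.with_suffix(".bed").exists() else "tsv"
    if fmt == "plink":
        return read_plink(path)
    if fmt == "tsv":
        return read_dosage_tsv(path)
    raise GenotypeError(f"unknown genotype format {fmt!r}")


# --- annotations / phenotypes -------------------------------------------------

GENE_COLUMNS = ["gene_id", "chrom", "start", "stop"]
PATHWAY_COLUMNS = ["pathway_id", "gene_id"]
PHENOTYPE_COLUMNS = ["accession", "replicate", "trait", "value"]


def read_gene_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, GENE_COLUMNS, path)
    return df


def read_pathway_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, PATHWAY_COLUMNS, path)
    return df


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, PHENOTYPE_COLUMNS, path)
    if df.duplicated(["accession", "replicate", "trait"]).any():
        raise ValueError(f"{path}: duplicated (accession, replicate, trait) keys")
    return df


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def write_kinship(K: KinshipMatrix, path: str | Path) -> None:
    """Square TSV with sample-id header plus a JSON sidecar of the metadata."""
    path = Path(path)
    pd.DataFrame(K.values, index=K.sample_ids, columns=K.sample_ids).to_csv(
        path, sep="\t"
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {"n_snps": K.n_snps, "alpha": K.alpha, "normalization": K.normalization}
        )
    )


def read_kinship(path: str | Path) -> KinshipMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return KinshipMatrix(
        df.to_numpy(float),
        [str(s) for s in df.columns],
        int(meta["n_snps"]),
        alpha=float(meta["alpha"]),
        normalization=meta["normalization"],
    )
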