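"""Genotype containers, filtering, PCA covariates, pathway SNP assignment and kinship.

The central objects are :class:`GenotypeMatrix` (an ``n x p`` dosage matrix with
SNP metadata), :class:`PathwayPartition` (the member / complement SNP split for
one pathway) and :class:`KinshipMatrix` (a genomic similarity matrix, GSM,
``K = Z Z' / p`` built from a SNP subset).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class GenotypeError(ValueError):
    """Raised for malformed or inconsistent genotype inputs."""


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages (0/1/2 copies of the counted allele) with metadata.

    ``dosages`` may contain NaN for missing calls; :meth:`imputed` fills them
    with twice the allele frequency (the column mean) so that downstream
    kinship algebra stays well defined.
    """

    dosages: np.ndarray  # (n, p) float64
    sample_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray  # (p,) int
    pos: np.ndarray  # (p,) int, 1-based

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=int)
        self.pos = np.asarray(self.pos, dtype=int)
        n, p = self.dosages.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != p:
            raise GenotypeError(
                f"dimension mismatch: dosages {self.dosages.shape}, "
                f"{len(self.sample_ids)} samples, {len(self.snp_ids)} SNPs"
            )
        if len(self.chrom) != p or len(self.pos) != p:
            raise GenotypeError("SNP metadata length does not match dosage columns")
        if np.any(self.pos < 0):
            raise GenotypeError("SNP positions must be non-negative")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]

    @property
    def freq(self) -> np.ndarray:
        """Counted-allele frequency per SNP, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        f = self.freq
        return np.minimum(f, 1.0 - f)

    def snp_index(self, snp_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise GenotypeError(f"unknown SNP id {exc.args[0]!r}") from None

    def imputed(self) -> tuple[np.ndarray, int]:
        """Return (dosage matrix with missing imputed to 2f, number imputed)."""
        X = self.dosages
        miss = np.isnan(X)
        n_missing = int(miss.sum())
        if n_missing == 0:
            return X.copy(), 0
        X = X.copy()
        fill = 2.0 * self.freq
        idx = np.where(miss)
        X[idx] = fill[idx[1]]
        return X, n_missing

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [lookup[s] for s in sample_ids]
        return GenotypeMatrix(
            self.dosages[rows], list(sample_ids), list(self.snp_ids),
            self.chrom, self.pos,
        )

    def subset(self, cols: np.ndarray) -> "GenotypeMatrix":
        cols = np.asarray(cols)
        if cols.dtype == bool:
            cols = np.where(cols)[0]
        return GenotypeMatrix(
            self.dosages[:, cols],
            list(self.sample_ids),
            [self.snp_ids[i] for i in cols],
            self.chrom[cols],
            self.pos[cols],
        )


@dataclass
class PathwayPartition:
    """Member/complement SNP split for one pathway (plus bookkeeping counts)."""

    pathway_id: str
    member_snps: list[str]
    complement_snps: list[str]
    member_genes: list[str]
    buffer_bp: int

    @property
    def n_member_snps(self) -> int:
        return len(self.member_snps)

    @property
    def n_member_genes(self) -> int:
        return len(self.member_genes)

    def __post_init__(self) -> None:
        if set(self.member_snps) & set(self.complement_snps):
            raise GenotypeError(
                f"pathway {self.pathway_id}: member and complement SNP sets overlap"
            )


@dataclass
class KinshipMatrix:
    """Genomic similarity matrix for a SNP subset.

    ``values`` is symmetric n x n; ``n_snps`` is the number of SNPs used (the
    divisor p of K = ZZ'/p); ``alpha`` is the MAF-scaling exponent (0 means
    centered-unstandardized dosages, -1 standardized); ``normalization``
    records the divisor convention ("p" or "mean_diag").
    """

    values: np.ndarray
    sample_ids: list[str]
    n_snps: int
    alpha: float = 0.0
    normalization: str = "p"

    def __post_init__(self) -> None:
        K = np.asarray(self.values, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise GenotypeError("kinship matrix must be square")
        if K.shape[0] != len(self.sample_ids):
            raise GenotypeError("kinship dimension does not match sample ids")
        if not np.all(np.isfinite(K)):
            raise GenotypeError("kinship matrix contains non-finite entries")
        if not np.allclose(K, K.T, atol=1e-10):
            raise GenotypeError("kinship matrix is not symmetric")
        self.values = (K + K.T) / 2.0

    @property
    def n(self) -> int:
        return self.values.shape[0]


def filter_maf(G: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Retain SNPs with minor allele frequency strictly above ``threshold``.

    The strict inequality (MAF > threshold, not >=) matters at the boundary:
    a SNP with MAF exactly 0.05 is dropped at the default threshold.
    """
    if not 0.0 <= threshold < 0.5:
        raise GenotypeError(f"MAF threshold must be in [0, 0.5), got {threshold}")
    keep = G.maf > threshold
    if not keep.any():
        raise GenotypeError(
            f"no SNPs pass MAF > {threshold}; lower the threshold or check input"
        )
    return G.subset(keep)


def compute_pcs(G: GenotypeMatrix, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component scores of the column-centered dosage matrix.

    Dosages are centered but not variance-scaled. Returns ``(scores, varexp)``
    where ``scores`` is n x k and ``varexp`` gives each component's fraction of
    total variance. Component signs are fixed by making the largest-magnitude
    SNP loading of each component positive, so results are deterministic.
    """
    X, _ = G.imputed()
    n, p = X.shape
    if not 0 < k < min(n, p):
        raise GenotypeError(f"k must satisfy 0 < k < min(n, p) = {min(n, p)}")
    Z = X - X.mean(axis=0)
    if np.allclose(Z, 0.0):
        raise GenotypeError("constant genotype matrix has no principal components")
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    varexp_all = S**2 / np.sum(S**2)
    scores = U[:, :k] * S[:k]
    for j in range(k):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            scores[:, j] = -scores[:, j]
    return scores, varexp_all[:k]


def snps_in_gene_window(
    G: GenotypeMatrix, chrom: int, start: int, stop: int, buffer_bp: int
) -> np.ndarray:
    """Column indices of SNPs within ``buffer_bp`` of a gene's [start, stop].

    Coordinates are 1-based inclusive; a SNP at position start-buffer or
    stop+buffer is included.
    """
    return np.where(
        (G.chrom == chrom)
        & (G.pos >= start - buffer_bp)
        & (G.pos <= stop + buffer_bp)
    )[0]


def gene_snp_map(
    G: GenotypeMatrix, gene_table: pd.DataFrame, buffer_bp: int = 2500
) -> dict[str, np.ndarray]:
    """Map every gene id to the column indices of SNPs in its buffered window."""
    out: dict[str, np.ndarray] = {}
    for row in gene_table.itertuples(index=False):
        out[row.gene_id] = snps_in_gene_window(
            G, int(row.chrom), int(row.start), int(row.stop), buffer_bp
        )
    return out


def assign_pathway_snps(
    G: GenotypeMatrix,
    gene_table: pd.DataFrame,
    pathway_map: pd.DataFrame,
    buffer_bp: int = 2500,
) -> dict[str, PathwayPartition]:
    """Assign SNPs to pathways via buffered gene windows.

    A SNP belongs to a gene iff it lies on the same chromosome within
    ``buffer_bp`` of the gene body (1-based inclusive); a pathway's SNP set is
    the deduplicated union over its member genes. Pathways mapping zero SNPs
    are flagged and excluded (they cannot support a two-kernel model).
    """
    per_gene = gene_snp_map(G, gene_table, buffer_bp)
    all_snps = np.array(G.snp_ids)
    partitions: dict[str, PathwayPartition] = {}
    for pw, grp in pathway_map.groupby("pathway_id", sort=True):
        genes = sorted(grp["gene_id"])
        missing = [g for g in genes if g not in per_gene]
        if missing:
            raise GenotypeError(
                f"pathway {pw} references genes absent from the gene table: {missing[:5]}"
            )
        idx = np.unique(np.concatenate([per_gene[g] for g in genes] or [np.array([], int)]))
        if idx.size == 0:
            import warnings

            warnings.warn(
                f"pathway {pw} maps zero SNPs and is excluded from model fitting",
                stacklevel=2,
            )
            continue
        member = set(all_snps[idx])
        partitions[str(pw)] = PathwayPartition(
            pathway_id=str(pw),
            member_snps=list(all_snps[idx]),
            complement_snps=[s for s in all_snps if s not in member],
            member_genes=genes,
            buffer_bp=buffer_bp,
        )
    return partitions


def _scaled_centered(G: GenotypeMatrix, cols: np.ndarray, alpha: float,
                     raw_crossproduct: bool) -> np.ndarray:
    X, _ = G.imputed()
    X = X[:, cols]
    if raw_crossproduct:
        return X
    f = X.mean(axis=0) / 2.0
    Z = X - 2.0 * f
    if alpha != 0.0:
        het = 2.0 * f * (1.0 - f)
        if np.any(het <= 0.0):
            raise GenotypeError(
                "monomorphic SNP in subset: MAF-dependent scaling (alpha != 0) "
                "divides by zero heterozygosity"
            )
        Z = Z * het ** (alpha / 2.0)
    return Z


def compute_kinship(
    G: GenotypeMatrix,
    snp_ids=None,
    alpha: float = 0.0,
    normalization: str = "p",
    raw_crossproduct: bool = False,
) -> KinshipMatrix:
    """Kinship K = ZZ'/p over a SNP subset.

    Columns are centered by 2f and scaled by [2f(1-f)]^(alpha/2); alpha=0
    (default) leaves dosages unstandardized, alpha=-1 reproduces the
    standardized-genotype kinship. ``raw_crossproduct=True`` skips centering
    (the literal cross-product formula). ``normalization="mean_diag"``
    rescales K to unit mean diagonal after the divide-by-p construction.
    """
    if snp_ids is None:
        cols = np.arange(G.p)
    else:
        cols = G.snp_index(snp_ids)
    if cols.size == 0:
        raise GenotypeError("cannot build a kinship matrix from an empty SNP set")
    Z = _scaled_centered(G, cols, alpha, raw_crossproduct)
    p_sub = cols.size
    K = Z @ Z.T / p_sub
    if normalization == "mean_diag":
        d = np.mean(np.diag(K))
        if d <= 0:
            raise GenotypeError("cannot normalize kinship with non-positive mean diagonal")
        K = K / d
    elif normalization != "p":
        raise GenotypeError(f"unknown kinship normalization {normalization!r}")
    return KinshipMatrix(K, list(G.sample_ids), p_sub, alpha=alpha,
                         normalization=normalization)


def kinship_overlap(K1: KinshipMatrix, K2: KinshipMatrix) -> float:
    """Spearman rank correlation between off-diagonal kinship entries.

    Used as the collinearity diagnostic between a pathway kinship and the
    complement kinship: high rho means the two kernels carry nearly the same
    relatedness signal and the two-kernel fit is poorly identified.
    """
    if K1.n != K2.n or K1.sample_ids != K2.sample_ids:
        raise GenotypeError("kinship matrices must share dimension and sample order")
    if K1.n < 3:
        raise GenotypeError("Spearman overlap needs at least 3 individuals")
    iu = np.triu_indices(K1.n, k=1)
    rho = stats.spearmanr(K1.values[iu], K2.values[iu]).statistic
    return float(rho)
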