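"""Synthetic genotypes, gene/pathway annotations and replicated phenotypes.

The generator emulates the study design downstream stages expect: biallelic
SNP dosages with a uniform MAF spectrum, genes tiled along chromosomes with a
pathway labelling, and phenotypes built from an additive polygenic
architecture in which one pathway's SNPs carry a controllable share of the
genomic heritability, observed in several replicates with replicate-level
noise. Everything is deterministic given ``SimConfig.seed``.

Per-SNP effects are Gaussian with equal variance within a group and act on
centered unstandardized dosages, so each SNP's expected contribution scales
with its heterozygosity (the alpha = 0 convention used for the kinship).
Each genetic component is rescaled so its realized sample variance equals its
target share of the unit total phenotypic variance, which makes
parameter-recovery checks sharp at moderate sample sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix


class SimulationError(ValueError):
    """Raised for infeasible simulation configurations."""


def _default_pathways() -> dict[str, int]:
    return {f"pw{i:02d}": 10 for i in range(1, 21)}


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic panel.

    Defaults describe a desk-scale panel with realistic structure: 300
    accessions, 4000 SNPs on 5 chromosomes with MAF uniform on (0.05, 0.5),
    400 genes of 2 kb separated by 2.5 kb (the typical intergenic distance in
    a compact plant genome), 20 pathways of 10 genes, a focal pathway carrying
    0.24 of phenotypic variance against a 0.36 polygenic background (total
    genomic h2 = 0.6), and 3 replicates with replicate variance 0.1.
    """

    n_individuals: int = 300
    n_snps: int = 4000
    n_chromosomes: int = 5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int = 400
    pathway_sizes: dict[str, int] = field(default_factory=_default_pathways)
    gene_length_bp: int = 2000
    intergenic_gap_bp: int = 2500
    buffer_bp: int = 2500
    h2_pathway: float = 0.24
    h2_background: float = 0.36
    n_replicates: int = 3
    replicate_var: float = 0.1
    seed: int = 0
    # optional block LD: SNPs in windows of this size are copies of the window
    # head with per-entry mutation probability ld_mutation; 1 = independent SNPs
    ld_block_snps: int = 1
    ld_mutation: float = 0.1

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimulationError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.h2_pathway < 0 or self.h2_background < 0:
            raise SimulationError("heritability shares must be non-negative")
        if self.h2_pathway + self.h2_background > 1.0 + 1e-12:
            raise SimulationError("h2_pathway + h2_background must be <= 1")
        if sum(self.pathway_sizes.values()) > self.n_genes:
            raise SimulationError("pathway gene counts exceed n_genes")
        if self.n_replicates < 1:
            raise SimulationError("need at least one replicate")
        if self.replicate_var < 0:
            raise SimulationError("replicate_var must be non-negative")
        if min(self.n_individuals, self.n_snps, self.n_chromosomes, self.n_genes) < 1:
            raise SimulationError("counts must be positive")
        if self.gene_length_bp < 1 or self.intergenic_gap_bp < 0 or self.buffer_bp < 0:
            raise SimulationError("lengths must be positive and buffers non-negative")
        if self.ld_block_snps < 1 or not 0.0 <= self.ld_mutation <= 1.0:
            raise SimulationError("invalid LD block settings")


@dataclass
class TruthRecord:
    """Ground truth for one simulated trait."""

    genetic_value: np.ndarray  # per-individual total genetic value
    pathway_value: np.ndarray  # per-individual pathway component
    realized_h2_pathway: float
    realized_h2_background: float

    def as_dict(self) -> dict:
        return {
            "genetic_value": self.genetic_value.tolist(),
            "pathway_value": self.pathway_value.tolist(),
            "realized_h2_pathway": self.realized_h2_pathway,
            "realized_h2_background": self.realized_h2_background,
        }


def _chromosome_layout(config: SimConfig) -> tuple[np.ndarray, np.ndarray, int]:
    """Genes per chromosome (round-robin remainder) and chromosome lengths."""
    base = config.n_genes // config.n_chromosomes
    counts = np.full(config.n_chromosomes, base, dtype=int)
    counts[: config.n_genes % config.n_chromosomes] += 1
    pitch = config.gene_length_bp + config.intergenic_gap_bp
    lengths = np.maximum(counts, 1) * pitch + config.intergenic_gap_bp
    return counts, lengths, pitch


def simulate_annotations(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tile non-overlapping genes along chromosomes and label pathway members.

    Returns ``(gene_table, pathway_map)`` with 1-based inclusive gene
    coordinates. Pathway membership is a seeded random draw without
    replacement, so pathway genes are scattered across the genome; genes left
    over belong to no pathway.
    """
    counts, _, pitch = _chromosome_layout(config)
    rows = []
    g = 0
    for c, cnt in enumerate(counts, start=1):
        for i in range(cnt):
            start = 1 + config.intergenic_gap_bp + i * pitch
            rows.append(
                {
                    "gene_id": f"gene{g:05d}",
                    "chrom": c,
                    "start": start,
                    "stop": start + config.gene_length_bp - 1,
                }
            )
            g += 1
    gene_table = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "stop"])

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    order = rng.permutation(config.n_genes)
    pw_rows = []
    cursor = 0
    for pw_id, size in config.pathway_sizes.items():
        members = order[cursor : cursor + size]
        cursor += size
        for gi in sorted(members):
            pw_rows.append({"pathway_id": pw_id, "gene_id": f"gene{gi:05d}"})
    pathway_map = pd.DataFrame(pw_rows, columns=["pathway_id", "gene_id"])
    return gene_table, pathway_map


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Independent biallelic dosages with per-SNP MAF uniform on maf_range.

    SNP positions are laid uniformly along each chromosome span implied by the
    gene layout (SNPs allocated to chromosomes proportionally to length), so
    buffered gene windows capture SNPs at a roughly constant density.
    """
    if config.n_snps < config.n_genes:
        raise SimulationError(
            f"n_snps={config.n_snps} is smaller than the {config.n_genes} genes "
            "implied by the layout; increase n_snps or reduce n_genes"
        )
    counts, lengths, _ = _chromosome_layout(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    snp_per_chrom = np.floor(config.n_snps * lengths / lengths.sum()).astype(int)
    while snp_per_chrom.sum() < config.n_snps:
        snp_per_chrom[int(np.argmax(lengths - snp_per_chrom))] += 1

    chroms, positions = [], []
    for c, (cnt, length) in enumerate(zip(snp_per_chrom, lengths), start=1):
        pos = np.sort(rng.choice(length, size=min(cnt, length), replace=False)) + 1
        chroms.append(np.full(pos.size, c))
        positions.append(pos)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)
    p = chrom.size

    lo, hi = config.maf_range
    f = rng.uniform(lo, hi, size=p)
    dosages = rng.binomial(2, f, size=(config.n_individuals, p)).astype(float)
    if config.ld_block_snps > 1:
        # copy-with-mutation within windows: correlated markers for
        # collinearity diagnostics, not a population-genetic LD model
        for start in range(0, p, config.ld_block_snps):
            head = dosages[:, start]
            for j in range(start + 1, min(start + config.ld_block_snps, p)):
                mutate = rng.random(config.n_individuals) < config.ld_mutation
                col = head.copy()
                col[mutate] = rng.binomial(2, f[j], size=int(mutate.sum()))
                dosages[:, j] = col
    return GenotypeMatrix(
        dosages,
        [f"acc{i:04d}" for i in range(config.n_individuals)],
        [f"snp{j:06d}" for j in range(p)],
        chrom,
        pos,
    )


def _rescale(component: np.ndarray, target_var: float) -> np.ndarray:
    v = float(np.var(component))
    if v <= 0:
        raise SimulationError(
            "genetic component has zero variance; cannot rescale to a positive share"
        )
    return component * np.sqrt(target_var / v)


def simulate_phenotypes(
    G: GenotypeMatrix,
    pathway_snps,
    config: SimConfig,
    trait: str = "trait1",
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Replicated phenotypes with a pathway / background variance split.

    Total phenotypic variance (of a single replicate, excluding replicate
    effects) is 1: the pathway component is rescaled to realized variance
    ``h2_pathway``, the background component (all remaining SNPs) to
    ``h2_background``, and i.i.d. residual noise with variance
    ``1 - h2_pathway - h2_background`` plus a shared per-replicate effect of
    variance ``replicate_var`` complete the record.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    pathway_snps = list(pathway_snps)
    if config.h2_pathway > 0 and len(pathway_snps) == 0:
        raise SimulationError("h2_pathway > 0 requires a nonempty pathway SNP set")
    noise_var = 1.0 - config.h2_pathway - config.h2_background
    if noise_var <= 0 and (config.replicate_var > 0 or noise_var < 0):
        if noise_var < 0:
            raise SimulationError("heritability shares exceed 1")
    X, _ = G.imputed()
    Z = X - X.mean(axis=0)
    member = np.zeros(G.p, dtype=bool)
    if pathway_snps:
        member[G.snp_index(pathway_snps)] = True

    n = G.n
    g_path = np.zeros(n)
    g_bg = np.zeros(n)
    if config.h2_pathway > 0:
        beta_m = rng.standard_normal(int(member.sum()))
        g_path = _rescale(Z[:, member] @ beta_m, config.h2_pathway)
    if config.h2_background > 0:
        bg = ~member
        if not bg.any():
            raise SimulationError("h2_background > 0 requires background SNPs")
        beta_b = rng.standard_normal(int(bg.sum()))
        g_bg = _rescale(Z[:, bg] @ beta_b, config.h2_background)
    g_total = g_path + g_bg

    rep_effects = (
        rng.normal(0.0, np.sqrt(config.replicate_var), size=config.n_replicates)
        if config.replicate_var > 0
        else np.zeros(config.n_replicates)
    )
    rows = []
    resid_var_sum = 0.0
    for r in range(config.n_replicates):
        eps = (
            rng.normal(0.0, np.sqrt(noise_var), size=n) if noise_var > 0 else np.zeros(n)
        )
        resid_var_sum += float(np.var(eps))
        values = g_total + rep_effects[r] + eps
        rows.append(
            pd.DataFrame(
                {
                    "accession": G.sample_ids,
                    "replicate": r + 1,
                    "trait": trait,
                    "value": values,
                }
            )
        )
    pheno = pd.concat(rows, ignore_index=True)

    # realized shares on the single-replicate scale (the target scale)
    var_total = float(np.var(g_total)) + resid_var_sum / config.n_replicates
    truth = TruthRecord(
        genetic_value=g_total,
        pathway_value=g_path,
        realized_h2_pathway=float(np.var(g_path) / var_total) if var_total > 0 else 0.0,
        realized_h2_background=float(np.var(g_bg) / var_total) if var_total > 0 else 0.0,
    )
    return pheno, truth


def write_simulation(
    outdir: str | Path,
    G: GenotypeMatrix,
    gene_table: pd.DataFrame,
    pathway_map: pd.DataFrame,
    pheno: pd.DataFrame,
    truth: dict[str, TruthRecord],
    plink: bool = True,
) -> dict[str, str]:
    """Write the simulated dataset to disk; returns the artifact paths."""
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if plink:
        _io.write_plink(G, outdir / "genotypes")
        paths["genotypes"] = str(outdir / "genotypes")
    else:
        _io.write_dosage_tsv(G, outdir / "genotypes.tsv")
        paths["genotypes"] = str(outdir / "genotypes.tsv")
    gene_table.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pathway_map.to_csv(outdir / "pathways.tsv", sep="\t", index=False)
    pheno.to_csv(outdir / "phenotypes.csv", index=False)
    (outdir / "truth.json").write_text(
        json.dumps({t: tr.as_dict() for t, tr in truth.items()}, indent=1)
    )
    paths.update(
        genes=str(outdir / "genes.tsv"),
        pathways=str(outdir / "pathways.tsv"),
        phenotypes=str(outdir / "phenotypes.csv"),
        truth=str(outdir / "truth.json"),
    )
    return paths
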