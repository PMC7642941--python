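"""Reusable simulation studies: null calibration and enrichment detection.

These drive the whole pipeline on synthetic panels with known ground truth:

* :func:`null_calibration_study` — traits with uniform per-SNP effects (no
  pathway enrichment); the empirical-null p-values should be uniform and the
  three-criteria rule should flag (almost) nothing.
* :func:`enrichment_study` — one pathway carries a fixed share of genomic
  heritability on a small fraction of SNPs; the pipeline should flag it and
  MultiBLUP should beat GBLUP in predictive ability.

Problem sizes default to desk scale (minutes on one CPU); they are arguments,
not constants.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .genotypes import filter_maf
from .phenotypes import prepare_blues
from .pipeline import AnalysisResult, PipelineConfig, run_analysis
from .simulate import SimConfig, simulate_annotations, simulate_genotypes, simulate_phenotypes


def _trait_blues(G, member_snps, sim: SimConfig, trait: str, seed: int):
    pheno, truth = simulate_phenotypes(
        G, member_snps, dataclasses.replace(sim, seed=seed), trait=trait
    )
    if sim.n_replicates == 1:
        y = pheno.set_index("accession")["value"]
        return y.loc[list(G.sample_ids)].rename(trait), truth
    blues, _ = prepare_blues(pheno, traits=[trait], boxcox=False)
    return blues[trait].loc[list(G.sample_ids)], truth


def null_calibration_study(
    seed: int = 0,
    n_traits: int = 20,
    n_individuals: int = 150,
    n_snps: int = 1500,
    n_genes: int = 200,
    n_pathways: int = 10,
    genes_per_pathway: int = 8,
    h2_total: float = 0.6,
    n_groups: int = 100,
    cv_folds: int = 10,
    cv_repeats: int = 5,
) -> AnalysisResult:
    """Traits with no pathway enrichment, analyzed against every pathway.

    Simulates one panel, draws ``n_traits`` polygenic traits whose SNP effects
    are uniform across the genome (each pathway's expected share of genomic
    heritability equals its SNP fraction), and runs the full analysis with
    ecdf null p-values. Returns the :class:`AnalysisResult` whose verdict
    table holds ``n_traits * n_pathways`` trait-pathway pairs.
    """
    sim = SimConfig(
        n_individuals=n_individuals,
        n_snps=n_snps,
        n_chromosomes=3,
        n_genes=n_genes,
        pathway_sizes={f"pw{i:02d}": genes_per_pathway for i in range(n_pathways)},
        h2_pathway=0.0,
        h2_background=h2_total,
        n_replicates=1,
        replicate_var=0.0,
        seed=seed,
    )
    G = filter_maf(simulate_genotypes(sim), 0.05)
    genes, pmap = simulate_annotations(sim)
    blues = {}
    for t in range(n_traits):
        col, _ = _trait_blues(
            G, [], sim, f"trait{t:02d}",
            (seed * 100003 + 7919 * t + 1) % (2**31),
        )
        blues[col.name] = col
    config = PipelineConfig(
        n_groups=n_groups,
        cv_folds=cv_folds,
        cv_repeats=cv_repeats,
        cv_seed=seed + 1,
        null_seed=seed + 2,
        pvalue_method="ecdf",
    )
    return run_analysis(G, genes, pmap, pd.DataFrame(blues), config)


def enrichment_study(
    seed: int = 0,
    n_individuals: int = 300,
    n_snps: int = 4000,
    n_genes: int = 400,
    n_pathways: int = 4,
    genes_per_pathway: int = 13,
    h2_total: float = 0.6,
    enriched_share: float = 0.4,
    n_replicates: int = 3,
    replicate_var: float = 0.1,
    n_groups: int = 100,
    cv_folds: int = 10,
    cv_repeats: int = 5,
    pvalue_method: str = "t",
) -> tuple[AnalysisResult, str, object]:
    """One enriched pathway among decoys, end to end through the pipeline.

    The first pathway's SNPs (roughly 5% of the genome) carry
    ``enriched_share`` of the genomic heritability ``h2_total``; phenotypes
    are observed in replicates, reduced to BLUEs, and analyzed against all
    pathways. Returns ``(result, enriched_pathway_id, truth)``.
    """
    sim = SimConfig(
        n_individuals=n_individuals,
        n_snps=n_snps,
        n_chromosomes=5,
        n_genes=n_genes,
        pathway_sizes={f"pw{i:02d}": genes_per_pathway for i in range(n_pathways)},
        h2_pathway=h2_total * enriched_share,
        h2_background=h2_total * (1.0 - enriched_share),
        n_replicates=n_replicates,
        replicate_var=replicate_var,
        seed=seed,
    )
    G = filter_maf(simulate_genotypes(sim), 0.05)
    genes, pmap = simulate_annotations(sim)
    from .genotypes import assign_pathway_snps

    parts = assign_pathway_snps(G, genes, pmap, sim.buffer_bp)
    focal = sorted(parts)[0]
    col, truth = _trait_blues(
        G, parts[focal].member_snps, sim, "trait1",
        (seed * 99991 + 13) % (2**31),
    )
    config = PipelineConfig(
        n_groups=n_groups,
        cv_folds=cv_folds,
        cv_repeats=cv_repeats,
        cv_seed=seed + 1,
        null_seed=seed + 2,
        pvalue_method=pvalue_method,
    )
    result = run_analysis(G, genes, pmap, pd.DataFrame({"trait1": col}), config)
    return result, focal, truth
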