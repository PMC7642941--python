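import numpy as np
import pytest

from pathpartblup import (
    SimConfig,
    assign_pathway_snps,
    filter_maf,
    simulate_annotations,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_panel():
    """A compact simulated panel shared by read-only tests.

    150 accessions, ~1.5k SNPs on 3 chromosomes, 200 genes, 10 pathways of 8
    genes, a polygenic trait with no pathway enrichment.
    """
    cfg = SimConfig(
        n_individuals=150,
        n_snps=1500,
        n_chromosomes=3,
        n_genes=200,
        pathway_sizes={f"pw{i}": 8 for i in range(10)},
        h2_pathway=0.0,
        h2_background=0.6,
        n_replicates=1,
        replicate_var=0.0,
        seed=11,
    )
    G = filter_maf(simulate_genotypes(cfg), 0.05)
    genes, pmap = simulate_annotations(cfg)
    parts = assign_pathway_snps(G, genes, pmap, cfg.buffer_bp)
    pheno, truth = simulate_phenotypes(G, [], cfg)
    y = (
        pheno.groupby("accession")["value"].mean().loc[G.sample_ids].to_numpy()
    )
    return {"cfg": cfg, "G": G, "genes": genes, "pmap": pmap, "parts": parts,
            "y": y, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
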