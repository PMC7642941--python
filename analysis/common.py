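"""Shared loading helpers for the numbered analysis scripts."""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
sys.path.insert(0, str(ROOT / "src"))

from pathpartblup import PipelineConfig  # noqa: E402
from pathpartblup import io as ppio  # noqa: E402
from pathpartblup.pipeline import prepare_genotypes  # noqa: E402

CONFIG = PipelineConfig(n_groups=100, cv_seed=77, null_seed=78)

TRAITS = ["aa1", "aa2", "aa1_t"]  # absolute (enriched, decoy) and one relative


def load_prepared():
    """Genotypes through MAF filter/PCs/partitions/kinship, plus the BLUEs."""
    G = ppio.read_genotypes(RESULTS / "data" / "genotypes")
    genes = ppio.read_gene_table(RESULTS / "data" / "genes.tsv")
    pmap = ppio.read_pathway_map(RESULTS / "data" / "pathways.tsv")
    blues = pd.read_csv(RESULTS / "blues.csv", index_col="accession")
    # outlier removal can delete every replicate of an accession; analyze the
    # accessions with complete BLUEs for the chosen traits
    complete = blues[TRAITS].dropna().index
    G = G.subset_samples([s for s in G.sample_ids if s in set(complete)])
    G, X, varexp, parts, K_all = prepare_genotypes(G, genes, pmap, CONFIG)
    blues = blues.loc[G.sample_ids]
    meta = json.loads((RESULTS / "data" / "meta.json").read_text())
    return G, X, varexp, parts, K_all, genes, blues, meta


def pathway_kernels(G, K_all, part, alpha=0.0):
    from pathpartblup import compute_kinship

    K_m = compute_kinship(G, part.member_snps, alpha=alpha)
    p, pm = K_all.n_snps, K_m.n_snps
    K_rest = (p * K_all.values - pm * K_m.values) / (p - pm)
    return K_m, K_rest
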