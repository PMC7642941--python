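"""Random-gene-group empirical null distributions for pathway enrichment.

The null hypothesis: a pathway explains no more trait variance than equally
many SNPs drawn from random gene groups. For each pathway, genes outside the
pathway are sampled one at a time (uniformly, without replacement) and their
buffered SNPs accumulated until the pathway's SNP count is reached; a
two-kernel model is refit with the group as kernel m, recording the
proportion of genomic heritability and the likelihood ratio against GBLUP.
One-sided p-values compare the observed pathway statistics to the null draws
either through the empirical CDF (add-one estimator) or through a one-sample
t-test of the null values against the observed value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, KinshipMatrix, PathwayPartition
from .reml import ModelError, ModelSpec, VarianceComponentFit, fit_reml, likelihood_ratio


class NullError(ValueError):
    """Raised for infeasible null-sampling requests."""


@dataclass
class NullDistribution:
    """Empirical null draws of (proportion h2, LR) for one trait-pathway pair."""

    pathway_id: str
    trait: str
    groups: pd.DataFrame  # columns: group, n_genes, n_snps, proportion, lr, converged
    observed_proportion: float | None
    observed_lr: float

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def pvalues(self) -> dict[str, float]:
        out = {}
        for stat, obs in (
            ("proportion", self.observed_proportion),
            ("lr", self.observed_lr),
        ):
            nulls = self.groups[stat].to_numpy(float)
            for method in ("ecdf", "t"):
                key = f"p_{stat}_{method}"
                out[key] = (
                    np.nan
                    if obs is None or not np.isfinite(obs)
                    else empirical_pvalue(obs, nulls, method=method)
                )
        return out


def sample_random_gene_group(
    gene_ids: list[str],
    gene_snps: dict[str, np.ndarray],
    excluded_genes,
    target_snps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str]]:
    """Sample genes until the deduplicated SNP set reaches ``target_snps``.

    Genes with zero mapped SNPs and excluded (pathway) genes are ineligible.
    Sampling stops at the first group whose size is >= target, so realized
    sizes overshoot by at most the largest single gene's SNP count. Returns
    (SNP column indices, sampled gene ids).
    """
    if target_snps < 1:
        raise NullError("target_snps must be >= 1")
    excluded = set(excluded_genes)
    eligible = [g for g in gene_ids if g not in excluded and len(gene_snps[g]) > 0]
    if not eligible:
        raise NullError("no eligible genes to sample from")
    order = rng.permutation(len(eligible))
    chosen: list[str] = []
    snps: list[np.ndarray] = []
    count = 0
    for i in order:
        g = eligible[i]
        chosen.append(g)
        snps.append(gene_snps[g])
        count = np.unique(np.concatenate(snps)).size
        if count >= target_snps:
            return np.unique(np.concatenate(snps)), chosen
    raise NullError(
        f"eligible gene pool exhausted at {count} SNPs before reaching "
        f"target {target_snps}"
    )


def build_null(
    trait: str,
    y: np.ndarray,
    X: np.ndarray,
    G: GenotypeMatrix,
    K_all: KinshipMatrix,
    partition: PathwayPartition,
    gene_snps: dict[str, np.ndarray],
    fit_gblup: VarianceComponentFit,
    fit_multi: VarianceComponentFit,
    n_groups: int = 1000,
    seed: int = 0,
    max_iter: int = 500,
) -> NullDistribution:
    """Null distribution of (proportion h2, LR) from random gene groups.

    The complement kernel of each group is obtained from the cross-product
    additivity p K_all = p_m K_m + p_notm K_notm, so only the group's own
    (low-rank) kinship is recomputed per draw. Group fits are warm-started
    from the observed GBLUP estimates split by SNP fraction. Non-convergent
    group fits are recorded as missing; more than 5% missing draws a warning.
    """
    rng = np.random.default_rng(seed)
    Ximp, _ = G.imputed()
    Z = Ximp - Ximp.mean(axis=0)
    p_total = K_all.n_snps
    if p_total != G.p:
        raise NullError("K_all must be built from all retained SNPs")
    target = partition.n_member_snps
    rows = []
    obs_lr, lr_fail = likelihood_ratio(fit_multi, fit_gblup)
    s2g = float(fit_gblup.variances[0])
    s2e = float(fit_gblup.residual_variance)
    for b in range(n_groups):
        cols, genes = sample_random_gene_group(
            list(gene_snps.keys()), gene_snps, partition.member_genes, target, rng
        )
        p_m = cols.size
        p_rest = p_total - p_m
        Zm = Z[:, cols]
        K_m = (Zm @ Zm.T) / p_m
        K_rest = (p_total * K_all.values - p_m * K_m) / p_rest
        spec = ModelSpec(y, X, [K_m, K_rest], ["group", "rest"])
        start = np.array([s2g * p_m / p_total, s2g * p_rest / p_total, s2e])
        prop = lr = np.nan
        conv = False
        try:
            fit = fit_reml(spec, max_iter=max_iter, start=start)
            conv = fit.converged
            if conv:
                prop = np.nan if fit.proportion is None else fit.proportion
                lr = likelihood_ratio(fit, fit_gblup)[0]
        except ModelError:
            pass
        rows.append(
            {
                "group": b,
                "n_genes": len(genes),
                "n_snps": int(p_m),
                "proportion": prop,
                "lr": lr,
                "converged": conv,
            }
        )
    groups = pd.DataFrame(rows)
    n_missing = int((~groups["converged"]).sum())
    if n_missing > 0.05 * n_groups:
        warnings.warn(
            f"{trait}/{partition.pathway_id}: {n_missing}/{n_groups} null fits "
            "did not converge",
            stacklevel=2,
        )
    return NullDistribution(
        pathway_id=partition.pathway_id,
        trait=trait,
        groups=groups,
        observed_proportion=fit_multi.proportion,
        observed_lr=obs_lr,
    )


def empirical_pvalue(observed: float, null_values, method: str = "ecdf") -> float:
    """One-sided p-value for observed > null.

    ``method="ecdf"``: add-one estimator (1 + #{null >= observed}) / (1 + N).
    ``method="t"``: one-sample t-test of the null draws against the observed
    value, alternative: null mean < observed.
    """
    nulls = np.asarray(null_values, dtype=float)
    nulls = nulls[np.isfinite(nulls)]
    if nulls.size == 0:
        raise NullError("all null values are missing")
    if method == "ecdf":
        return float((1 + np.sum(nulls >= observed)) / (1 + nulls.size))
    if method == "t":
        if np.allclose(nulls, nulls[0]):
            return 0.0 if observed > nulls[0] else 1.0
        return float(
            stats.ttest_1samp(nulls, popmean=observed, alternative="less").pvalue
        )
    raise NullError(f"unknown p-value method {method!r}")
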