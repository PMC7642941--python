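"""End-to-end orchestration: simulate -> prep -> fit -> cv -> null -> report.

``run_analysis`` is the in-memory core used by the tests and the acceptance
script: given genotypes, annotations and prepared BLUEs it fits GBLUP and the
per-pathway MultiBLUP models, runs the shared-fold cross-validation, builds
the random-gene-group nulls and applies the three-criteria decision rule.
``run_pipeline`` wraps it with file I/O, stage skipping and a checksum
manifest for resumable runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .crossval import compare_models, evaluate_model, make_folds
from .genotypes import (
    GenotypeMatrix,
    KinshipMatrix,
    assign_pathway_snps,
    compute_kinship,
    compute_pcs,
    filter_maf,
    gene_snp_map,
    kinship_overlap,
)
from .nulldist import build_null
from .phenotypes import prepare_blues
from .report import flag_pathways, write_report
from .reml import ModelSpec, fit_reml, likelihood_ratio
from .simulate import SimConfig, simulate_annotations, simulate_genotypes, simulate_phenotypes, write_simulation

log = logging.getLogger("pathpartblup")


@dataclass
class PipelineConfig:
    """Every coupled setting of the analysis, with the standard defaults:

    MAF filter > 0.05, 2 PC covariates, 2.5 kb gene buffer, alpha = 0 kinship
    scaling, REML capped at 500 iterations, 10-fold x 5-repeat CV (50 CVs),
    1000 random gene groups, BH correction per trait across pathways at a 10%
    FDR, and the t-test form of the null p-value.
    """

    sim: SimConfig | None = None
    genotypes: str | None = None
    genes: str | None = None
    pathways: str | None = None
    phenotypes: str | None = None
    maf_threshold: float = 0.05
    n_pcs: int = 2
    buffer_bp: int = 2500
    alpha: float = 0.0
    reml_max_iter: int = 500
    cv_folds: int = 10
    cv_repeats: int = 5
    cv_seed: int = 0
    n_groups: int = 1000
    null_seed: int = 0
    fdr: float = 0.10
    pvalue_method: str = "t"  # "t" or "ecdf"
    comparison_method: str = "paired"  # "paired" or "welch"
    outlier_alpha: float = 0.05
    boxcox: bool = True
    # leakage-control options (off by default: single PCA / full-sample
    # allele frequencies, reused across CV folds)
    foldwise_pcs: bool = False
    trainonly_frequencies: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        sim = data.pop("sim", None)
        cfg = cls(**data)
        if sim is not None:
            cfg.sim = SimConfig(**{
                k: (tuple(v) if k == "maf_range" else v) for k, v in sim.items()
            })
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.sim is not None:
            d["sim"] = asdict(self.sim)
        return d


@dataclass
class AnalysisResult:
    """Everything the decision report consumes, in memory."""

    verdicts: pd.DataFrame
    cv_records: pd.DataFrame
    null_records: pd.DataFrame
    diagnostics: pd.DataFrame
    fits: dict
    h2_gblup: dict


def prepare_genotypes(G: GenotypeMatrix, gene_table, pathway_map,
                      config: PipelineConfig):
    """MAF filter, PC covariates, pathway partitions, genome-wide kinship."""
    G = filter_maf(G, config.maf_threshold)
    pcs, varexp = compute_pcs(G, config.n_pcs)
    X = np.column_stack([np.ones(G.n), pcs])
    partitions = assign_pathway_snps(G, gene_table, pathway_map, config.buffer_bp)
    K_all = compute_kinship(G, alpha=config.alpha)
    return G, X, varexp, partitions, K_all


def _make_fold_builder(G: GenotypeMatrix, X_global: np.ndarray,
                       kernel_cols: list[np.ndarray], config: PipelineConfig):
    """Fold hook recomputing PCs and/or allele frequencies from the training
    fold only; returns None when both leakage-control flags are off."""
    if not (config.foldwise_pcs or config.trainonly_frequencies):
        return None
    Ximp, _ = G.imputed()

    def build(train, test):
        f = (Ximp[train] if config.trainonly_frequencies else Ximp).mean(0) / 2.0
        Z = Ximp - 2.0 * f
        if config.alpha != 0.0:
            Z = Z * (2.0 * f * (1.0 - f)) ** (config.alpha / 2.0)
        kernels_tr, cross = [], []
        for cols in kernel_cols:
            Ztr, Zte = Z[np.ix_(train, cols)], Z[np.ix_(test, cols)]
            kernels_tr.append(Ztr @ Ztr.T / cols.size)
            cross.append(Zte @ Ztr.T / cols.size)
        if config.foldwise_pcs:
            C = Ximp[train] - Ximp[train].mean(0)
            U, S, Vt = np.linalg.svd(C, full_matrices=False)
            X_tr = np.column_stack([np.ones(train.size),
                                    U[:, : config.n_pcs] * S[: config.n_pcs]])
        else:
            X_tr = X_global[train]
        return X_tr, kernels_tr, cross

    return build


def _pathway_kernels(G: GenotypeMatrix, K_all: KinshipMatrix, member_snps,
                     alpha: float):
    """Member kinship plus complement from cross-product additivity."""
    K_m = compute_kinship(G, member_snps, alpha=alpha)
    p, p_m = K_all.n_snps, K_m.n_snps
    K_rest = KinshipMatrix(
        (p * K_all.values - p_m * K_m.values) / (p - p_m),
        K_all.sample_ids, p - p_m, alpha=alpha,
    )
    return K_m, K_rest


def run_analysis(
    G: GenotypeMatrix,
    gene_table: pd.DataFrame,
    pathway_map: pd.DataFrame,
    blues: pd.DataFrame,
    config: PipelineConfig,
    traits: list[str] | None = None,
) -> AnalysisResult:
    """Fit, cross-validate, build nulls and apply the decision rule.

    ``blues`` is the wide accession x trait BLUE matrix; its index must match
    the genotype sample ids (inner-joined in order).
    """
    G, X, _, partitions, K_all = prepare_genotypes(G, gene_table, pathway_map, config)
    blues.index = blues.index.astype(str)
    missing = [s for s in G.sample_ids if s not in blues.index]
    if missing:
        raise ValueError(
            f"{len(missing)} genotyped sample(s) lack BLUEs (e.g. {missing[:3]})"
        )
    blues = blues.loc[G.sample_ids]
    gene_snps = gene_snp_map(G, gene_table, config.buffer_bp)
    folds = make_folds(G.sample_ids, config.cv_folds, config.cv_repeats,
                       config.cv_seed)
    if traits is None:
        traits = list(blues.columns)

    rows, cv_rows, null_rows, diag_rows = [], [], [], []
    fits: dict = {}
    h2_gblup: dict = {}
    for trait in traits:
        y = blues[trait].to_numpy(float)
        spec_g = ModelSpec(y, X, [K_all.values], ["all"])
        fit_g = fit_reml(spec_g, max_iter=config.reml_max_iter)
        h2_g = float(fit_g.h2[0])
        h2_gblup[trait] = h2_g
        fits[(trait, "gblup")] = fit_g
        cv_g = evaluate_model(
            y, X, [K_all.values], G.sample_ids, folds, h2_g, ["all"],
            max_iter=config.reml_max_iter,
            start=np.append(fit_g.variances, fit_g.residual_variance),
            fold_builder=_make_fold_builder(G, X, [np.arange(G.p)], config),
        )
        cv_rows.append(_cv_frame(cv_g, trait, "gblup", None))
        for pw_id, part in partitions.items():
            K_m, K_rest = _pathway_kernels(G, K_all, part.member_snps, config.alpha)
            spec_m = ModelSpec(y, X, [K_m.values, K_rest.values], ["pathway", "rest"])
            start = np.array([
                fit_g.variances[0] * K_m.n_snps / K_all.n_snps,
                fit_g.variances[0] * K_rest.n_snps / K_all.n_snps,
                fit_g.residual_variance,
            ])
            fit_m = fit_reml(spec_m, max_iter=config.reml_max_iter, start=start)
            fits[(trait, pw_id)] = fit_m
            lr, _ = likelihood_ratio(fit_m, fit_g)
            h2_m_total = float(fit_m.h2.sum())
            member_cols = G.snp_index(part.member_snps)
            rest_cols = np.setdiff1d(np.arange(G.p), member_cols)
            cv_m = evaluate_model(
                y, X, [K_m.values, K_rest.values], G.sample_ids, folds,
                h2_m_total, ["pathway", "rest"], max_iter=config.reml_max_iter,
                start=np.append(fit_m.variances, fit_m.residual_variance),
                fold_builder=_make_fold_builder(G, X, [member_cols, rest_cols],
                                                config),
            )
            cv_rows.append(_cv_frame(cv_m, trait, "multiblup", pw_id))
            p_pred, delta_r = compare_models(cv_m, cv_g, config.comparison_method)
            null = build_null(
                trait, y, X, G, K_all, part, gene_snps, fit_g, fit_m,
                n_groups=config.n_groups,
                seed=int(np.random.SeedSequence(
                    [config.null_seed, _stable_id(trait), _stable_id(pw_id)]
                ).generate_state(1)[0] % (2**31)),
                max_iter=config.reml_max_iter,
            )
            pv = null.pvalues()
            g = null.groups.assign(trait=trait, pathway=pw_id)
            null_rows.append(g)
            slope_m = float(cv_m.records["slope"].mean())
            slope_g = float(cv_g.records["slope"].mean())
            rows.append(
                {
                    "trait": trait,
                    "pathway": pw_id,
                    "n_member_genes": part.n_member_genes,
                    "n_member_snps": part.n_member_snps,
                    "proportion_h2": np.nan if fit_m.proportion is None else fit_m.proportion,
                    "lr": lr,
                    "h2_gblup": h2_g,
                    "h2_multiblup": h2_m_total,
                    "p_proportion": pv[f"p_proportion_{config.pvalue_method}"],
                    "p_lr": pv[f"p_lr_{config.pvalue_method}"],
                    "p_proportion_ecdf": pv["p_proportion_ecdf"],
                    "p_lr_ecdf": pv["p_lr_ecdf"],
                    "p_proportion_t": pv["p_proportion_t"],
                    "p_lr_t": pv["p_lr_t"],
                    "p_predictive": p_pred,
                    "delta_r": delta_r,
                    "delta_reliability": float(
                        cv_m.records["reliability"].mean()
                        - cv_g.records["reliability"].mean()
                    ),
                    "slope_multiblup": slope_m,
                    "slope_gblup": slope_g,
                    # Table-3-footnote convention: |slope - 1| differences
                    "delta_slope": abs(slope_m - 1.0) - abs(slope_g - 1.0),
                    "delta_rmse": cv_m.rmse - cv_g.rmse,
                }
            )
            diag_rows.append(
                {
                    "trait": trait,
                    "pathway": pw_id,
                    "snp_fraction": part.n_member_snps / K_all.n_snps,
                    "kinship_spearman": kinship_overlap(K_m, K_rest),
                    "proportion_h2": np.nan if fit_m.proportion is None else fit_m.proportion,
                    "delta_r": delta_r,
                }
            )
    results = pd.DataFrame(rows)
    verdicts = flag_pathways(results, fdr=config.fdr) if len(results) else results
    return AnalysisResult(
        verdicts=verdicts,
        cv_records=pd.concat(cv_rows, ignore_index=True) if cv_rows else pd.DataFrame(),
        null_records=pd.concat(null_rows, ignore_index=True) if null_rows else pd.DataFrame(),
        diagnostics=pd.DataFrame(diag_rows),
        fits=fits,
        h2_gblup=h2_gblup,
    )


def _cv_frame(cv, trait, model, pathway):
    rec = cv.records.copy()
    rec.insert(0, "trait", trait)
    rec.insert(1, "model", model)
    rec.insert(2, "pathway", pathway)
    return rec


# --- stage functions (the same science as run_analysis, one stage at a time,
# with JSON/TSV-ready outputs; used by the stage CLI and analysis scripts) ---


def _multiblup_start(fit_g, p_m: int, p_rest: int):
    p = p_m + p_rest
    return np.array([
        fit_g.variances[0] * p_m / p,
        fit_g.variances[0] * p_rest / p,
        fit_g.residual_variance,
    ])


def stage_fit_models(G, X, partitions, K_all, blues, traits,
                     config: PipelineConfig):
    """GBLUP + per-pathway MultiBLUP fits; returns (fits, diagnostics).

    ``fits`` maps "trait|gblup" / "trait|pathway" to the JSON-ready fit dict
    (with ``lr_vs_gblup`` on MultiBLUP entries); diagnostics carry the
    Spearman kinship-overlap collinearity measure per pair.
    """
    fits, diag = {}, []
    for trait in traits:
        y = blues[trait].to_numpy(float)
        fit_g = fit_reml(ModelSpec(y, X, [K_all.values], ["all"]),
                         max_iter=config.reml_max_iter)
        fits[f"{trait}|gblup"] = fit_g.as_dict()
        for pw, part in partitions.items():
            K_m, K_rest = _pathway_kernels(G, K_all, part.member_snps,
                                           config.alpha)
            fit_m = fit_reml(
                ModelSpec(y, X, [K_m.values, K_rest.values],
                          ["pathway", "rest"]),
                max_iter=config.reml_max_iter,
                start=_multiblup_start(fit_g, K_m.n_snps, K_rest.n_snps),
            )
            rec = fit_m.as_dict()
            rec["lr_vs_gblup"] = likelihood_ratio(fit_m, fit_g)[0]
            fits[f"{trait}|{pw}"] = rec
            diag.append({
                "trait": trait, "pathway": pw,
                "n_snps": part.n_member_snps,
                "snp_fraction": part.n_member_snps / K_all.n_snps,
                "kinship_spearman": kinship_overlap(K_m, K_rest),
                "proportion_h2": rec["proportion"],
                "lr": rec["lr_vs_gblup"],
            })
    return fits, pd.DataFrame(diag)


def stage_cross_validate(G, X, partitions, K_all, blues, traits,
                         config: PipelineConfig, fits: dict):
    """Shared-fold CV of GBLUP vs every MultiBLUP; returns (records, summary)."""
    folds = make_folds(G.sample_ids, config.cv_folds, config.cv_repeats,
                       config.cv_seed)
    records, summary = [], []
    for trait in traits:
        y = blues[trait].to_numpy(float)
        fg = fits[f"{trait}|gblup"]
        cv_g = evaluate_model(
            y, X, [K_all.values], G.sample_ids, folds,
            h2_full=fg["h2"]["all"], kernel_names=["all"],
            max_iter=config.reml_max_iter,
            start=np.array([fg["variances"]["all"], fg["residual_variance"]]),
            fold_builder=_make_fold_builder(G, X, [np.arange(G.p)], config),
        )
        records.append(_cv_frame(cv_g, trait, "gblup", None))
        for pw, part in partitions.items():
            K_m, K_rest = _pathway_kernels(G, K_all, part.member_snps,
                                           config.alpha)
            fm = fits[f"{trait}|{pw}"]
            member_cols = G.snp_index(part.member_snps)
            rest_cols = np.setdiff1d(np.arange(G.p), member_cols)
            cv_m = evaluate_model(
                y, X, [K_m.values, K_rest.values], G.sample_ids, folds,
                h2_full=sum(fm["h2"].values()),
                kernel_names=["pathway", "rest"],
                max_iter=config.reml_max_iter,
                start=np.array([fm["variances"]["pathway"],
                                fm["variances"]["rest"],
                                fm["residual_variance"]]),
                fold_builder=_make_fold_builder(G, X, [member_cols, rest_cols],
                                                config),
            )
            records.append(_cv_frame(cv_m, trait, "multiblup", pw))
            p_pred, delta_r = compare_models(cv_m, cv_g,
                                             config.comparison_method)
            summary.append({
                "trait": trait, "pathway": pw,
                "r_gblup": cv_g.mean_r, "r_multiblup": cv_m.mean_r,
                "delta_r": delta_r, "p_predictive": p_pred,
                "delta_reliability": float(
                    cv_m.records["reliability"].mean()
                    - cv_g.records["reliability"].mean()),
                "rmse_gblup": cv_g.rmse, "rmse_multiblup": cv_m.rmse,
                "slope_gblup": float(cv_g.records["slope"].mean()),
                "slope_multiblup": float(cv_m.records["slope"].mean()),
            })
    return pd.concat(records, ignore_index=True), pd.DataFrame(summary)


def stage_empirical_null(G, X, partitions, K_all, gene_table, blues, traits,
                         config: PipelineConfig):
    """Random-gene-group nulls for each pair; returns (records, pvalues)."""
    gene_snps = gene_snp_map(G, gene_table, config.buffer_bp)
    rows, pvals = [], []
    for trait in traits:
        y = blues[trait].to_numpy(float)
        fit_g = fit_reml(ModelSpec(y, X, [K_all.values], ["all"]),
                         max_iter=config.reml_max_iter)
        for pw, part in partitions.items():
            K_m, K_rest = _pathway_kernels(G, K_all, part.member_snps,
                                           config.alpha)
            fit_m = fit_reml(
                ModelSpec(y, X, [K_m.values, K_rest.values]),
                max_iter=config.reml_max_iter,
                start=_multiblup_start(fit_g, K_m.n_snps, K_rest.n_snps),
            )
            null = build_null(
                trait, y, X, G, K_all, part, gene_snps, fit_g, fit_m,
                n_groups=config.n_groups,
                seed=int(np.random.SeedSequence(
                    [config.null_seed, _stable_id(trait), _stable_id(pw)]
                ).generate_state(1)[0] % (2**31)),
                max_iter=config.reml_max_iter,
            )
            rows.append(null.groups.assign(trait=trait, pathway=pw))
            pvals.append({
                "trait": trait, "pathway": pw,
                "n_member_genes": part.n_member_genes,
                "n_member_snps": part.n_member_snps,
                "observed_proportion": null.observed_proportion,
                "observed_lr": null.observed_lr,
                **null.pvalues(),
            })
    return pd.concat(rows, ignore_index=True), pd.DataFrame(pvals)


def stage_decision_report(null_pvalues: pd.DataFrame, cv_summary: pd.DataFrame,
                          config: PipelineConfig) -> pd.DataFrame:
    """Merge stage outputs, BH-adjust and apply the three-criteria rule."""
    results = null_pvalues.merge(cv_summary, on=["trait", "pathway"])
    results["p_proportion"] = results[f"p_proportion_{config.pvalue_method}"]
    results["p_lr"] = results[f"p_lr_{config.pvalue_method}"]
    results["delta_slope"] = (
        (results["slope_multiblup"] - 1).abs()
        - (results["slope_gblup"] - 1).abs()
    )
    results["delta_rmse"] = results["rmse_multiblup"] - results["rmse_gblup"]
    return flag_pathways(results, fdr=config.fdr)


def _stable_id(s: str) -> int:
    return int.from_bytes(hashlib.sha256(s.encode()).digest()[:4], "big")


# --- file-based pipeline ------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 force: bool = False) -> dict:
    """Execute all stages against ``outdir``, skipping stages whose outputs
    already exist with matching checksums; returns the artifact manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() and not force
        else {"stages": {}, "artifacts": {}}
    )

    def stage_done(name: str, outputs: list[Path]) -> bool:
        if force or name not in manifest["stages"]:
            return False
        for p in outputs:
            rec = manifest["artifacts"].get(str(p))
            if rec is None or not p.exists() or _sha256(p) != rec:
                return False
        return True

    def record(name: str, outputs: list[Path], t0: float) -> None:
        for p in outputs:
            manifest["artifacts"][str(p)] = _sha256(p)
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
        manifest_path.write_text(json.dumps(manifest, indent=1))
        log.info("stage %s done in %.1fs", name, time.time() - t0)

    # stage: simulate (optional)
    simdir = outdir / "sim"
    if config.sim is not None:
        outputs = [simdir / f for f in
                   ["genes.tsv", "pathways.tsv", "phenotypes.csv", "truth.json",
                    "genotypes.bed", "genotypes.bim", "genotypes.fam"]]
        if not stage_done("simulate", outputs):
            t0 = time.time()
            sim = config.sim
            G = simulate_genotypes(sim)
            genes, pmap = simulate_annotations(sim)
            parts = assign_pathway_snps(G, genes, pmap, sim.buffer_bp)
            focal = next(iter(parts)) if parts else None
            pheno, truth = simulate_phenotypes(
                G, parts[focal].member_snps if focal and sim.h2_pathway > 0 else [],
                sim,
            )
            write_simulation(simdir, G, genes, pmap, pheno, {"trait1": truth})
            record("simulate", outputs, t0)
        geno_path = simdir / "genotypes"
        genes_path, pw_path = simdir / "genes.tsv", simdir / "pathways.tsv"
        pheno_path = simdir / "phenotypes.csv"
    else:
        if not all([config.genotypes, config.genes, config.pathways,
                    config.phenotypes]):
            raise ValueError("provide either a sim block or all input paths")
        geno_path = Path(config.genotypes)
        genes_path, pw_path = Path(config.genes), Path(config.pathways)
        pheno_path = Path(config.phenotypes)

    # stage: phenotype prep
    prepdir = outdir / "prep"
    prepdir.mkdir(exist_ok=True)
    blues_path = prepdir / "blues.csv"
    prep_report = prepdir / "prep_report.csv"
    if not stage_done("prep_pheno", [blues_path, prep_report]):
        t0 = time.time()
        raw = _io.read_phenotypes(pheno_path)
        blues, rep = prepare_blues(raw, outlier_alpha=config.outlier_alpha,
                                   boxcox=config.boxcox)
        blues.to_csv(blues_path, index_label="accession")
        rep.to_csv(prep_report, index=False)
        record("prep_pheno", [blues_path, prep_report], t0)

    # stage: analysis (fit + cv + null + report)
    repdir = outdir / "report"
    outputs = [repdir / "results_master.tsv", repdir / "results_flagged.tsv",
               repdir / "diagnostics.tsv", outdir / "cv_records.tsv",
               outdir / "null_records.tsv"]
    if not stage_done("analysis", outputs):
        t0 = time.time()
        G = _io.read_genotypes(geno_path)
        genes = _io.read_gene_table(genes_path)
        pmap = _io.read_pathway_map(pw_path)
        blues = pd.read_csv(blues_path, index_col="accession")
        res = run_analysis(G, genes, pmap, blues, config)
        write_report(res.verdicts, repdir, res.diagnostics)
        res.cv_records.to_csv(outdir / "cv_records.tsv", sep="\t", index=False)
        res.null_records.to_csv(outdir / "null_records.tsv", sep="\t", index=False)
        record("analysis", outputs, t0)

    return manifest
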