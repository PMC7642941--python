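"""Phenotype preparation: outlier removal, Box-Cox, BLUEs, ratio traits.

Raw replicated measurements become one best linear unbiased estimate (BLUE)
per accession and trait, via the mixed model

    value = accession (fixed) + replicate (random) + error,

in three narrated steps: (1) flag and drop observations whose studentized
deleted residual exceeds a Bonferroni-adjusted t critical value, (2) Box-Cox
transform each trait, (3) estimate the accession fixed effects by GLS with
the replicate variance component from REML. Ratio traits (relative levels and
within-family ratios) are then derived from the BLUEs of absolute traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reml import ModelSpec, fit_reml


class PhenotypeError(ValueError):
    """Raised for unusable phenotype inputs."""


@dataclass
class FamilyMap:
    """Trait -> biochemical family labelling used to derive ratio traits."""

    families: dict[str, list[str]]  # family -> member absolute traits

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for fam, traits in self.families.items():
            for t in traits:
                if t in seen:
                    raise PhenotypeError(
                        f"trait {t!r} assigned to both {seen[t]!r} and {fam!r}"
                    )
                seen[t] = fam

    @property
    def trait_to_family(self) -> dict[str, str]:
        return {t: f for f, ts in self.families.items() for t in ts}

    @property
    def member_traits(self) -> list[str]:
        return [t for ts in self.families.values() for t in ts]


def _trait_arrays(raw: pd.DataFrame, trait: str):
    sub = raw.loc[raw["trait"] == trait]
    if sub.empty:
        raise PhenotypeError(f"trait {trait!r} absent from phenotype table")
    if sub.duplicated(["accession", "replicate"]).any():
        raise PhenotypeError(f"duplicated (accession, replicate) rows for {trait!r}")
    y = sub["value"].to_numpy(float)
    acc = sub["accession"].to_numpy()
    rep = sub["replicate"].to_numpy()
    return sub, y, acc, rep


def _design(acc: np.ndarray, rep: np.ndarray):
    """Cell-means accession design and the replicate-incidence kernel ZZ'."""
    acc_levels, acc_idx = np.unique(acc, return_inverse=True)
    rep_levels, rep_idx = np.unique(rep, return_inverse=True)
    X = np.zeros((acc.size, acc_levels.size))
    X[np.arange(acc.size), acc_idx] = 1.0
    Zr = np.zeros((acc.size, rep_levels.size))
    Zr[np.arange(acc.size), rep_idx] = 1.0
    return X, Zr @ Zr.T, acc_levels


def _replicate_model(y, acc, rep):
    X, K_rep, acc_levels = _design(acc, rep)
    spec = ModelSpec(y, X, [K_rep], ["replicate"])
    fit = fit_reml(spec, tol=1e-8)
    V = fit.variances[0] * K_rep + fit.residual_variance * np.eye(y.size)
    return spec, fit, V, X, acc_levels


def studentized_deleted_residuals(raw: pd.DataFrame, trait: str) -> pd.Series:
    """Leave-one-out deletion residuals under the replicate mixed model.

    Variance components are held at the full-data REML estimates; for each
    observation the accession fixed effects are re-estimated by GLS without
    it and the observation is predicted from its conditional (kriging)
    distribution. The returned statistic is the prediction error divided by
    its standard error, indexed like the trait's rows in ``raw``.
    """
    sub, y, acc, rep = _trait_arrays(raw, trait)
    if len(np.unique(acc)) < 2 or len(np.unique(rep)) < 2:
        raise PhenotypeError("need >=2 accessions and >=2 replicates per accession")
    _, fit, V, X, _ = _replicate_model(y, acc, rep)
    if fit.residual_variance <= 0:
        raise PhenotypeError("non-positive residual variance estimate")
    # exact GLS leave-one-out identity: with P the REML projection
    # P = V^-1 - V^-1 X (X'V^-1 X)^- X'V^-1, the deleted prediction error is
    # (Py)_i / P_ii with variance 1 / P_ii, so t_i = (Py)_i / sqrt(P_ii)
    Vi = np.linalg.inv(V)
    ViX = Vi @ X
    P = Vi - ViX @ np.linalg.pinv(X.T @ ViX) @ ViX.T
    Py = P @ y
    dP = np.clip(np.diag(P), 1e-300, None)
    return pd.Series(Py / np.sqrt(dP), index=sub.index)


def detect_outliers(raw: pd.DataFrame, trait: str, alpha: float = 0.05) -> pd.Index:
    """Rows of ``raw`` flagged as outliers for ``trait``.

    The cutoff is the two-sided t critical value at family-wise level
    ``alpha`` with Bonferroni correction over the trait's observations
    (df = N - #accessions - 1).
    """
    sub, y, acc, _ = _trait_arrays(raw, trait)
    if np.allclose(y, y[0]):
        return pd.Index([])
    t = studentized_deleted_residuals(raw, trait)
    n = len(t)
    df = max(n - len(np.unique(acc)) - 1, 1)
    crit = stats.t.ppf(1.0 - alpha / (2.0 * n), df)
    return t.index[np.abs(t.to_numpy()) > crit]


def boxcox_transform(
    values: np.ndarray, lmbda: float | None = None
) -> tuple[np.ndarray, float]:
    """Box-Cox transform with lambda chosen on a grid over [-2, 2], step 0.01.

    The profile log-likelihood is maximized over the grid; the transform is
    (y^lambda - 1)/lambda, natural log at lambda = 0. Non-positive values are
    shifted above zero with a warning; constant input is returned unchanged
    (lambda = 1) with a warning.
    """
    y = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(y)):
        raise PhenotypeError("non-finite trait values")
    if np.allclose(y, y[0] if y.size else 0.0):
        warnings.warn("constant trait: Box-Cox skipped (identity)", stacklevel=2)
        return y.copy(), 1.0
    if np.min(y) <= 0:
        shift = -np.min(y) + 1e-6 * np.ptp(y)
        warnings.warn(
            f"non-positive values: shifting by {shift:.6g} before Box-Cox",
            stacklevel=2,
        )
        y = y + shift
    if lmbda is None:
        grid = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.01), 10)
        llf = np.array([stats.boxcox_llf(lam, y) for lam in grid])
        lmbda = float(grid[int(np.argmax(llf))])
    if abs(lmbda) < 1e-12:
        return np.log(y), 0.0
    return (y**lmbda - 1.0) / lmbda, float(lmbda)


def compute_blues(raw: pd.DataFrame, trait: str) -> pd.Series:
    """Per-accession BLUEs from the one-random-effect replicate model.

    Generalized-least-squares accession estimates with the replicate variance
    component from REML (kernel = replicate-incidence cross-product). In a
    balanced design these equal accession means; with missing replicates they
    are the proper GLS solution. Accessions with no observations are absent.
    """
    _, y, acc, rep = _trait_arrays(raw, trait)
    if len(np.unique(rep)) < 2 or np.var(y) == 0:
        # degenerate: no replicate structure to model
        return pd.Series(y, index=acc).groupby(level=0).mean().rename(trait)
    _, fit, V, X, acc_levels = _replicate_model(y, acc, rep)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    if np.linalg.matrix_rank(XtViX) < XtViX.shape[0]:
        raise PhenotypeError("singular accession design (an accession has no data?)")
    beta = np.linalg.solve(XtViX, X.T @ np.linalg.solve(V, y))
    return pd.Series(beta, index=acc_levels, name=trait)


def prepare_blues(
    raw: pd.DataFrame,
    traits: list[str] | None = None,
    outlier_alpha: float = 0.05,
    boxcox: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full preparation: outliers -> Box-Cox -> BLUEs, for each trait.

    Returns (wide BLUE matrix indexed by accession, per-trait report with the
    outlier count and selected lambda).
    """
    if traits is None:
        traits = sorted(raw["trait"].unique())
    blues, report = {}, []
    for trait in traits:
        flagged = detect_outliers(raw, trait, alpha=outlier_alpha)
        clean = raw.drop(index=flagged)
        lam = np.nan
        if boxcox:
            sub = clean.loc[clean["trait"] == trait]
            transformed, lam = boxcox_transform(sub["value"].to_numpy())
            clean = clean.copy()
            clean.loc[sub.index, "value"] = transformed
        blues[trait] = compute_blues(clean, trait)
        report.append(
            {"trait": trait, "n_outliers_removed": len(flagged), "boxcox_lambda": lam}
        )
    return pd.DataFrame(blues), pd.DataFrame(report)


def derive_ratio_traits(blues: pd.DataFrame, family_map: FamilyMap) -> pd.DataFrame:
    """Extend a BLUE matrix of absolute traits with totals and ratio traits.

    Adds: ``Total`` (sum over all member absolute traits), ``Total_<family>``
    per family, relative traits ``<trait>_t`` (absolute / Total) and family
    ratios ``<trait>_Fam`` (absolute / family total). Accessions with a zero
    or negative denominator get NaN for the affected ratios, with a warning.
    """
    missing = [t for t in family_map.member_traits if t not in blues.columns]
    if missing:
        raise PhenotypeError(f"family map references absent traits: {missing}")
    out = blues.copy()
    members = family_map.member_traits
    total = blues[members].sum(axis=1)
    bad = total <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} accession(s) with non-positive trait total; "
            "their relative traits are NaN",
            stacklevel=2,
        )
    total = total.where(~bad)
    out["Total"] = total
    for fam, traits in family_map.families.items():
        fam_total = blues[traits].sum(axis=1)
        fam_bad = fam_total <= 0
        if fam_bad.any():
            warnings.warn(
                f"{int(fam_bad.sum())} accession(s) with non-positive "
                f"{fam} family total; family ratios are NaN",
                stacklevel=2,
            )
        fam_total = fam_total.where(~fam_bad)
        out[f"Total_{fam}"] = fam_total
        for t in traits:
            out[f"{t}_t"] = blues[t] / total
            out[f"{t}_Fam"] = blues[t] / fam_total
    return out
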