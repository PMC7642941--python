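"""Repeated k-fold cross-validation of genomic prediction models.

The protocol is 10-fold cross-validation with a one-fold holdout, repeated 5
times (50 CVs per trait-model); the identical fold plan is reused for GBLUP
and MultiBLUP so their predictive abilities are paired. Per CV the variance
components are refit on the training folds, GEBVs are predicted for the
held-out individuals, and four metrics are computed: predictive ability
r(GEBV, BLUE), reliability r^2 / h^2 (h^2 from the full-data fit of the same
model class), the bias slope of BLUE regressed on GEBV (1 = unbiased), and an
aggregate RMSE over all CVs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .reml import ModelSpec, VarianceComponentFit, fit_reml, predict_gebv


class CVError(ValueError):
    """Raised for invalid cross-validation setups."""


@dataclass
class FoldPlan:
    """One holdout fold within one repeat."""

    repeat: int
    fold: int
    test_ids: list[str]


@dataclass
class CVResult:
    """Per-CV metrics plus the aggregate RMSE for one trait-model."""

    records: pd.DataFrame  # columns: repeat, fold, r, reliability, slope, mse, n_test
    rmse: float
    h2_full: float
    gebv: pd.DataFrame  # columns: repeat, fold, accession, gebv, blue

    @property
    def n_cv(self) -> int:
        return len(self.records)

    @property
    def mean_r(self) -> float:
        return float(self.records["r"].mean())

    def summary(self) -> dict:
        rec = self.records
        return {
            "n_cv": self.n_cv,
            "mean_r": self.mean_r,
            "se_r": float(rec["r"].std(ddof=1) / np.sqrt(len(rec))),
            "mean_reliability": float(rec["reliability"].mean()),
            "mean_slope": float(rec["slope"].mean()),
            "rmse": self.rmse,
            "h2_full": self.h2_full,
        }


def make_folds(
    sample_ids, k: int = 10, repeats: int = 5, seed: int = 0
) -> list[FoldPlan]:
    """Uniform random partitions into k folds per repeat, deterministic by seed."""
    ids = list(sample_ids)
    n = len(ids)
    if k > n:
        raise CVError(f"k={k} folds exceed n={n} individuals")
    if k < 2:
        raise CVError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    plans = []
    for rep in range(1, repeats + 1):
        order = rng.permutation(n)
        for fold, chunk in enumerate(np.array_split(order, k), start=1):
            plans.append(FoldPlan(rep, fold, [ids[i] for i in chunk]))
    return plans


def fold_metrics(gebv: np.ndarray, blue: np.ndarray, h2_full: float) -> dict:
    """Per-CV metrics: r, reliability r^2/h^2, bias slope, MSE.

    The slope regresses BLUE on GEBV (slope 1 = unbiased). Degenerate GEBVs
    (essentially constant) yield NaN for r, reliability and slope.
    """
    gebv = np.asarray(gebv, float)
    blue = np.asarray(blue, float)
    mse = float(np.mean((blue - gebv) ** 2))
    # GEBVs at the variance floor are numerical noise, not predictions
    if np.std(gebv) < 1e-6 * max(np.std(blue), 1.0):
        return {"r": np.nan, "reliability": np.nan, "slope": np.nan, "mse": mse}
    r = float(np.corrcoef(gebv, blue)[0, 1])
    slope = float(np.polyfit(gebv, blue, 1)[0])
    rel = r**2 / h2_full if h2_full > 0 else np.nan
    return {"r": r, "reliability": rel, "slope": slope, "mse": mse}


def evaluate_model(
    y: np.ndarray,
    X: np.ndarray,
    kernels: list[np.ndarray],
    sample_ids,
    fold_plan: list[FoldPlan],
    h2_full: float,
    kernel_names: list[str] | None = None,
    max_iter: int = 500,
    start: np.ndarray | None = None,
    fold_builder=None,
) -> CVResult:
    """Run the fold plan for one model class and compute the four metrics.

    ``h2_full`` must be the genomic heritability from the same model class
    fitted on all individuals (it scales reliability). Kinships are the
    full-sample matrices sliced by fold; passing ``fold_builder(train, test)
    -> (X_train, kernels_train, kernels_cross)`` overrides the slicing, e.g.
    to recompute PCs or allele frequencies from the training fold only.
    Folds where the GEBVs are essentially constant yield r = NaN and are
    excluded from means, with a logged count.
    """
    y = np.asarray(y, float).ravel()
    ids = list(sample_ids)
    index = {s: i for i, s in enumerate(ids)}
    rows, gebv_rows = [], []
    n_degenerate = 0
    for plan in fold_plan:
        test = np.array([index[s] for s in plan.test_ids])
        train = np.setdiff1d(np.arange(len(ids)), test)
        if fold_builder is None:
            X_tr = X[train]
            kernels_tr = [K[np.ix_(train, train)] for K in kernels]
            cross = [K[np.ix_(test, train)] for K in kernels]
        else:
            X_tr, kernels_tr, cross = fold_builder(train, test)
        spec_tr = ModelSpec(
            y[train], X_tr, kernels_tr,
            kernel_names or [f"K{i+1}" for i in range(len(kernels))],
        )
        fit = fit_reml(spec_tr, max_iter=max_iter, start=start)
        g_hat = predict_gebv(fit, spec_tr, cross)
        g_obs = y[test]
        metrics = fold_metrics(g_hat, g_obs, h2_full)
        if not np.isfinite(metrics["r"]):
            n_degenerate += 1
        rows.append(
            {"repeat": plan.repeat, "fold": plan.fold, **metrics, "n_test": len(test)}
        )
        for s, gh, go in zip(plan.test_ids, g_hat, g_obs):
            gebv_rows.append(
                {"repeat": plan.repeat, "fold": plan.fold, "accession": s,
                 "gebv": gh, "blue": go}
            )
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} fold(s) with zero-variance GEBVs excluded from r",
            stacklevel=2,
        )
    records = pd.DataFrame(rows)
    rmse = float(np.sqrt(records["mse"].mean()))
    return CVResult(records, rmse, float(h2_full), pd.DataFrame(gebv_rows))


def compare_models(
    cv_multi: CVResult, cv_gblup: CVResult, method: str = "paired"
) -> tuple[float, float]:
    """One-sided test that MultiBLUP beats GBLUP in predictive ability.

    Returns ``(p_value, delta_r)`` with delta_r the mean of the per-CV paired
    differences. ``method="paired"`` runs the one-sample t-test on the
    differences (the shared fold plan makes CVs paired); ``method="welch"``
    runs the unpaired unequal-variance variant.
    """
    r1 = cv_multi.records["r"].to_numpy()
    r2 = cv_gblup.records["r"].to_numpy()
    if r1.size != r2.size:
        raise CVError("CV results have different numbers of folds")
    ok = np.isfinite(r1) & np.isfinite(r2)
    r1, r2 = r1[ok], r2[ok]
    if r1.size < 2:
        raise CVError("fewer than 2 usable paired CVs")
    d = r1 - r2
    delta = float(d.mean())
    if method == "paired":
        if np.allclose(d, d[0]):
            p = 0.0 if d[0] > 0 else 1.0  # degenerate-variance limit
        else:
            p = float(stats.ttest_rel(r1, r2, alternative="greater").pvalue)
    elif method == "welch":
        p = float(stats.ttest_ind(r1, r2, equal_var=False, alternative="greater").pvalue)
    else:
        raise CVError(f"unknown comparison method {method!r}")
    return p, delta
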