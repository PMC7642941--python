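"""Variance-component mixed models: AI-REML, heritability partitions, BLUP.

Model: y = X beta + sum_k u_k + e with u_k ~ N(0, sigma2_k K_k) and
e ~ N(0, sigma2_e I), so V = sum_k sigma2_k K_k + sigma2_e I. With one
genome-wide kinship this is GBLUP; with a pathway kinship and its complement
kinship it is the two-kernel MultiBLUP. Fitting maximizes the restricted
likelihood by average-information (AI) updates with an EM fallback whenever an
AI step would leave the feasible region or decrease the likelihood; variances
are floored at 1e-8 times the phenotypic variance, which is how the [0,1]
heritability constraint is enforced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve

_LOG_2PI = float(np.log(2.0 * np.pi))


class ModelError(ValueError):
    """Raised for ill-posed model specifications."""


@dataclass
class ModelSpec:
    """Response, fixed-effect design, and ordered genetic kernels.

    ``y`` holds one observation per individual (BLUEs in the headline
    pipeline, so the observation->individual incidence is the identity);
    ``X`` is the fixed design (intercept + PC covariates); ``kernels`` are
    n x n kinship arrays sharing the sample order of ``y``.
    """

    y: np.ndarray
    X: np.ndarray
    kernels: list[np.ndarray]
    kernel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.size:
            raise ModelError("fixed design rows do not match response length")
        self.kernels = [np.asarray(K, dtype=float) for K in self.kernels]
        for K in self.kernels:
            if K.shape != (self.y.size, self.y.size):
                raise ModelError(
                    f"kernel shape {K.shape} does not match n={self.y.size}"
                )
        if not self.kernel_names:
            self.kernel_names = [f"K{i + 1}" for i in range(len(self.kernels))]

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def n_kernels(self) -> int:
        return len(self.kernels)


@dataclass
class VarianceComponentFit:
    """REML estimates for one model: variances, heritabilities, likelihood."""

    variances: np.ndarray  # per-kernel genetic variances
    residual_variance: float
    loglik: float
    h2: np.ndarray  # per-kernel genomic heritability (share of total variance)
    proportion: float | None  # h2_m / (h2_m + h2_notm); None if undefined
    iterations: int
    converged: bool
    kernel_names: list[str]
    beta: np.ndarray  # GLS fixed-effect estimates at the optimum

    def as_dict(self) -> dict:
        return {
            "variances": dict(zip(self.kernel_names, map(float, self.variances))),
            "residual_variance": float(self.residual_variance),
            "loglik": float(self.loglik),
            "h2": dict(zip(self.kernel_names, map(float, self.h2))),
            "proportion": None if self.proportion is None else float(self.proportion),
            "iterations": self.iterations,
            "converged": self.converged,
        }


def _build_v(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    V = np.eye(spec.n) * theta[-1]
    for s2, K in zip(theta[:-1], spec.kernels):
        V += s2 * K
    return V


def _reml_pieces(spec: ModelSpec, theta: np.ndarray):
    """Cholesky-based REML quantities shared by likelihood and derivatives."""
    y, X = spec.y, spec.X
    n, r = X.shape
    V = _build_v(spec, theta)
    try:
        L = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(V)
        raise ModelError(f"singular covariance matrix (cond={cond:.3e})") from exc
    logdet_v = 2.0 * np.sum(np.log(np.diag(L[0])))
    ViX = cho_solve(L, X)
    Viy = cho_solve(L, y)
    XtViX = X.T @ ViX
    sign, logdet_xvx = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise ModelError("singular fixed-effect information matrix X'V^-1X")
    beta = solve(XtViX, X.T @ Viy, assume_a="pos")
    Py = Viy - ViX @ beta
    ll = -0.5 * ((n - r) * _LOG_2PI + logdet_v + logdet_xvx + float(y @ Py))
    return L, ViX, XtViX, beta, Py, ll


def reml_loglik(spec: ModelSpec, variances, residual_variance: float | None = None) -> float:
    """Restricted log-likelihood at given variances.

    ``variances`` is either the full vector (per-kernel variances followed by
    the residual variance) or the per-kernel part with ``residual_variance``
    passed separately.
    """
    theta = np.asarray(variances, dtype=float).ravel()
    if residual_variance is not None:
        theta = np.append(theta, float(residual_variance))
    if theta.size != spec.n_kernels + 1:
        raise ModelError(
            f"expected {spec.n_kernels + 1} variances (kernels + residual), "
            f"got {theta.size}"
        )
    if np.any(theta < 0) or not np.any(theta > 0):
        raise ModelError("variances must be non-negative and not all zero")
    return _reml_pieces(spec, theta)[5]


def _project(L, ViX, XtViX, M: np.ndarray) -> np.ndarray:
    """Apply P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1 to columns of M."""
    ViM = cho_solve(L, M)
    return ViM - ViX @ solve(XtViX, ViX.T @ M if M.ndim > 1 else ViX.T @ M,
                             assume_a="pos")


def _score_and_ai(spec: ModelSpec, theta: np.ndarray):
    """Log-likelihood, score vector and average-information matrix."""
    y, X = spec.y, spec.X
    n = spec.n
    L, ViX, XtViX, beta, Py, ll = _reml_pieces(spec, theta)
    comps = spec.kernels  # residual handled as K = I implicitly
    m = len(comps) + 1

    # K_k P y for every component (identity last)
    KPy = np.empty((n, m))
    for k, K in enumerate(comps):
        KPy[:, k] = K @ Py
    KPy[:, -1] = Py
    PKPy = _project(L, ViX, XtViX, KPy)

    # traces tr(P K_k) = tr(V^-1 K_k) - tr((X'V^-1X)^-1 X'V^-1 K_k V^-1 X)
    Vi = cho_solve(L, np.eye(n))
    XtViX_inv_ViXt = solve(XtViX, ViX.T, assume_a="pos")
    score = np.empty(m)
    quad = np.empty(m)
    for k in range(m):
        K = comps[k] if k < m - 1 else None
        if K is None:
            tr_ViK = float(np.trace(Vi))
            corr = float(np.sum(XtViX_inv_ViXt * ViX.T))
        else:
            tr_ViK = float(np.sum(Vi * K))
            corr = float(np.sum(XtViX_inv_ViXt * (K @ ViX).T))
        tr_PK = tr_ViK - corr
        quad[k] = float(Py @ KPy[:, k])
        score[k] = -0.5 * (tr_PK - quad[k])
    AI = 0.5 * (KPy.T @ PKPy)
    AI = (AI + AI.T) / 2.0
    return ll, score, AI, quad, beta


def fit_reml(
    spec: ModelSpec,
    max_iter: int = 500,
    tol: float = 1e-6,
    start: np.ndarray | None = None,
) -> VarianceComponentFit:
    """Fit variance components by AI-REML with EM fallback and variance floors.

    Convergence is declared when the restricted log-likelihood changes by less
    than ``tol`` between iterations. Non-convergence after ``max_iter``
    returns the last iterate with ``converged=False``.
    """
    if spec.n_kernels < 1:
        raise ModelError("at least one genetic kernel is required")
    n, r = spec.X.shape
    if n <= r:
        raise ModelError("need more observations than fixed effects")
    vary = float(np.var(spec.y, ddof=1))
    if vary <= 0:
        raise ModelError("response has zero variance")
    floor = 1e-8 * vary
    m = spec.n_kernels + 1

    if start is not None:
        theta = np.maximum(np.asarray(start, dtype=float).ravel(), floor)
        if theta.size != m:
            raise ModelError(f"start vector must have length {m}")
    else:
        theta = np.full(m, vary / m)
        theta[-1] = vary / 2.0
        theta[:-1] = (vary / 2.0) / spec.n_kernels
    # kernels with large diagonals (unstandardized dosages) need matching scale
    diag_scale = np.array([max(np.mean(np.diag(K)), 1e-12) for K in spec.kernels])
    if start is None:
        theta[:-1] = theta[:-1] / diag_scale

    ll, score, AI, quad, beta = _score_and_ai(spec, theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # Active set: components pinned at the floor whose gradient points
        # further down are held fixed, otherwise they poison the AI direction.
        free = ~((theta <= floor * 1.0001) & (score < 0.0))
        delta = None
        if free.any():
            try:
                delta = np.zeros(m)
                with warnings.catch_warnings():
                    # ill-conditioned AI steps are vetted by the line search
                    warnings.simplefilter("ignore")
                    delta[free] = solve(AI[np.ix_(free, free)], score[free],
                                        assume_a="sym")
            except np.linalg.LinAlgError:
                delta = None
        def _safe_ll(cand):
            try:
                return _reml_pieces(spec, cand)[5]
            except ModelError:
                return -np.inf

        def _em_step(base):
            # EM: theta_k <- theta_k + theta_k^2 (y'PK_kPy - tr(PK_k)) / n,
            # halved toward the current point until it does not decrease
            cand = np.maximum(base + (base**2) * (2.0 * score) / n, floor)
            ll_cand = _safe_ll(cand)
            for _ in range(30):
                if ll_cand >= ll - 1e-12:
                    return cand, ll_cand
                cand = np.maximum((cand + base) / 2.0, floor)
                ll_cand = _safe_ll(cand)
            return base, ll

        proposal = None
        if delta is not None:
            step = 1.0
            for _ in range(12):  # step-halving line search on the AI direction
                cand = np.maximum(theta + step * delta, floor)
                ll_cand = _safe_ll(cand)
                if ll_cand > ll + 1e-12:
                    proposal, ll_new = cand, ll_cand
                    break
                step /= 2.0
        if proposal is None:
            proposal, ll_new = _em_step(theta)
        dll = ll_new - ll
        theta = proposal
        ll, score, AI, quad, beta = _score_and_ai(spec, theta)
        if abs(dll) < tol:
            # confirm stationarity: a further EM step must not gain more than tol
            em_cand, em_ll = _em_step(theta)
            if em_ll - ll < tol:
                converged = True
                break
            theta = em_cand
            ll, score, AI, quad, beta = _score_and_ai(spec, theta)

    variances = theta[:-1].copy()
    resid = float(theta[-1])
    h2 = heritability_shares(variances, resid, diag_means=diag_scale)
    prop = heritability_proportion(
        h2, floor_h2=floor / float(variances.sum() + resid)
    )
    return VarianceComponentFit(
        variances=variances,
        residual_variance=resid,
        loglik=float(ll),
        h2=h2,
        proportion=prop,
        iterations=it,
        converged=converged,
        kernel_names=list(spec.kernel_names),
        beta=beta,
    )


def heritability_shares(variances, residual_variance: float,
                        diag_means=None) -> np.ndarray:
    """Per-kernel genomic heritability: each kernel's share of total variance.

    With unit-mean-diagonal kinships this is the plain variance-component
    ratio sigma2_k / (sum_j sigma2_j + sigma2_e); for other normalizations
    each component is weighted by its kernel's mean diagonal, which is the
    same ratio after reparametrizing to unit-diagonal kernels (the model fit
    is invariant to that rescaling).
    """
    v = np.asarray(variances, dtype=float)
    d = np.ones_like(v) if diag_means is None else np.asarray(diag_means, float)
    contrib = v * d
    total = float(contrib.sum() + residual_variance)
    if total <= 0:
        raise ModelError("total variance must be positive")
    return contrib / total


def heritability_proportion(h2, floor_h2: float = 1e-7) -> float | None:
    """Proportion of genomic heritability carried by the first kernel.

    For a two-kernel fit this is h2_m / (h2_m + h2_notm); single-kernel
    models return 1.0. When every genetic variance sits at the floor the
    proportion is undefined and None is returned.
    """
    h2 = np.asarray(h2, dtype=float)
    if h2.size == 1:
        return 1.0
    denom = float(h2.sum())
    if denom <= 2 * floor_h2 * h2.size:
        return None
    return float(h2[0] / denom)


def heritability_partition(fit: VarianceComponentFit) -> tuple[np.ndarray, float | None]:
    """Per-kernel genomic heritabilities and the first-kernel proportion."""
    return fit.h2.copy(), fit.proportion


def likelihood_ratio(fit_multi: VarianceComponentFit,
                     fit_gblup: VarianceComponentFit) -> tuple[float, bool]:
    """LR = 2 (ll_multi - ll_gblup); returns (LR, optimizer_failure_flag).

    The statistic may be marginally negative within convergence tolerance;
    values below -0.01 are flagged as an optimizer failure of the richer model.
    """
    lr = 2.0 * (fit_multi.loglik - fit_gblup.loglik)
    return float(lr), lr < -0.01


def predict_gebv(
    fit: VarianceComponentFit,
    spec_train: ModelSpec,
    kernels_cross: list[np.ndarray],
) -> np.ndarray:
    """Genomic estimated breeding values for held-out individuals.

    ``kernels_cross`` holds the test x train kinship blocks, one per kernel in
    the training spec, sliced from full-sample kinships. The GEBV is the
    genetic value only:

        g_test = sum_k sigma2_k K_k[test, train] V_train^-1 (y - X beta)

    with no fixed-effect contribution.
    """
    if len(kernels_cross) != spec_train.n_kernels:
        raise ModelError("one cross-kinship block per training kernel is required")
    n_train = spec_train.n
    for Kc in kernels_cross:
        if Kc.shape[1] != n_train:
            raise ModelError(
                f"cross block has {Kc.shape[1]} training columns, expected {n_train}"
            )
    theta = np.append(fit.variances, fit.residual_variance)
    L, ViX, XtViX, beta, Py, _ = _reml_pieces(spec_train, theta)
    g = np.zeros(kernels_cross[0].shape[0])
    for s2, Kc in zip(fit.variances, kernels_cross):
        g += s2 * (Kc @ Py)
    return g
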