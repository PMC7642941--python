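"""Independent reference implementations used only by the tests.

Everything here is written from the textbook definitions with dense algebra
and no shared code with the package, so agreement between the package and
these oracles is a genuine dual-route check.
"""

import numpy as np


def dense_reml_loglik(y, X, kernels, variances):
    """Restricted log-likelihood via explicit inverses and determinants."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, r = X.shape
    V = variances[-1] * np.eye(n)
    for s2, K in zip(variances[:-1], kernels):
        V = V + s2 * K
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    resid = y - X @ beta
    yPy = resid @ Vi @ y
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtViX)
    return -0.5 * ((n - r) * np.log(2 * np.pi) + ld_v + ld_x + yPy)


def grid_reml_maximum(y, X, K1, K2, res=0.01):
    """Dense grid search over heritability shares with the overall scale
    profiled out analytically; returns the maximum restricted log-likelihood."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, r = X.shape
    d1, d2 = np.mean(np.diag(K1)), np.mean(np.diag(K2))
    I = np.eye(n)
    best = -np.inf
    for h1 in np.arange(0.0, 1.0 + 1e-9, res):
        for h2 in np.arange(0.0, 1.0 - h1 + 1e-9, res):
            he = 1.0 - h1 - h2
            if he < 1e-6:
                continue
            V0 = (h1 / d1) * K1 + (h2 / d2) * K2 + he * I
            _, ld_v = np.linalg.slogdet(V0)
            Vi = np.linalg.inv(V0)
            XtViX = X.T @ Vi @ X
            _, ld_x = np.linalg.slogdet(XtViX)
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
            yPy = (y - X @ beta) @ Vi @ y
            c = yPy / (n - r)  # profiled overall variance scale
            ll = -0.5 * (
                (n - r) * np.log(2 * np.pi)
                + (n - r) * np.log(c)
                + ld_v
                + ld_x
                + (n - r)
            )
            best = max(best, ll)
    return best


def henderson_gebv(y_train, X_train, train, test, kernels, variances,
                   residual_variance):
    """Held-out genetic values via Henderson's mixed-model equations.

    Builds the joint train+test equations with one random effect per kernel
    (covariance sigma2_k K_k over all individuals) and solves the full system;
    returns the summed random-effect solutions for the test individuals.
    Kernels must be nonsingular.
    """
    n_all = kernels[0].shape[0]
    nt = len(train)
    Z = np.zeros((nt, n_all))
    Z[np.arange(nt), train] = 1.0
    k = len(kernels)
    se = residual_variance
    blocks = [[X_train.T @ X_train / se] + [X_train.T @ Z / se] * k]
    for i in range(k):
        Gi = np.linalg.inv(variances[i] * kernels[i])
        row = [Z.T @ X_train / se]
        for j in range(k):
            B = Z.T @ Z / se
            if i == j:
                B = B + Gi
            row.append(B)
        blocks.append(row)
    A = np.block(blocks)
    rhs = np.concatenate([X_train.T @ y_train / se] + [Z.T @ y_train / se] * k)
    sol = np.linalg.solve(A, rhs)
    r = X_train.shape[1]
    g = np.zeros(n_all)
    for i in range(k):
        g += sol[r + i * n_all : r + (i + 1) * n_all]
    return g[test]


def brute_force_pathway_snps(G, gene_table, pathway_map, buffer_bp):
    """O(genes x SNPs) interval scan returning pathway -> sorted SNP-id list."""
    out = {}
    for pw in sorted(pathway_map["pathway_id"].unique()):
        genes = pathway_map.loc[pathway_map["pathway_id"] == pw, "gene_id"]
        snps = set()
        for g in genes:
            row = gene_table.loc[gene_table["gene_id"] == g].iloc[0]
            for j in range(G.p):
                if (
                    G.chrom[j] == row["chrom"]
                    and row["start"] - buffer_bp <= G.pos[j] <= row["stop"] + buffer_bp
                ):
                    snps.add(G.snp_ids[j])
        out[pw] = sorted(snps)
    return out


def loop_standardized_kinship(X):
    """Correlation-style kinship via an explicit per-SNP loop (alpha = -1)."""
    n, p = X.shape
    K = np.zeros((n, n))
    for j in range(p):
        f = X[:, j].mean() / 2.0
        z = (X[:, j] - 2 * f) / np.sqrt(2 * f * (1 - f))
        K += np.outer(z, z)
    return K / p


def rank_then_pearson(a, b):
    """Spearman rho as Pearson correlation of midranks."""

    def midrank(x):
        order = np.argsort(x, kind="mergesort")
        ranks = np.empty(len(x), float)
        sx = x[order]
        i = 0
        while i < len(x):
            j = i
            while j + 1 < len(x) and sx[j + 1] == sx[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    ra, rb = midrank(np.asarray(a)), midrank(np.asarray(b))
    return float(np.corrcoef(ra, rb)[0, 1])


def sign_flip_pvalue(d, n_perm=20000, seed=0):
    """One-sided paired permutation test of mean(d) > 0 by sign flipping."""
    rng = np.random.default_rng(seed)
    d = np.asarray(d, float)
    obs = d.mean()
    signs = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
    perm = (signs * d).mean(axis=1)
    return (1 + np.sum(perm >= obs)) / (1 + n_perm)


def loo_deletion_residuals(y, X, V):
    """Studentized deleted residuals by explicit leave-one-out refits.

    For each observation: re-estimate the fixed effects by GLS without it,
    predict it from the conditional (kriging) distribution given the rest,
    and studentize the prediction error. Variance components (inside V) are
    held fixed, matching the package's convention.
    """
    n = len(y)
    t = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        Vi = V[np.ix_(keep, keep)]
        v = V[keep, i]
        Xi, yi = X[keep], y[keep]
        Vi_inv_X = np.linalg.solve(Vi, Xi)
        Vi_inv_y = np.linalg.solve(Vi, yi)
        Vi_inv_v = np.linalg.solve(Vi, v)
        XtViX = Xi.T @ Vi_inv_X
        beta = np.linalg.lstsq(XtViX, Xi.T @ Vi_inv_y, rcond=None)[0]
        pred = X[i] @ beta + v @ np.linalg.solve(Vi, yi - Xi @ beta)
        d = X[i] - Xi.T @ Vi_inv_v
        var = (V[i, i] - v @ Vi_inv_v) + d @ np.linalg.lstsq(XtViX, d, rcond=None)[0]
        t[i] = (y[i] - pred) / np.sqrt(var)
    return t


def gls_blues(y, acc, V):
    """Explicit V^-1-weighted least squares accession estimates."""
    levels = sorted(set(acc))
    X = np.zeros((len(y), len(levels)))
    for i, a in enumerate(acc):
        X[i, levels.index(a)] = 1.0
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    return dict(zip(levels, beta))
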