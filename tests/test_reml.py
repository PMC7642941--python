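import numpy as np
import pytest

from oracles import dense_reml_loglik, henderson_gebv
from pathpartblup import (
    ModelSpec,
    compute_kinship,
    fit_reml,
    heritability_partition,
    likelihood_ratio,
    predict_gebv,
    reml_loglik,
)
from pathpartblup.reml import ModelError, VarianceComponentFit, heritability_shares


def random_problem(rng, n=20, p=60, n_kernels=2, h2=(0.3, 0.3), resid=0.4):
    f = rng.uniform(0.1, 0.5, p)
    Xd = rng.binomial(2, f, (n, p)).astype(float)
    Z = Xd - Xd.mean(axis=0)
    cuts = np.linspace(0, p, n_kernels + 1).astype(int)
    kernels, g = [], np.zeros(n)
    for k in range(n_kernels):
        Zk = Z[:, cuts[k] : cuts[k + 1]]
        kernels.append(Zk @ Zk.T / Zk.shape[1])
        if h2[k] > 0:
            gk = Zk @ rng.standard_normal(Zk.shape[1])
            g += gk * np.sqrt(h2[k] / np.var(gk))
    y = 1.5 + g + rng.normal(0, np.sqrt(resid), n)
    X = np.ones((n, 1))
    return y, X, kernels


class TestRemlLoglik:
    def test_matches_dense_textbook_formula(self, rng):
        y, X, kernels = random_problem(rng)
        for _ in range(5):
            v = rng.uniform(0.05, 2.0, 3)
            ours = reml_loglik(ModelSpec(y, X, kernels), v)
            assert ours == pytest.approx(
                dense_reml_loglik(y, X, kernels, v), abs=1e-8
            )

    def test_translation_invariant_with_intercept(self, rng):
        y, X, kernels = random_problem(rng)
        v = [0.4, 0.2, 0.5]
        l0 = reml_loglik(ModelSpec(y, X, kernels), v)
        l1 = reml_loglik(ModelSpec(y + 7.3, X, kernels), v)
        assert l1 == pytest.approx(l0, abs=1e-8)

    def test_identity_kernel_flat_ridge(self, rng):
        # with K = I only the total sigma2_G + sigma2_e is identified
        n = 15
        y = rng.standard_normal(n)
        spec = ModelSpec(y, np.ones((n, 1)), [np.eye(n)])
        l1 = reml_loglik(spec, [0.3, 0.7])
        l2 = reml_loglik(spec, [0.9, 0.1])
        l3 = reml_loglik(spec, [0.5, 0.5])
        assert l1 == pytest.approx(l2, abs=1e-9)
        assert l1 == pytest.approx(l3, abs=1e-9)

    def test_invalid_variances_rejected(self, rng):
        y, X, kernels = random_problem(rng)
        spec = ModelSpec(y, X, kernels)
        with pytest.raises(ModelError):
            reml_loglik(spec, [-0.1, 0.5, 0.5])
        with pytest.raises(ModelError):
            reml_loglik(spec, [0.1, 0.5])


class TestFitReml:
    def test_zero_component_estimated_at_floor(self, rng):
        y, X, kernels = random_problem(rng, n=100, p=200, h2=(0.0, 0.5))
        fit = fit_reml(ModelSpec(y, X, kernels))
        assert fit.converged
        assert fit.h2[0] < 0.05

    def test_nesting_single_kernel_at_least_constrained_two_kernel(self, rng):
        y, X, kernels = random_problem(rng, n=50, p=100)
        Z_all_K = (50 * kernels[0] + 50 * kernels[1]) / 100  # p_m = p_notm = 50
        single = fit_reml(ModelSpec(y, X, [Z_all_K]))
        # two-kernel model constrained to per-SNP-proportional variances == GBLUP
        ll_constrained = reml_loglik(
            ModelSpec(y, X, kernels),
            [single.variances[0] * 0.5, single.variances[0] * 0.5,
             single.residual_variance],
        )
        assert single.loglik >= ll_constrained - 1e-6
        assert single.loglik == pytest.approx(ll_constrained, abs=1e-6)

    def test_scale_equivariance(self, rng):
        y, X, kernels = random_problem(rng, n=60, p=120)
        f1 = fit_reml(ModelSpec(y, X, kernels))
        c = 3.7
        f2 = fit_reml(ModelSpec(c * y, X, kernels))
        assert np.allclose(f2.variances, c**2 * f1.variances, rtol=1e-3)
        assert f2.residual_variance == pytest.approx(
            c**2 * f1.residual_variance, rel=1e-3
        )
        assert np.allclose(f2.h2, f1.h2, atol=1e-4)
        assert f2.proportion == pytest.approx(f1.proportion, abs=1e-4)

    def test_zero_variance_response_rejected(self):
        n = 10
        spec = ModelSpec(np.ones(n), np.ones((n, 1)), [np.eye(n)])
        with pytest.raises(ModelError, match="zero variance"):
            fit_reml(spec)

    def test_iteration_cap_reported(self, rng):
        y, X, kernels = random_problem(rng, n=40, p=80)
        fit = fit_reml(ModelSpec(y, X, kernels), max_iter=1)
        assert fit.iterations == 1
        assert not fit.converged


class TestHeritabilityPartition:
    def test_hand_examples(self):
        assert np.allclose(heritability_shares([1.0, 0.0], 1.0), [0.5, 0.0])
        h2 = heritability_shares([0.3, 0.3], 0.4)
        fit = VarianceComponentFit(
            variances=np.array([0.3, 0.3]), residual_variance=0.4, loglik=0.0,
            h2=h2, proportion=float(h2[0] / h2.sum()), iterations=1,
            converged=True, kernel_names=["m", "rest"], beta=np.zeros(1),
        )
        shares, prop = heritability_partition(fit)
        assert prop == pytest.approx(0.5)
        assert shares.sum() == pytest.approx(0.6)

    def test_random_triples_match_direct_arithmetic(self, rng):
        for _ in range(20):
            a, b, e = rng.uniform(0.01, 2.0, 3)
            h2 = heritability_shares([a, b], e)
            assert np.allclose(h2, [a / (a + b + e), b / (a + b + e)])

    def test_single_kernel_proportion_is_one(self, rng):
        y, X, kernels = random_problem(rng, n=60, p=60, n_kernels=1, h2=(0.5,))
        fit = fit_reml(ModelSpec(y, X, kernels))
        assert fit.proportion == 1.0


class TestLikelihoodRatio:
    def test_identical_fits_give_zero(self, rng):
        y, X, kernels = random_problem(rng)
        fit = fit_reml(ModelSpec(y, X, kernels))
        lr, failed = likelihood_ratio(fit, fit)
        assert lr == 0.0
        assert not failed

    def test_negative_beyond_tolerance_flagged(self, rng):
        y, X, kernels = random_problem(rng)
        f1 = fit_reml(ModelSpec(y, X, kernels))
        f2 = VarianceComponentFit(
            variances=f1.variances, residual_variance=f1.residual_variance,
            loglik=f1.loglik - 1.0, h2=f1.h2, proportion=f1.proportion,
            iterations=1, converged=True, kernel_names=f1.kernel_names,
            beta=f1.beta,
        )
        lr, failed = likelihood_ratio(f2, f1)
        assert lr == pytest.approx(-2.0)
        assert failed


class TestPredictGebv:
    def test_floored_variances_give_null_prediction(self, rng):
        y, X, kernels = random_problem(rng, n=40, p=80, h2=(0.0, 0.0), resid=1.0)
        train = np.arange(30)
        test = np.arange(30, 40)
        spec = ModelSpec(y[train], X[train],
                         [K[np.ix_(train, train)] for K in kernels])
        fit = fit_reml(spec)
        g = predict_gebv(fit, spec, [K[np.ix_(test, train)] for K in kernels])
        assert np.max(np.abs(g)) < 0.05 * np.std(y)

    def test_duplicated_genotype_approaches_training_genetic_value(self, rng):
        # a test individual identical to a training one shares its GEBV in the
        # high-heritability limit
        n, p = 60, 300
        f = rng.uniform(0.2, 0.5, p)
        Xd = rng.binomial(2, f, (n, p)).astype(float)
        Xd[0] = Xd[1]  # sample 0 (test) duplicates sample 1 (train)
        Z = Xd - Xd.mean(axis=0)
        K = Z @ Z.T / p + 1e-8 * np.eye(n)
        g = Z @ rng.standard_normal(p)
        g *= np.sqrt(0.95 / np.var(g))
        y = g + rng.normal(0, np.sqrt(0.05), n)
        train = np.arange(1, n)
        spec = ModelSpec(y[train], np.ones((n - 1, 1)), [K[np.ix_(train, train)]])
        fit = fit_reml(spec)
        g_test = predict_gebv(fit, spec, [K[np.ix_([0], train)]])
        u_train = fit.variances[0] * K[np.ix_(train, train)] @ np.linalg.solve(
            fit.variances[0] * K[np.ix_(train, train)]
            + fit.residual_variance * np.eye(n - 1),
            y[train] - np.mean(y[train]),
        )
        assert g_test[0] == pytest.approx(u_train[0], abs=0.05 * np.std(y))

    def test_matches_henderson_mixed_model_equations(self, rng):
        """Fold GEBVs equal the joint train+test BLUP from Henderson's MME."""
        n, p = 50, 200
        f = rng.uniform(0.1, 0.5, p)
        Xd = rng.binomial(2, f, (n, p)).astype(float)
        Z = Xd - Xd.mean(axis=0)
        pm = 40
        jitter = 1e-8 * np.eye(n)  # keeps G invertible for the MME oracle
        K1 = Z[:, :pm] @ Z[:, :pm].T / pm + jitter
        K2 = Z[:, pm:] @ Z[:, pm:].T / (p - pm) + jitter
        g = Z @ rng.standard_normal(p)
        g *= np.sqrt(0.6 / np.var(g))
        y = 2.0 + g + rng.normal(0, np.sqrt(0.4), n)
        test = np.arange(7)
        train = np.arange(7, n)
        X = np.ones((n, 1))
        spec = ModelSpec(y[train], X[train],
                         [K[np.ix_(train, train)] for K in (K1, K2)])
        fit = fit_reml(spec)
        ours = predict_gebv(
            fit, spec, [K[np.ix_(test, train)] for K in (K1, K2)]
        )
        oracle = henderson_gebv(
            y[train], X[train], train, test, [K1, K2], fit.variances,
            fit.residual_variance,
        )
        assert np.max(np.abs(ours - oracle)) < 1e-6

    def test_mismatched_cross_blocks_rejected(self, rng):
        y, X, kernels = random_problem(rng)
        spec = ModelSpec(y, X, kernels)
        fit = fit_reml(spec)
        with pytest.raises(ModelError):
            predict_gebv(fit, spec, [np.zeros((3, 5))] * 2)


class TestGblupMultiblupEquivalence:
    def test_constrained_two_kernel_equals_gblup(self, small_panel):
        """With alpha=0 and divide-by-p scaling, GBLUP on all SNPs equals the
        two-kernel model with per-SNP-proportional variances (kinship
        additivity carried through the likelihood)."""
        G, y = small_panel["G"], small_panel["y"]
        part = list(small_panel["parts"].values())[0]
        K_all = compute_kinship(G)
        K_m = compute_kinship(G, part.member_snps)
        K_r = compute_kinship(G, part.complement_snps)
        X = np.ones((G.n, 1))
        fit = fit_reml(ModelSpec(y, X, [K_all.values]))
        s = fit.variances[0]
        p, pm, pr = K_all.n_snps, K_m.n_snps, K_r.n_snps
        ll = reml_loglik(
            ModelSpec(y, X, [K_m.values, K_r.values]),
            [s * pm / p, s * pr / p, fit.residual_variance],
        )
        assert ll == pytest.approx(fit.loglik, abs=1e-6)
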