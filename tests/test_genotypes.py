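import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import (
    brute_force_pathway_snps,
    loop_standardized_kinship,
    rank_then_pearson,
)
from pathpartblup import (
    GenotypeMatrix,
    KinshipMatrix,
    assign_pathway_snps,
    compute_kinship,
    compute_pcs,
    filter_maf,
    kinship_overlap,
)
from pathpartblup.genotypes import GenotypeError
from pathpartblup import io as ppio


def make_genotypes(dosages, chrom=None, pos=None):
    dosages = np.asarray(dosages, float)
    n, p = dosages.shape
    return GenotypeMatrix(
        dosages,
        [f"s{i}" for i in range(n)],
        [f"m{j}" for j in range(p)],
        chrom if chrom is not None else np.ones(p, int),
        pos if pos is not None else (np.arange(p) + 1) * 100,
    )


class TestIO:
    def test_plink_round_trip(self, small_panel, tmp_path):
        G = small_panel["G"]
        ppio.write_plink(G, tmp_path / "panel")
        G2 = ppio.read_plink(tmp_path / "panel")
        assert np.array_equal(G.dosages, G2.dosages)
        assert G.sample_ids == G2.sample_ids
        assert G.snp_ids == G2.snp_ids
        assert np.array_equal(G.pos, G2.pos)
        assert np.array_equal(G.chrom, G2.chrom)

    def test_tsv_round_trip_preserves_missing(self, tmp_path):
        d = np.array([[0.0, 2.0], [1.0, np.nan], [2.0, 1.0]])
        G = make_genotypes(d)
        ppio.write_dosage_tsv(G, tmp_path / "g.tsv")
        G2 = ppio.read_dosage_tsv(tmp_path / "g.tsv")
        assert np.array_equal(G.dosages, G2.dosages, equal_nan=True)

    def test_plink_missing_code_round_trip(self, tmp_path):
        d = np.array([[0.0, 2.0], [1.0, np.nan], [2.0, 1.0], [0.0, 0.0]])
        G = make_genotypes(d)
        ppio.write_plink(G, tmp_path / "m")
        G2 = ppio.read_plink(tmp_path / "m")
        assert np.array_equal(G.dosages, G2.dosages, equal_nan=True)

    def test_fam_bim_order_preserved(self, tmp_path):
        d = np.array([[0.0, 1.0], [1.0, 2.0], [2.0, 0.0]])
        G = make_genotypes(d)
        ppio.write_plink(G, tmp_path / "o")
        G2 = ppio.read_plink(tmp_path / "o")
        assert G2.sample_ids == ["s0", "s1", "s2"]
        assert G2.snp_ids == ["m0", "m1"]

    def test_bad_magic_rejected(self, tmp_path):
        (tmp_path / "x.bed").write_bytes(b"\x00\x00\x00")
        (tmp_path / "x.bim").write_text("1\tm0\t0\t100\tA\tB\n")
        (tmp_path / "x.fam").write_text("s0\ts0\t0\t0\t0\t-9\n")
        with pytest.raises(GenotypeError, match="magic"):
            ppio.read_plink(tmp_path / "x")

    def test_all_missing_snp_dropped_with_warning(self, tmp_path):
        d = np.array([[0.0, np.nan], [1.0, np.nan]])
        ppio.write_dosage_tsv(make_genotypes(d), tmp_path / "g.tsv")
        with pytest.warns(UserWarning, match="no called genotypes"):
            G2 = ppio.read_dosage_tsv(tmp_path / "g.tsv")
        assert G2.p == 1


class TestImputation:
    def test_missing_imputed_to_twice_frequency(self):
        # three called dosages 0,1,0 at one SNP -> f=1/6, impute 2f=1/3
        d = np.array([[0.0], [1.0], [0.0], [np.nan]])
        G = make_genotypes(d)
        X, n_imp = G.imputed()
        assert n_imp == 1
        assert X[3, 0] == pytest.approx(1.0 / 3.0)

    def test_quarter_frequency_example(self):
        d = np.array([[1.0], [0.0], [1.0], [0.0], [np.nan]])
        G = make_genotypes(d)  # f = 2/8 = 0.25
        X, _ = G.imputed()
        assert X[4, 0] == pytest.approx(0.5)


class TestMafFilter:
    def test_strict_inequality_at_threshold(self, rng):
        # MAFs 0.04, 0.05, 0.051, 0.30 -> keep the last two only
        mafs = [0.04, 0.05, 0.051, 0.30]
        n = 1000
        cols = [np.r_[np.full(int(round(2 * n * f)) , 1.0),
                      np.zeros(2 * n - int(round(2 * n * f)))][:n]
                for f in mafs]
        d = np.column_stack(cols)
        G = make_genotypes(d)
        kept = filter_maf(G, 0.05)
        assert kept.snp_ids == ["m2", "m3"]

    def test_zero_threshold_drops_monomorphic(self):
        d = np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 1.0]])
        G = make_genotypes(d)
        kept = filter_maf(G, 0.0)
        assert kept.snp_ids == ["m1"]

    def test_matches_direct_enumeration(self, rng):
        d = rng.binomial(2, rng.uniform(0.01, 0.5, 50), (40, 50)).astype(float)
        G = make_genotypes(d)
        kept = filter_maf(G, 0.1)
        f = d.mean(axis=0) / 2
        expected = [f"m{j}" for j in range(50) if min(f[j], 1 - f[j]) > 0.1]
        assert kept.snp_ids == expected

    def test_empty_result_rejected(self):
        d = np.zeros((3, 2))
        with pytest.raises(GenotypeError, match="MAF"):
            filter_maf(make_genotypes(d), 0.05)


class TestPCA:
    def test_rank_one_matrix_second_component_zero(self):
        u = np.array([0.0, 1.0, 2.0, 1.0])
        d = np.outer(u, np.ones(5)) * np.linspace(0.5, 1, 5)
        scores, varexp = compute_pcs(make_genotypes(d), 2)
        assert varexp[1] == pytest.approx(0.0, abs=1e-12)

    def test_scores_orthogonal_and_varexp_matches_eigendecomposition(self, rng):
        d = rng.binomial(2, 0.3, (30, 80)).astype(float)
        G = make_genotypes(d)
        scores, varexp = compute_pcs(G, 4)
        gram = scores.T @ scores
        assert np.allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)
        # oracle: dense eigendecomposition of the centered covariance
        Z = d - d.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(Z.T @ Z))[::-1]
        assert np.allclose(varexp, evals[:4] / evals.sum(), atol=1e-10)

    def test_sign_convention_deterministic(self, rng):
        d = rng.binomial(2, 0.4, (25, 60)).astype(float)
        s1, _ = compute_pcs(make_genotypes(d), 3)
        s2, _ = compute_pcs(make_genotypes(d.copy()), 3)
        assert np.array_equal(s1, s2)

    def test_constant_matrix_rejected(self):
        with pytest.raises(GenotypeError):
            compute_pcs(make_genotypes(np.ones((5, 4))), 2)


class TestPathwayAssignment:
    def _gene_table(self):
        return pd.DataFrame(
            {"gene_id": ["g1"], "chrom": [1], "start": [10000], "stop": [12000]}
        )

    def _pmap(self):
        return pd.DataFrame({"pathway_id": ["pw"], "gene_id": ["g1"]})

    @pytest.mark.parametrize("pos,included", [(7500, True), (7499, False),
                                              (14500, True), (14501, False)])
    def test_buffer_boundary_inclusive(self, pos, included):
        d = np.array([[0.0], [1.0], [2.0]])
        G = make_genotypes(d, pos=np.array([pos]))
        parts = assign_pathway_snps(G, self._gene_table(), self._pmap(), 2500)
        if included:
            assert parts["pw"].member_snps == ["m0"]
        else:
            assert not parts  # zero-SNP pathway flagged and excluded

    def test_shared_snp_counted_once(self):
        genes = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "chrom": [1, 1],
             "start": [100, 150], "stop": [200, 260]}
        )
        pmap = pd.DataFrame({"pathway_id": ["pw", "pw"], "gene_id": ["g1", "g2"]})
        d = np.tile([[0.0], [1.0], [2.0]], (1, 1))
        G = make_genotypes(d, pos=np.array([180]))
        parts = assign_pathway_snps(G, genes, pmap, 0)
        assert parts["pw"].member_snps == ["m0"]
        assert parts["pw"].n_member_snps == 1

    def test_matches_brute_force_interval_scan(self, rng):
        n_genes, p = 30, 300
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n_genes)],
                "chrom": rng.integers(1, 4, n_genes),
                "start": rng.integers(1, 50000, n_genes),
            }
        )
        genes["stop"] = genes["start"] + rng.integers(500, 3000, n_genes)
        pmap = pd.DataFrame(
            {
                "pathway_id": rng.choice(["a", "b", "c"], 15),
                "gene_id": rng.choice(genes["gene_id"], 15, replace=False),
            }
        )
        d = rng.binomial(2, 0.4, (5, p)).astype(float)
        G = make_genotypes(
            d, chrom=rng.integers(1, 4, p), pos=rng.integers(1, 55000, p)
        )
        parts = assign_pathway_snps(G, genes, pmap, 2500)
        expected = brute_force_pathway_snps(G, genes, pmap, 2500)
        for pw, part in parts.items():
            assert sorted(part.member_snps) == expected[pw]
            assert sorted(part.member_snps + part.complement_snps) == sorted(G.snp_ids)


class TestKinship:
    def test_hand_worked_two_snp_example(self):
        d = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        K = compute_kinship(make_genotypes(d), alpha=0.0)
        expected = np.array([[1.0, 0.0, -1.0], [0.0, 0.0, 0.0], [-1.0, 0.0, 1.0]])
        assert np.allclose(K.values, expected)
        assert K.n_snps == 2

    def test_identical_rows_give_identical_kinship_rows(self, rng):
        d = rng.binomial(2, 0.4, (6, 40)).astype(float)
        d[3] = d[0]
        K = compute_kinship(make_genotypes(d)).values
        assert np.allclose(K[0], K[3])

    def test_alpha_minus_one_matches_loop_oracle(self, rng):
        d = rng.binomial(2, rng.uniform(0.2, 0.5, 30), (12, 30)).astype(float)
        K = compute_kinship(make_genotypes(d), alpha=-1.0)
        assert np.allclose(K.values, loop_standardized_kinship(d), atol=1e-10)

    def test_monomorphic_snp_rejected_under_alpha_scaling(self):
        d = np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 1.0]])
        with pytest.raises(GenotypeError, match="monomorphic"):
            compute_kinship(make_genotypes(d), alpha=-1.0)

    def test_subset_order_invariance(self, small_panel):
        G = small_panel["G"]
        ids = list(small_panel["parts"].values())[0].member_snps
        K1 = compute_kinship(G, ids)
        K2 = compute_kinship(G, ids[::-1])
        assert np.allclose(K1.values, K2.values, atol=1e-12)

    def test_mean_diag_normalization(self, small_panel):
        K = compute_kinship(small_panel["G"], normalization="mean_diag")
        assert np.mean(np.diag(K.values)) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=15)
    @given(st.integers(min_value=1, max_value=39), st.integers(0, 2**31 - 1))
    def test_crossproduct_additivity_over_random_partitions(self, pm, seed):
        """p K_all = p_m K_m + p_notm K_notm for any disjoint SNP partition."""
        rng = np.random.default_rng(seed)
        d = rng.binomial(2, rng.uniform(0.05, 0.5, 40), (15, 40)).astype(float)
        G = make_genotypes(d)
        member = [f"m{j}" for j in rng.choice(40, pm, replace=False)]
        rest = [s for s in G.snp_ids if s not in set(member)]
        K_all = compute_kinship(G)
        K_m = compute_kinship(G, member)
        K_r = compute_kinship(G, rest)
        lhs = 40 * K_all.values
        rhs = pm * K_m.values + (40 - pm) * K_r.values
        assert np.max(np.abs(lhs - rhs)) < 1e-10 * max(1.0, np.abs(lhs).max())


class TestKinshipOverlap:
    def test_monotone_transform_gives_rho_one(self, small_panel):
        K1 = compute_kinship(small_panel["G"])
        K2 = KinshipMatrix(2.0 * K1.values, K1.sample_ids, K1.n_snps)
        assert kinship_overlap(K1, K2) == pytest.approx(1.0)
        K3 = KinshipMatrix(-K1.values, K1.sample_ids, K1.n_snps)
        assert kinship_overlap(K1, K3) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        n = 12
        A = rng.standard_normal((n, n)); A = (A + A.T) / 2
        B = rng.standard_normal((n, n)); B = (B + B.T) / 2
        ids = [f"s{i}" for i in range(n)]
        rho = kinship_overlap(KinshipMatrix(A, ids, 5), KinshipMatrix(B, ids, 5))
        iu = np.triu_indices(n, 1)
        assert rho == pytest.approx(rank_then_pearson(A[iu], B[iu]), abs=1e-10)

    def test_too_few_individuals_rejected(self):
        ids = ["a", "b"]
        K = KinshipMatrix(np.eye(2), ids, 3)
        with pytest.raises(GenotypeError, match="at least 3"):
            kinship_overlap(K, K)
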