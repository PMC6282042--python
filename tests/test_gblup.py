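import numpy as np
import pytest

from lvscan.gblup import (
    backsolve_snp_effects,
    estimate_genetic_correlation,
    estimate_variance_components,
    solve_mme,
)
from lvscan.kinship import RelationshipMatrix, genomic_G, pedigree_A

from conftest import (
    gls_blup_oracle,
    random_genotypes,
    random_small_pedigree,
    ridge_oracle,
)


def identity_H(n):
    return RelationshipMatrix(np.eye(n), np.arange(1, n + 1), "Hinv")


class TestSolveMme:
    def test_infinite_shrinkage_limit(self):
        rng = np.random.default_rng(0)
        n = 30
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([1.0, 2.0]) + rng.standard_normal(n)
        sol = solve_mme(y, X, identity_H(n), lam=1e8)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(sol.fixed_solutions.to_numpy(), ols, atol=1e-5)
        assert np.abs(sol.gebv.to_numpy()).max() < 1e-5

    def test_ridge_closed_form(self):
        rng = np.random.default_rng(1)
        n, lam = 25, 2.5
        X = np.ones((n, 1))
        y = rng.standard_normal(n)
        sol = solve_mme(y, X, identity_H(n), lam=lam)
        b, a = ridge_oracle(y, X, lam)
        np.testing.assert_allclose(sol.fixed_solutions.to_numpy(), b, atol=1e-8)
        np.testing.assert_allclose(sol.gebv.to_numpy(), a, atol=1e-8)

    def test_gblup_equals_snp_blup(self):
        # 50 animals x 200 SNPs, H = unblended VanRaden G
        rng = np.random.default_rng(2)
        n, m = 50, 200
        geno = random_genotypes(n, m, seed=2)
        # generating (not sample) frequencies keep Zc full rank so the
        # unblended G is invertible and the equivalence is exact
        freqs = geno.founder_freqs
        G = genomic_G(geno, freqs)
        Zc = geno.dosages - 2 * freqs
        c = 2 * np.sum(freqs * (1 - freqs))
        sigma_a, sigma_e = 1.0, 1.5
        lam = sigma_e / sigma_a
        X = np.ones((n, 1))
        y = rng.standard_normal(n)
        sol = solve_mme(y, X, G.inverse(), lam=lam, record_ids=geno.ids)
        # SNP-BLUP with per-marker variance sigma_a / c
        lam_u = lam * c
        k = X.shape[1]
        C = np.block([[X.T @ X, X.T @ Zc], [Zc.T @ X, Zc.T @ Zc + lam_u * np.eye(m)]])
        rhs = np.concatenate([X.T @ y, Zc.T @ y])
        u = np.linalg.solve(C, rhs)[k:]
        np.testing.assert_allclose(sol.gebv.to_numpy(), Zc @ u, atol=1e-8)

    def test_pedigree_blup_matches_gls_oracle(self):
        ped = random_small_pedigree(3, n_founders=6, n_nonf=8)
        A = pedigree_A(ped)
        n_all = len(A.ids)
        rng = np.random.default_rng(3)
        rec_ids = A.ids[-10:]
        W = np.zeros((10, n_all))
        for r, aid in enumerate(rec_ids):
            W[r, list(A.ids).index(aid)] = 1.0
        X = np.column_stack([np.ones(10), rng.standard_normal(10)])
        y = rng.standard_normal(10)
        sa, se = 1.0, 2.0
        sol = solve_mme(y, X, A.inverse(), lam=se / sa, record_ids=rec_ids)
        b, a = gls_blup_oracle(y, X, A.values, W, sa, se)
        np.testing.assert_allclose(sol.fixed_solutions.to_numpy(), b, atol=1e-8)
        np.testing.assert_allclose(sol.gebv.to_numpy(), a, atol=1e-8)

    def test_gebv_ranking_invariant_to_shift(self):
        rng = np.random.default_rng(4)
        n = 40
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        H = identity_H(n)
        g1 = solve_mme(y, X, H, 1.0).gebv.to_numpy()
        g2 = solve_mme(y + 7.0, X, H, 1.0).gebv.to_numpy()
        np.testing.assert_allclose(g1, g2, atol=1e-8)

    def test_rank_deficient_fixed_block(self):
        n = 20
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError, match="rank deficient"):
            solve_mme(np.zeros(n), X, identity_H(n), 1.0,
                      fixed_names=["mu", "dup"])


@pytest.fixture(scope="module")
def herd():
    from lvscan import synthetic as syn
    from lvscan import kinship as kin
    cfg = syn.SimConfig(n_founders=200, n_generations=2, n_sires=40,
                        n_animals_target=800, n_snps=400, seed=10)
    sim = syn.simulate_dataset(cfg)
    A = kin.pedigree_A(sim.pedigree)
    gq, _ = kin.snp_qc(sim.genotypes)
    G = kin.genomic_G(gq)
    A22 = A.submatrix(gq.ids)
    Gb = kin.blend_G(G, A22)
    Hinv = kin.build_H_inverse(A.inverse(), A22.inverse(), Gb.inverse(), gq.ids)
    return sim, Hinv


class TestVarianceComponents:
    def test_null_heritability(self, herd):
        sim, Hinv = herd
        n = sim.genotypes.n_animals
        X = np.ones((n, 1))
        rng = np.random.default_rng(11)
        low = 0
        for _ in range(10):
            y = rng.standard_normal(n)
            vc = estimate_variance_components(y, X, Hinv, sim.genotypes.ids)
            low += vc.h2 < 0.1
        assert low >= 9

    def test_recovery_single_replicate(self, herd):
        sim, Hinv = herd
        n = sim.genotypes.n_animals
        vc = estimate_variance_components(
            sim.latent_A, np.ones((n, 1)), Hinv, sim.genotypes.ids
        )
        assert vc.converged
        assert vc.h2 == pytest.approx(0.46, abs=0.15)
        assert 0 < vc.h2_se < 0.2

    def test_scale_equivariance(self, herd):
        sim, Hinv = herd
        n = sim.genotypes.n_animals
        X = np.ones((n, 1))
        v1 = estimate_variance_components(sim.latent_A, X, Hinv, sim.genotypes.ids)
        v2 = estimate_variance_components(2 * sim.latent_A, X, Hinv,
                                          sim.genotypes.ids)
        assert v2.sigma2_a == pytest.approx(4 * v1.sigma2_a, rel=1e-3)
        assert v2.sigma2_e == pytest.approx(4 * v1.sigma2_e, rel=1e-3)
        assert v2.h2 == pytest.approx(v1.h2, abs=1e-6)

    def test_too_few_records(self):
        with pytest.raises(ValueError, match="too few"):
            estimate_variance_components(np.zeros(3), np.ones((3, 2)),
                                         identity_H(3))


class TestGeneticCorrelation:
    def test_identical_traits(self):
        from lvscan import synthetic as syn
        from lvscan import kinship as kin
        cfg = syn.SimConfig(n_founders=150, n_generations=1, n_sires=30,
                            n_animals_target=400, n_snps=300, seed=12)
        sim = syn.simulate_dataset(cfg)
        A = kin.pedigree_A(sim.pedigree)
        gq, _ = kin.snp_qc(sim.genotypes)
        Gb = kin.blend_G(kin.genomic_G(gq), A.submatrix(gq.ids))
        Hinv = kin.build_H_inverse(A.inverse(), A.submatrix(gq.ids).inverse(),
                                   Gb.inverse(), gq.ids)
        n = sim.genotypes.n_animals
        res = estimate_genetic_correlation(
            sim.latent_A, sim.latent_A.copy(), np.ones((n, 1)), Hinv,
            sim.genotypes.ids,
        )
        assert res["r_g"] == pytest.approx(1.0, abs=1e-3)

    def test_independent_traits_near_zero(self):
        from lvscan import synthetic as syn
        from lvscan import kinship as kin
        rgs = []
        for seed in range(6):
            cfg = syn.SimConfig(n_founders=150, n_generations=2, n_sires=30,
                                n_animals_target=500, n_snps=300, seed=100 + seed,
                                beta_causal=0.0, rg_target=None)
            sim = syn.simulate_dataset(cfg)
            A = kin.pedigree_A(sim.pedigree)
            gq, _ = kin.snp_qc(sim.genotypes)
            Gb = kin.blend_G(kin.genomic_G(gq), A.submatrix(gq.ids))
            Hinv = kin.build_H_inverse(
                A.inverse(), A.submatrix(gq.ids).inverse(), Gb.inverse(), gq.ids
            )
            n = sim.genotypes.n_animals
            res = estimate_genetic_correlation(
                sim.latent_A, sim.latent_B, np.ones((n, 1)), Hinv,
                sim.genotypes.ids,
            )
            rgs.append(res["r_g"])
        assert abs(np.mean(rgs)) < 0.15


class TestBacksolve:
    def setup_method(self):
        self.geno = random_genotypes(40, 120, seed=13)
        self.freqs = self.geno.founder_freqs  # keeps unblended G invertible
        self.G = genomic_G(self.geno, self.freqs)
        self.Zc = self.geno.dosages - 2 * self.freqs

    def _solution(self, y):
        return solve_mme(y, np.ones((40, 1)), self.G.inverse(), 1.0,
                         record_ids=self.geno.ids)

    def test_zero_gebv_zero_effects(self):
        sol = self._solution(np.zeros(40))
        u = backsolve_snp_effects(sol, self.Zc, self.G, self.freqs)
        np.testing.assert_allclose(u, 0.0, atol=1e-12)

    def test_reconstruction_identity_unblended(self):
        rng = np.random.default_rng(14)
        sol = self._solution(rng.standard_normal(40))
        u = backsolve_snp_effects(sol, self.Zc, self.G, self.freqs)
        a = sol.gebv.reindex(self.G.ids).to_numpy()
        assert np.abs(self.Zc @ u - a).max() < 1e-8

    def test_blended_reconstruction_error_small(self):
        from lvscan.kinship import RelationshipMatrix, blend_G
        rng = np.random.default_rng(15)
        A22 = RelationshipMatrix(np.eye(40), self.geno.ids, "A22")
        Gb = blend_G(self.G, A22, 0.95)
        y = rng.standard_normal(40)
        sol = solve_mme(y, np.ones((40, 1)), Gb.inverse(), 1.0,
                        record_ids=self.geno.ids)
        u = backsolve_snp_effects(sol, self.Zc, Gb, self.freqs,
                                  reconstruction_tol=1.0)
        a = sol.gebv.reindex(Gb.ids).to_numpy()
        rel = np.linalg.norm(self.Zc @ u - a) / np.linalg.norm(a)
        assert rel < 0.1


def test_no_genotypes_matches_pedigree_blup():
    # cross-module property: ssGBLUP with an empty genotype set reproduces
    # pedigree BLUP exactly
    from lvscan.kinship import build_H_inverse
    ped = random_small_pedigree(16, n_founders=5, n_nonf=7)
    A = pedigree_A(ped)
    Hinv = build_H_inverse(A.inverse(), None, None, [])
    rng = np.random.default_rng(17)
    n = len(A.ids)
    y = rng.standard_normal(n)
    X = np.ones((n, 1))
    sol_h = solve_mme(y, X, Hinv, 1.7, record_ids=A.ids)
    sol_a = solve_mme(y, X, A.inverse(), 1.7, record_ids=A.ids)
    np.testing.assert_allclose(sol_h.gebv.to_numpy(), sol_a.gebv.to_numpy(),
                               atol=1e-10)
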