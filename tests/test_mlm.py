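"""REML fitting: dense-matrix oracles, grid-search oracle, path equivalence."""

import numpy as np
import pytest

import greml as gm
from greml.mlm import MLMData, airml_fit, gls_fixed_effects, reml_fit_eigen, restricted_loglik


def simulated_problem(n, m, n_qtn, h2, seed, x=None):
    g = gm.simulate_genotypes(gm.GenotypeSimSpec(n_samples=n, n_snps=m, seed=seed))
    trait = gm.simulate_trait(g, gm.TraitSimSpec(n_qtn=n_qtn, h2=h2, seed=seed + 1))
    z = gm.standardize(g, gm.compute_snp_stats(g))
    return MLMData(y=trait.phenotypes, x=x, z=z), z, trait


def dense_restricted_loglik(sg, se, y, x, G):
    """Brute-force REML value from explicit V, for use as an oracle."""
    n = y.size
    V = sg * G + se * np.eye(n)
    Vi = np.linalg.inv(V)
    xvx = x.T @ Vi @ x
    P = Vi - Vi @ x @ np.linalg.inv(xvx) @ x.T @ Vi
    return -0.5 * (
        np.linalg.slogdet(V)[1] + np.linalg.slogdet(xvx)[1] + y @ P @ y
    )


class TestRestrictedLoglik:
    def test_collapses_to_residual_model_at_zero_genetic_variance(self):
        data, _, _ = simulated_problem(30, 10, 5, 0.5, seed=1)
        se = 0.8
        y, x = data.y, data.x
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        rss = float(((y - x @ beta) ** 2).sum())
        n, c = data.n, data.c
        expected = -0.5 * (
            (n - c) * np.log(se) + rss / se
            + np.linalg.slogdet(x.T @ x)[1]
        )
        assert restricted_loglik((0.0, se), data) == pytest.approx(expected, abs=1e-8)

    def test_translation_invariance_with_intercept(self):
        data, z, trait = simulated_problem(25, 15, 5, 0.5, seed=2)
        shifted = MLMData(y=trait.phenotypes + 17.3, z=z)
        a = restricted_loglik((0.4, 0.6), data)
        b = restricted_loglik((0.4, 0.6), shifted)
        assert a == pytest.approx(b, abs=1e-8)

    @pytest.mark.parametrize("theta", [(0.3, 0.7), (0.9, 0.2)])
    def test_matches_dense_determinant_oracle(self, theta):
        data, z, _ = simulated_problem(6, 4, 2, 0.5, seed=3)
        G = z.values @ z.values.T / z.n_snps
        expected = dense_restricted_loglik(*theta, data.y, data.x, G)
        assert restricted_loglik(theta, data) == pytest.approx(expected, abs=1e-9)

    def test_grm_and_z_representations_agree(self):
        data, z, trait = simulated_problem(40, 25, 10, 0.5, seed=4)
        grm = gm.compute_grm(z)
        data_g = MLMData(y=trait.phenotypes, grm=grm)
        a = restricted_loglik((0.5, 0.5), data)
        b = restricted_loglik((0.5, 0.5), data_g)
        assert a == pytest.approx(b, abs=1e-8)

    def test_rejects_nonpositive_residual_variance(self):
        data, _, _ = simulated_problem(10, 5, 2, 0.5, seed=5)
        with pytest.raises(ValueError):
            restricted_loglik((0.5, 0.0), data)


class TestAiReml:
    def test_pure_noise_trait_estimates_negligible_heritability(self):
        """A trait independent of the genotypes yields h2-hat near zero; a
        fixture where the optimum collapses to the constraint also raises
        the boundary flag."""
        g = gm.simulate_genotypes(gm.GenotypeSimSpec(n_samples=500, n_snps=200, seed=6))
        z = gm.standardize(g, gm.compute_snp_stats(g))
        for seed, expect_boundary in ((7, None), (10, True)):
            y = np.random.default_rng(seed).standard_normal(500)
            vc = airml_fit(MLMData(y=y, z=z))
            assert vc.h2 <= 0.05
            if expect_boundary:
                assert vc.boundary
                assert vc.sigma2_g == pytest.approx(1e-6 * np.var(y))

    def test_matches_two_dimensional_grid_search_oracle(self):
        data, z, trait = simulated_problem(12, 4, 4, 0.5, seed=8)
        vc = airml_fit(data)
        y, vy = data.y, float(np.var(data.y))
        G = z.values @ z.values.T / z.n_snps
        w, u = np.linalg.eigh(G)          # independent full rotation
        yt, xt = u.T @ y, (u.T @ data.x)[:, 0]
        res = 1e-3 * vy
        sg_grid = np.arange(0.0, 2 * vy + res, res)
        best_ll, best = -np.inf, None
        for se in np.arange(res, 2 * vy + res, res):
            lam = sg_grid[:, None] * w[None, :] + se
            a = 1.0 / lam
            xtvx = (a * xt**2).sum(1)
            xtvy = (a * xt * yt).sum(1)
            yvy = (a * yt**2).sum(1)
            ll = -0.5 * (np.log(lam).sum(1) + np.log(xtvx) + yvy - xtvy**2 / xtvx)
            i = int(np.argmax(ll))
            if ll[i] > best_ll:
                best_ll, best = ll[i], (sg_grid[i], se)
        assert abs(vc.sigma2_g - best[0]) <= res
        assert abs(vc.sigma2_e - best[1]) <= res

    def test_loglik_path_monotone_nondecreasing(self):
        data, _, _ = simulated_problem(200, 100, 30, 0.5, seed=9)
        vc = airml_fit(data)
        path = np.asarray(vc.loglik_path)
        assert (np.diff(path) >= -1e-10).all()
        assert vc.converged

    def test_scale_equivariance(self):
        data, z, trait = simulated_problem(150, 80, 20, 0.5, seed=10)
        c = 3.7
        vc1 = airml_fit(data)
        vc2 = airml_fit(MLMData(y=c * trait.phenotypes, z=z))
        assert vc2.h2 == pytest.approx(vc1.h2, abs=1e-8)
        assert vc2.sigma2_g == pytest.approx(c**2 * vc1.sigma2_g, rel=1e-6)
        assert vc2.sigma2_e == pytest.approx(c**2 * vc1.sigma2_e, rel=1e-6)

    def test_h2_consistent_with_components(self):
        data, _, _ = simulated_problem(100, 50, 20, 0.5, seed=11)
        vc = airml_fit(data)
        assert vc.h2 == pytest.approx(
            vc.sigma2_g / (vc.sigma2_g + vc.sigma2_e), abs=1e-12
        )
        assert vc.se_h2 >= 0


@pytest.mark.parametrize("h2", [0.2, 0.5, 0.7])
def test_reml_recovers_simulated_heritability(h2):
    """Mean REML h2-hat over 30 replicates (N=2000, M=1000, 100 QTNs)
    lies within 2 Monte-Carlo s.e. of the generating heritability."""
    est = []
    for rep in range(30):
        seed = 50_000 + 1000 * int(h2 * 10) + rep
        g = gm.simulate_genotypes(
            gm.GenotypeSimSpec(n_samples=2000, n_snps=1000, seed=seed)
        )
        trait = gm.simulate_trait(
            g, gm.TraitSimSpec(n_qtn=100, h2=h2, seed=seed + 1)
        )
        z = gm.standardize(g, gm.compute_snp_stats(g))
        vc = airml_fit(MLMData(y=trait.phenotypes, z=z))
        est.append(vc.h2)
    est = np.asarray(est)
    sem = est.std(ddof=1) / np.sqrt(est.size)
    assert abs(est.mean() - h2) <= 2 * sem


class TestEigenPath:
    def test_agrees_with_ai_reml_on_random_instances(self):
        for s in range(8):
            data, _, _ = simulated_problem(120 + 11 * s, 200, 50, 0.5, seed=100 + s)
            v1 = airml_fit(data)
            v2 = reml_fit_eigen(data)
            if v1.boundary and v2.boundary:
                continue
            assert v2.sigma2_g == pytest.approx(v1.sigma2_g, rel=1e-4)
            assert v2.sigma2_e == pytest.approx(v1.sigma2_e, rel=1e-4)
            assert v2.loglik >= v1.loglik - 1e-6

    def test_noise_trait_reports_boundary(self):
        g = gm.simulate_genotypes(gm.GenotypeSimSpec(n_samples=300, n_snps=150, seed=12))
        z = gm.standardize(g, gm.compute_snp_stats(g))
        y = np.random.default_rng(13).standard_normal(300)
        vc = reml_fit_eigen(MLMData(y=y, z=z))
        assert vc.boundary
        assert vc.h2 < 0.05

    def test_explicit_grm_eigendecomposition_accepted(self):
        data, z, trait = simulated_problem(60, 40, 10, 0.5, seed=14)
        grm = gm.compute_grm(z)
        eig = gm.eigendecompose_grm(grm)
        data_g = MLMData(y=trait.phenotypes, grm=grm)
        v1 = reml_fit_eigen(data_g, grm_eigen=eig)
        v2 = reml_fit_eigen(data)
        assert v1.sigma2_g == pytest.approx(v2.sigma2_g, rel=1e-6, abs=1e-10)


class TestGlsFixedEffects:
    def test_reduces_to_ols_at_zero_genetic_variance(self):
        data, _, _ = simulated_problem(50, 20, 5, 0.5, seed=15,
                                       x=np.column_stack([np.ones(50),
                                                          np.arange(50.0)]))
        vc = gm.VarianceComponents(0.0, 0.7, 0.0, 0, 0, 0, 0.0, 0, True, True)
        beta, se = gls_fixed_effects(data, vc)
        ols = np.linalg.lstsq(data.x, data.y, rcond=None)[0]
        np.testing.assert_allclose(beta, ols, atol=1e-10)

    def test_intercept_only_identity_v_gives_mean(self):
        data, _, _ = simulated_problem(40, 10, 5, 0.5, seed=16)
        vc = gm.VarianceComponents(0.0, 1.0, 0.0, 0, 0, 0, 0.0, 0, True, True)
        beta, _ = gls_fixed_effects(data, vc)
        assert beta[0] == pytest.approx(data.y.mean(), abs=1e-12)

    def test_matches_dense_solve_oracle(self):
        x = np.column_stack([np.ones(6), [0.0, 1, 2, 0, 1, 2]])
        data, z, _ = simulated_problem(6, 3, 2, 0.5, seed=17, x=x)
        vc = gm.VarianceComponents(0.4, 0.6, 0.4, 0, 0, 0, 0.0, 0, True, False)
        beta, se = gls_fixed_effects(data, vc)
        G = z.values @ z.values.T / z.n_snps
        Vi = np.linalg.inv(0.4 * G + 0.6 * np.eye(6))
        xvx = x.T @ Vi @ x
        expected = np.linalg.solve(xvx, x.T @ Vi @ data.y)
        np.testing.assert_allclose(beta, expected, atol=1e-10)
        np.testing.assert_allclose(
            se, np.sqrt(np.diag(np.linalg.inv(xvx))), atol=1e-10
        )
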