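"""Mixed-model machinery: projection adjustments against hat-matrix
oracles, REML against a grid-search oracle, the measured genotype test
against OLS when K = I, and GRAMMAR against its closed matrix form."""

import numpy as np
import pytest

from pedscore import (
    KinshipMatrix,
    additive_relationship,
    adjust_covariates,
    adjust_major_gene,
    fit_polygenic,
    grammar_decorrelate,
    kinship_eigen,
    measured_genotype_test,
    simulate_pedigree,
)


def hat_residuals(y, design):
    """Explicit (I - H) y with H = X (X'X)^+ X'."""
    h = design @ np.linalg.pinv(design.T @ design) @ design.T
    return (np.eye(len(y)) - h) @ y


def reml_loglik_dense(h2, y, k_values, x):
    """Direct-matrix REML profile log-likelihood (independent of the
    rotated-basis implementation)."""
    n, p = x.shape
    v = h2 * k_values + (1 - h2) * np.eye(n)
    vinv = np.linalg.inv(v)
    xvx = x.T @ vinv @ x
    beta = np.linalg.solve(xvx, x.T @ vinv @ y)
    r = y - x @ beta
    sigma_p2 = float(r @ vinv @ r) / (n - p)
    _, ld_v = np.linalg.slogdet(v)
    _, ld_xvx = np.linalg.slogdet(xvx)
    return -0.5 * ((n - p) * np.log(sigma_p2) + ld_v + ld_xvx + (n - p))


@pytest.fixture
def toy12():
    """12-individual two-family pedigree with kinship and a fixed trait."""
    ped = simulate_pedigree(2, 2, 4, seed=42)
    assert ped.n == 12
    k = additive_relationship(ped)
    rng = np.random.default_rng(7)
    y = rng.normal(size=12) + 0.8 * rng.normal() * np.ones(12)
    return ped, k, y


class TestAdjustCovariates:
    def test_matches_hat_matrix_oracle(self):
        rng = np.random.default_rng(0)
        age = np.array([30, 41, 52, 63, 74, 25, 36, 47, 58, 69], dtype=float)
        sex = np.array([1, 2, 1, 2, 1, 2, 1, 2, 1, 2], dtype=float)
        y = rng.normal(size=10)
        got = adjust_covariates(y, np.column_stack([age, sex]))
        want = hat_residuals(y, np.column_stack([np.ones(10), age, sex]))
        np.testing.assert_allclose(got, want, atol=1e-12)
        # residuals orthogonal to both covariates
        assert abs(got @ age) < 1e-9 and abs(got @ sex) < 1e-9

    def test_projection_idempotent_and_exact_fit(self):
        age = np.linspace(20, 70, 8)
        sex = np.array([1, 2] * 4, dtype=float)
        cov = np.column_stack([age, sex])
        np.testing.assert_allclose(adjust_covariates(3 * age, cov), 0, atol=1e-10)
        resid = adjust_covariates(np.random.default_rng(1).normal(size=8), cov)
        np.testing.assert_allclose(adjust_covariates(resid, cov), resid, atol=1e-10)

    def test_constant_column_handled_rank_aware(self):
        y = np.random.default_rng(2).normal(size=8)
        cov = np.column_stack([np.ones(8), np.arange(8.0)])
        got = adjust_covariates(y, cov)
        want = hat_residuals(y, np.column_stack([np.ones(8), np.arange(8.0)]))
        np.testing.assert_allclose(got, want, atol=1e-10)


class TestFitPolygenic:
    def test_identity_kinship_gives_h2_zero(self):
        k = KinshipMatrix(np.eye(20), [f"i{j}" for j in range(20)])
        fit = fit_polygenic(np.random.default_rng(3).normal(size=20), k)
        assert fit.h2 == 0.0
        assert fit.sigma_u2 == 0.0

    def test_matches_grid_search_oracle(self, toy12):
        _, k, y = toy12
        fit = fit_polygenic(y, k)
        grid = np.arange(0.0, 1.0, 0.001)
        x = np.ones((12, 1))
        lls = [reml_loglik_dense(h, y, k.values, x) for h in grid]
        h2_grid = grid[int(np.argmax(lls))]
        assert fit.h2 == pytest.approx(h2_grid, abs=0.001)
        # returned optimum is at least as good as every grid point
        assert reml_loglik_dense(fit.h2, y, k.values, x) >= max(lls) - 1e-6

    def test_residual_identity_and_errors(self, toy12):
        _, k, y = toy12
        fit = fit_polygenic(y, k)
        np.testing.assert_allclose(fit.residuals, y - fit.mu_hat - fit.u_hat, atol=1e-12)
        assert 0.0 <= fit.h2 < 1.0 and fit.sigma_u2 >= 0 and fit.sigma_eps2 > 0
        with pytest.raises(ValueError, match="zero variance"):
            fit_polygenic(np.ones(12), k)

    def test_recovers_simulated_heritability(self):
        ped = simulate_pedigree(10, 3, 3, seed=5)
        k = additive_relationship(ped)
        eig = kinship_eigen(k)
        rng = np.random.default_rng(6)
        sd = np.sqrt(0.5 * eig.d + 0.5)
        est = [
            fit_polygenic(eig.u @ (sd * rng.normal(size=ped.n)), k, eig=eig).h2
            for _ in range(40)
        ]
        assert np.mean(est) == pytest.approx(0.5, abs=0.08)


class TestMeasuredGenotypeTest:
    def test_identity_kinship_collapses_to_ols(self):
        rng = np.random.default_rng(8)
        n = 40
        g = rng.integers(0, 3, size=n).astype(float)
        y = 0.3 * g + rng.normal(size=n)
        k = KinshipMatrix(np.eye(n), [f"i{j}" for j in range(n)])
        beta, se, _ = measured_genotype_test(y, g, k)
        x = np.column_stack([np.ones(n), g])
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ coef
        sigma2 = resid @ resid / (n - 2)
        se_ols = np.sqrt(sigma2 * np.linalg.inv(x.T @ x)[1, 1])
        assert beta == pytest.approx(coef[1], rel=1e-6)
        assert se == pytest.approx(se_ols, rel=1e-6)

    def test_monomorphic_rejected_and_missing_imputed(self, toy12):
        _, k, y = toy12
        with pytest.raises(ValueError, match="monomorphic"):
            measured_genotype_test(y, np.ones(12), k)
        g = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0, 1, -1], dtype=float)
        beta, se, p = measured_genotype_test(y, g, k)
        assert np.isfinite([beta, se]).all() and 0 < p <= 1

    def test_recovers_effect_sign(self, mid_study):
        ped, geno, k, eig, panel = mid_study
        rng = np.random.default_rng(9)
        hits = 0
        for rep in range(20):
            g = geno.imputed(np.array([rng.integers(geno.n_snps)]))[:, 0]
            gc = (g - g.mean()) / g.std()
            y = 0.1 * gc + rng.normal(size=ped.n)  # 1% of variance
            beta, _, _ = measured_genotype_test(y, g, k, eig=eig)
            hits += beta > 0
        assert hits >= 19


class TestGrammar:
    def test_matches_closed_form_matrix_oracle(self, toy12):
        _, k, y = toy12
        fit = fit_polygenic(y, k)
        got = grammar_decorrelate(y, k)
        n = len(y)
        v = fit.sigma_u2 * k.values + fit.sigma_eps2 * np.eye(n)
        u_hat = fit.sigma_u2 * k.values @ np.linalg.solve(v, y - fit.mu_hat)
        np.testing.assert_allclose(got, y - fit.mu_hat - u_hat, atol=1e-8)

    def test_h2_zero_reduces_to_centering(self):
        k = KinshipMatrix(np.eye(15), [f"i{j}" for j in range(15)])
        y = np.random.default_rng(11).normal(size=15)
        np.testing.assert_allclose(grammar_decorrelate(y, k), y - y.mean(), atol=1e-10)

    def test_shrinks_variance_and_family_correlation(self, mid_study):
        ped, geno, k, eig, panel = mid_study
        smaller = 0
        for r in range(1, 11):
            y = adjust_covariates(panel.replicate(r), panel.covariates)
            y_star = grammar_decorrelate(y, k, eig=eig)
            assert np.var(y_star) <= np.var(y) + 1e-12
            fam_means_raw, fam_means_dec = [], []
            for idx in ped.family_blocks().values():
                fam_means_raw.append(y[idx].mean())
                fam_means_dec.append(y_star[idx].mean())
            smaller += np.var(fam_means_dec) < np.var(fam_means_raw)
        assert smaller >= 9  # family-level signal removed in >= 90% of replicates


class TestAdjustMajorGene:
    def test_matches_hat_matrix_oracle_two_snps(self):
        rng = np.random.default_rng(12)
        g = rng.integers(0, 3, size=(10, 2)).astype(float)
        y = rng.normal(size=10)
        got = adjust_major_gene(y, g)
        want = hat_residuals(y, np.column_stack([np.ones(10), g]))
        np.testing.assert_allclose(got, want, atol=1e-10)
        assert np.abs(got @ g).max() < 1e-9

    def test_exact_linear_trait_and_collinear_columns(self):
        g = np.array([[0.0, 0], [1, 1], [2, 2], [0, 0], [1, 1], [2, 2]])
        y = 2.0 * g[:, 0] + 1.0
        np.testing.assert_allclose(adjust_major_gene(y, g), 0, atol=1e-10)
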