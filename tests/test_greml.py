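"""REML variance components, BLUP, heritability arithmetic, and the LRT."""

import numpy as np
import pytest
from scipy import stats

from domgp import (SimulationConfig, VarianceComponents, blup_solve, build_G,
                   build_trait_design, heritabilities, likelihood_ratio_test,
                   reml_fit, simulate_dataset, stabilize)
from domgp.greml import TraitDesign, restricted_loglik


def direct_restricted_loglik(y, X, V):
    """Independent dense evaluation of the restricted normal log-likelihood."""
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    P = Vinv - Vinv @ X @ np.linalg.inv(XtVinvX) @ X.T @ Vinv
    s, ld_V = np.linalg.slogdet(V)
    assert s > 0
    s, ld_X = np.linalg.slogdet(XtVinvX)
    assert s > 0
    return -0.5 * (ld_V + ld_X + y @ P @ y)


class TestRemlFit:
    def test_loglik_matches_direct_evaluation(self, cw_dataset, cw_design, cw_matrices):
        G, D = cw_matrices
        vc = reml_fit(cw_design, [G, D])
        assert vc.converged
        V = (
            vc.sigma_a2 * G.values
            + vc.sigma_d2 * D.values
            + vc.sigma_e2 * np.eye(cw_design.n)
        )
        direct = direct_restricted_loglik(cw_design.y, cw_design.X, V)
        assert vc.logL == pytest.approx(direct, abs=1e-6)
        # and through the package's own evaluator at the optimum
        assert restricted_loglik(cw_design, [G, D], vc) == pytest.approx(
            vc.logL, abs=1e-8
        )

    def test_pure_noise_hits_boundary(self):
        cfg = SimulationConfig(
            n_individuals=300, n_snps=600, h2_additive=0.0, h2_dominance=0.0,
            n_qtl_additive=0, n_qtl_dominance=0, seed=21,
        )
        ds = simulate_dataset(cfg)
        design = build_trait_design(ds.phenotypes)
        G = stabilize(build_G(ds.genotypes), 1e-6)
        from domgp import build_D

        D = stabilize(build_D(ds.genotypes), 1e-6)
        vc_a = reml_fit(design, [G])
        vc_ad = reml_fit(design, [G, D])
        vary = np.var(design.y)
        assert vc_ad.sigma_a2 < 0.15 * vary
        assert vc_ad.sigma_d2 < 0.15 * vary
        assert vc_ad.logL - vc_a.logL < 2.0

    def test_nested_models_ordered(self, cw_design, cw_matrices):
        G, D = cw_matrices
        logL_a = reml_fit(cw_design, [G]).logL
        logL_ad = reml_fit(cw_design, [G, D]).logL
        assert logL_ad >= logL_a - 1e-6

    def test_translation_and_scale_equivariance(self, cw_design, cw_matrices):
        G, D = cw_matrices
        base = reml_fit(cw_design, [G, D])
        shifted = TraitDesign(
            cw_design.y + 100.0, cw_design.X, cw_design.column_names
        )
        vc_s = reml_fit(shifted, [G, D])
        assert vc_s.sigma_a2 == pytest.approx(base.sigma_a2, rel=1e-3)
        assert vc_s.sigma_e2 == pytest.approx(base.sigma_e2, rel=1e-3)
        scaled = TraitDesign(3.0 * cw_design.y, cw_design.X, cw_design.column_names)
        vc_c = reml_fit(scaled, [G, D])
        assert vc_c.sigma_a2 == pytest.approx(9.0 * base.sigma_a2, rel=1e-3)
        assert vc_c.sigma_d2 == pytest.approx(9.0 * base.sigma_d2, rel=1e-2)
        assert vc_c.sigma_e2 == pytest.approx(9.0 * base.sigma_e2, rel=1e-3)

    def test_quick_parameter_recovery(self, cw_dataset, cw_design, cw_matrices):
        """Single-seed sanity check (wide bounds: the dominance ratio has a
        sampling SD near 0.1 at this size); the multi-seed recovery check
        lives in the acceptance suite."""
        G, D = cw_matrices
        vc = reml_fit(cw_design, [G, D])
        h = heritabilities(vc)
        assert 0.15 < h.h2_narrow < 0.65
        assert 0.0 <= h.h2_dominance < 0.45
        assert h.h2_broad < 0.85

    def test_dimension_mismatch_rejected(self, cw_design, cw_matrices):
        G, _ = cw_matrices
        short = TraitDesign(
            cw_design.y[:100], cw_design.X[:100, :1], ["intercept"]
        )
        with pytest.raises(ValueError, match="dimension"):
            reml_fit(short, [G])


class TestHeritabilities:
    @pytest.mark.parametrize(
        "components,expected",
        [
            # (sigma_a2, sigma_d2, sigma_e2) -> (hA2, hD2, d/(a+d))
            ((415.642, 156.579, 417.453), (0.420, 0.158, 0.274)),
            ((0.000133, 0.0000932, 0.000352), (0.230, 0.161, 0.412)),
            ((1.0, 0.0, 1.0), (0.5, 0.0, 0.0)),
        ],
    )
    def test_ratio_arithmetic(self, components, expected):
        sa, sd, se = components
        h = heritabilities(VarianceComponents(sigma_a2=sa, sigma_d2=sd, sigma_e2=se))
        assert h.h2_narrow == pytest.approx(expected[0], abs=5e-4)
        assert h.h2_dominance == pytest.approx(expected[1], abs=5e-4)
        assert h.dominance_to_genetic == pytest.approx(expected[2], abs=1e-3)
        assert h.h2_broad == pytest.approx(h.h2_narrow + h.h2_dominance, abs=1e-12)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValueError):
            heritabilities(VarianceComponents(sigma_a2=0.0, sigma_d2=0.0, sigma_e2=0.0))


class TestBlupSolve:
    def test_identity_g_closed_form_shrinkage(self):
        rng = np.random.default_rng(17)
        n = 60
        y = rng.standard_normal(n)
        design = TraitDesign(y, np.ones((n, 1)), ["intercept"])
        from domgp.grm import RelationshipMatrix

        G = RelationshipMatrix(np.eye(n), "additive", 1.0, np.array([]))
        vc = VarianceComponents(sigma_a2=0.7, sigma_e2=0.3)
        sol = blup_solve(design, [G], vc)
        k = 0.7 / (0.7 + 0.3)
        assert np.allclose(sol.a_hat, k * (y - sol.b_hat[0]), atol=1e-10)

    def test_vanishing_dominance_matches_additive_model(self, cw_design, cw_matrices):
        G, D = cw_matrices
        vc_a = VarianceComponents(sigma_a2=0.4, sigma_e2=0.6)
        vc_ad = VarianceComponents(sigma_a2=0.4, sigma_d2=1e-12, sigma_e2=0.6)
        sol_a = blup_solve(cw_design, [G], vc_a)
        sol_ad = blup_solve(cw_design, [G, D], vc_ad)
        assert np.max(np.abs(sol_a.a_hat - sol_ad.a_hat)) < 1e-6
        assert np.max(np.abs(sol_a.b_hat - sol_ad.b_hat)) < 1e-6

    def test_mme_equals_direct_gls_blup(self, cw_design, cw_matrices):
        """Henderson MME solution vs direct full-covariance GLS on a subset."""
        G, D = cw_matrices
        rows = np.arange(80)
        design = TraitDesign(
            cw_design.y[rows], cw_design.X[rows, :3], cw_design.column_names[:3]
        )
        from domgp.grm import RelationshipMatrix

        Gs = RelationshipMatrix(G.submatrix(rows), "additive", 1.0, np.array([]))
        Ds = RelationshipMatrix(D.submatrix(rows), "dominance", 1.0, np.array([]))
        vc = VarianceComponents(sigma_a2=0.5, sigma_d2=0.2, sigma_e2=0.4)
        sol = blup_solve(design, [Gs, Ds], vc)
        V = 0.5 * Gs.values + 0.2 * Ds.values + 0.4 * np.eye(80)
        Vinv = np.linalg.inv(V)
        X, y = design.X, design.y
        b = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
        a = 0.5 * Gs.values @ Vinv @ (y - X @ b)
        d = 0.2 * Ds.values @ Vinv @ (y - X @ b)
        assert np.allclose(sol.b_hat, b, atol=1e-8)
        assert np.allclose(sol.a_hat, a, atol=1e-8)
        assert np.allclose(sol.d_hat, d, atol=1e-8)

    def test_gblup_equals_snp_blup(self):
        """a_hat from GBLUP == M @ (ridge-regression SNP effects) at matched ratio."""
        rng = np.random.default_rng(23)
        cfg = SimulationConfig(
            n_individuals=80, n_snps=120, h2_additive=0.5, h2_dominance=0.0,
            n_qtl_additive=40, n_qtl_dominance=0, seed=23,
        )
        ds = simulate_dataset(cfg)
        from domgp.grm import marker_codings

        cod = marker_codings(ds.genotypes)
        M = cod.M
        sum2pq = float(np.sum(2 * cod.freqs * (1 - cod.freqs)))
        y = ds.phenotypes["trait"].to_numpy()
        design = TraitDesign(y, np.ones((len(y), 1)), ["intercept"])
        G = build_G(ds.genotypes)
        sigma_a2, sigma_e2 = 0.5, 0.5
        sol = blup_solve(design, [stabilize(G, 1e-8)],
                         VarianceComponents(sigma_a2=sigma_a2, sigma_e2=sigma_e2))
        # SNP-BLUP: per-marker variance sigma_a2 / sum2pq, same residual
        lam = sigma_e2 * sum2pq / sigma_a2
        m = M.shape[1]
        ones = np.ones((len(y), 1))
        C = np.block(
            [
                [ones.T @ ones, ones.T @ M],
                [M.T @ ones, M.T @ M + lam * np.eye(m)],
            ]
        )
        rhs = np.concatenate([ones.T @ y, M.T @ y])
        sol_snp = np.linalg.solve(C, rhs)
        a_snp = M @ sol_snp[1:]
        assert np.corrcoef(sol.a_hat, a_snp)[0, 1] > 1 - 1e-6
        assert np.allclose(sol.a_hat, a_snp, atol=1e-4)

    def test_zero_component_rejected(self, cw_design, cw_matrices):
        G, _ = cw_matrices
        with pytest.raises(ValueError, match="positive"):
            blup_solve(cw_design, [G], VarianceComponents(sigma_a2=0.0, sigma_e2=1.0))


class TestLikelihoodRatioTest:
    def test_equal_likelihoods(self):
        res = likelihood_ratio_test(-100.0, -100.0)
        assert res.chi2 == 0.0
        assert res.p_value == pytest.approx(0.5)

    def test_standard_quantile(self):
        res = likelihood_ratio_test(-100.0, -100.0 + 3.84 / 2)
        assert res.chi2 == pytest.approx(3.84)
        assert res.p_value_chi2_1 == pytest.approx(0.050, abs=5e-4)
        assert res.p_value == pytest.approx(0.025, abs=3e-4)

    def test_negative_statistic_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clamping"):
            res = likelihood_ratio_test(-99.0, -100.0)
        assert res.chi2 == 0.0

    def test_mixture_halves_tail_probability(self):
        for c in (0.5, 2.0, 6.6):
            res = likelihood_ratio_test(0.0, c / 2)
            assert res.p_value == pytest.approx(0.5 * stats.chi2.sf(c, 1))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            likelihood_ratio_test(np.nan, 0.0)
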