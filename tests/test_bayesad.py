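"""BayesA/BayesAD sampler: codings, scale calibration, conjugate oracle,
signal recovery, and the limiting-case links to BayesA and the prior."""

import numpy as np
import pytest
from scipy import stats

from domgp import (BayesADHyper, SimulationConfig, build_designs, derive_scale,
                   predict_genetic_values, run_chain, simulate_dataset)
from domgp.greml import TraitDesign
from domgp.io_qc import GenotypeMatrix, MISSING

from conftest import make_geno_frame


def geno_from(dosages):
    d = np.asarray(dosages, dtype=np.int8)
    return GenotypeMatrix(
        d, [f"i{k}" for k in range(d.shape[0])], make_geno_frame(d.shape[1])
    )


def intercept_design(y):
    return TraitDesign(np.asarray(y, float), np.ones((len(y), 1)), ["intercept"])


class TestBuildDesigns:
    def test_coding_definitions(self):
        g = geno_from([[0], [1], [2]])
        d = build_designs(g)
        assert np.allclose(d.Wa[:, 0] + d.means_a[0], [0, 1, 2])
        assert np.allclose(d.Wb[:, 0] + d.means_b[0], [0, 1, 0])

    def test_all_homozygous_snp_has_zero_het_column(self):
        g = geno_from([[0], [2], [0], [2]])
        d = build_designs(g)
        assert np.allclose(d.Wb[:, 0] + d.means_b[0], 0.0)

    def test_columns_centered(self):
        rng = np.random.default_rng(4)
        g = geno_from(rng.binomial(2, 0.4, size=(50, 20)))
        d = build_designs(g)
        assert np.max(np.abs(d.Wa.mean(0))) < 1e-12
        assert np.max(np.abs(d.Wb.mean(0))) < 1e-12

    def test_missing_filled_with_column_mean(self):
        g = geno_from([[0], [2], [MISSING], [2]])
        d = build_designs(g)
        assert d.n_missing_filled == 1
        # filled entry equals the observed mean -> centered value 0
        assert d.Wa[2, 0] == pytest.approx(0.0)


@pytest.fixture(scope="module")
def geno():
    rng = np.random.default_rng(5)
    return geno_from(rng.binomial(2, 0.3, size=(100, 50)))


class TestDeriveScale:
    def test_linearity_in_trait_variance(self, geno):
        s1 = derive_scale(0.4, geno, 4.2, var_y=1.0)
        s2 = derive_scale(0.4, geno, 4.2, var_y=2.0)
        assert s2 == pytest.approx(2.0 * s1)

    def test_inverts_prior_variance_identity(self, geno):
        from domgp.grm import allele_frequencies

        h2, nu, vary = 0.37, 5.0, 2.3
        s2 = derive_scale(h2, geno, nu, var_y=vary)
        p = allele_frequencies(geno)
        sum2pq = np.sum(2 * p * (1 - p))
        var_alpha = s2 * nu / (nu - 2)
        assert var_alpha * sum2pq == pytest.approx(h2 * vary, rel=1e-12)

    def test_large_nu_limit(self, geno):
        from domgp.grm import allele_frequencies

        p = allele_frequencies(geno)
        sum2pq = np.sum(2 * p * (1 - p))
        s2 = derive_scale(0.5, geno, 1e9, var_y=1.0)
        assert s2 == pytest.approx(0.5 / sum2pq, rel=1e-6)


class TestRunChain:
    def test_seeded_determinism(self):
        cfg = SimulationConfig(
            n_individuals=60, n_snps=40, n_qtl_additive=10, n_qtl_dominance=5, seed=3
        )
        ds = simulate_dataset(cfg)
        design = intercept_design(ds.phenotypes["trait"])
        d = build_designs(ds.genotypes)
        hyper = BayesADHyper(n_iterations=200, burn_in=50, thinning=2, seed=9)
        a = run_chain(design, d, hyper, model="bayesAD")
        b = run_chain(design, d, hyper, model="bayesAD")
        assert np.array_equal(a.alpha_mean, b.alpha_mean)
        assert np.array_equal(a.beta_mean, b.beta_mean)
        assert a.acceptance_rate == b.acceptance_rate

    def test_null_data_calibration(self):
        rng = np.random.default_rng(11)
        n, m = 300, 400
        g = geno_from(rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)))
        y = rng.standard_normal(n)  # pure noise, variance 1
        design = intercept_design(y)
        d = build_designs(g)
        # weak prior scale so the residual conditional, not prior mass,
        # determines sigma_e2 (an informative scale would legitimately pull
        # phenotypic variance into the markers even without signal)
        hyper = BayesADHyper(
            s_alpha2=derive_scale(0.05, g, 4.2), n_iterations=1500, burn_in=500,
            thinning=5, seed=12,
        )
        s = run_chain(design, d, hyper, model="bayesAD")
        assert np.all(np.abs(s.alpha_mean) <= 4 * s.alpha_sd + 1e-12)
        assert np.all(np.abs(s.beta_mean) <= 4 * s.beta_sd + 1e-12)
        assert s.sigma_e2_mean == pytest.approx(np.var(y), rel=0.10)

    def test_single_qtl_recovery(self):
        hits = 0
        for seed in range(5):
            cfg = SimulationConfig(
                n_individuals=300, n_snps=200, h2_additive=0.3, h2_dominance=0.0,
                n_qtl_additive=1, n_qtl_dominance=0, seed=100 + seed,
            )
            ds = simulate_dataset(cfg)
            qtl = int(ds.true_qtl_table["snp_index"].iloc[0])
            sign = np.sign(
                np.corrcoef(
                    ds.genotypes.dosages[:, qtl].astype(float),
                    ds.true_breeding_values,
                )[0, 1]
            )
            design = intercept_design(ds.phenotypes["trait"])
            d = build_designs(ds.genotypes)
            hyper = BayesADHyper(
                s_alpha2=derive_scale(0.3, ds.genotypes, 4.2),
                n_iterations=1200, burn_in=400, thinning=4, seed=seed,
            )
            s = run_chain(design, d, hyper, model="bayesA")
            if (
                int(np.argmax(np.abs(s.alpha_mean))) == qtl
                and np.sign(s.alpha_mean[qtl]) == sign
            ):
                hits += 1
        assert hits >= 4

    def test_conjugate_single_snp_posterior(self):
        """With nu huge the per-SNP variance is pinned at s_alpha2, so the
        alpha conditional is the closed-form Gaussian ridge posterior."""
        rng = np.random.default_rng(21)
        n = 400
        w_raw = rng.binomial(2, 0.5, n).astype(np.int8)
        g = geno_from(w_raw[:, None])
        d = build_designs(g)
        w = d.Wa[:, 0]
        sigma_e_true = 0.3
        y = 0.5 * w + sigma_e_true * rng.standard_normal(n)
        design = intercept_design(y)
        s_alpha2 = 0.25
        hyper = BayesADHyper(
            nu_alpha=1e10, s_alpha2=s_alpha2, n_iterations=4000, burn_in=1000,
            thinning=2, seed=5,
        )
        s = run_chain(design, d, hyper, model="bayesA", keep_draws=True)
        se2 = s.sigma_e2_mean
        prec = (w @ w) / se2 + 1.0 / s_alpha2
        mean = (w @ (y - y.mean()) / se2) / prec
        assert s.alpha_mean[0] == pytest.approx(mean, abs=4 * s.alpha_sd[0] / np.sqrt(s.n_draws) + 1e-3)
        assert s.alpha_sd[0] == pytest.approx(1 / np.sqrt(prec), rel=0.15)

    def test_prior_marginal_is_student_t_when_data_uninformative(self):
        """Drown the likelihood in noise: sampled alphas should follow the
        scaled-t implied by the normal/scaled-inverse-chi-square hierarchy."""
        rng = np.random.default_rng(31)
        n, m = 60, 25
        g = geno_from(rng.binomial(2, 0.5, size=(n, m)))
        y = 1e4 * rng.standard_normal(n)  # sigma_e2 ~ 1e8 >> prior effect scale
        design = intercept_design(y)
        d = build_designs(g)
        nu = 4.2
        hyper = BayesADHyper(
            nu_alpha=nu, s_alpha2=1.0, n_iterations=6000, burn_in=1000,
            thinning=5, seed=6,
        )
        s = run_chain(design, d, hyper, model="bayesA", keep_draws=True)
        draws = s.alpha_draws.ravel()
        ks = stats.kstest(draws, stats.t(df=nu).cdf)
        assert ks.pvalue > 0.01

    def test_bayesad_with_tiny_dominance_scale_matches_bayesa(self):
        cfg = SimulationConfig(
            n_individuals=250, n_snps=150, h2_additive=0.4, h2_dominance=0.0,
            n_qtl_additive=30, n_qtl_dominance=0, seed=8,
        )
        ds = simulate_dataset(cfg)
        design = intercept_design(ds.phenotypes["trait"])
        d = build_designs(ds.genotypes)
        base = dict(
            s_alpha2=derive_scale(0.4, ds.genotypes, 4.2),
            n_iterations=2000, burn_in=500, thinning=5, seed=3,
        )
        sa = run_chain(design, d, BayesADHyper(**base), model="bayesA")
        sad = run_chain(
            design, d, BayesADHyper(s_D=1e-6, mu_beta=0.0, **base), model="bayesAD"
        )
        assert np.max(np.abs(sad.beta_mean)) < 1e-4
        assert np.corrcoef(sa.alpha_mean, sad.alpha_mean)[0, 1] > 0.98

    def test_divergence_aborts(self):
        g = geno_from(np.tile([0, 1, 2, 1], (5, 1)).T.astype(np.int8)[:4])
        # absurd input: y with infinities triggers the divergence guard
        design = intercept_design([1.0, np.inf, 0.0, -1.0])
        d = build_designs(g)
        hyper = BayesADHyper(n_iterations=10, burn_in=2, thinning=1, seed=1)
        with pytest.raises((RuntimeError, ValueError)):
            run_chain(design, d, hyper, model="bayesA")


class TestPredictGeneticValues:
    def test_bayesa_total_equals_breeding(self):
        cfg = SimulationConfig(
            n_individuals=80, n_snps=50, h2_dominance=0.0,
            n_qtl_additive=10, n_qtl_dominance=0, seed=2
        )
        ds = simulate_dataset(cfg)
        design = intercept_design(ds.phenotypes["trait"])
        d = build_designs(ds.genotypes)
        hyper = BayesADHyper(n_iterations=300, burn_in=100, thinning=2, seed=4)
        s = run_chain(design, d, hyper, model="bayesA")
        bv, total = predict_genetic_values(s, d.Wa, d.Wb)
        assert np.array_equal(bv, total)

    def test_zero_effects_zero_predictions(self):
        from domgp.bayesad import MarkerEffectSamples, MarkerDesigns

        m, n = 5, 7
        Wa = np.ones((n, m))
        s = MarkerEffectSamples(
            alpha_mean=np.zeros(m), alpha_sd=np.zeros(m), beta_mean=np.zeros(m),
            beta_sd=np.zeros(m), b_mean=np.zeros(1), sigma_e2_mean=1.0,
            sigma_e2_draws=np.ones(2), acceptance_rate=1.0, n_draws=2, model="bayesA",
        )
        bv, total = predict_genetic_values(s, Wa)
        assert np.all(bv == 0) and np.all(total == 0)

    def test_near_noiseless_training_fit(self):
        cfg = SimulationConfig(
            n_individuals=200, n_snps=100, h2_additive=0.95, h2_dominance=0.0,
            n_qtl_additive=20, n_qtl_dominance=0, seed=6,
        )
        ds = simulate_dataset(cfg)
        from domgp import build_trait_design

        design = build_trait_design(ds.phenotypes)  # fixed effects modeled
        d = build_designs(ds.genotypes)
        hyper = BayesADHyper(
            s_alpha2=derive_scale(0.95, ds.genotypes, 4.2),
            n_iterations=2000, burn_in=500, thinning=5, seed=7,
        )
        s = run_chain(design, d, hyper, model="bayesA")
        bv, _ = predict_genetic_values(s, d.Wa, d.Wb)
        assert np.corrcoef(bv, ds.true_breeding_values)[0, 1] > 0.95

    def test_dimension_mismatch_rejected(self):
        from domgp.bayesad import MarkerEffectSamples

        s = MarkerEffectSamples(
            alpha_mean=np.zeros(3), alpha_sd=np.zeros(3), beta_mean=np.zeros(3),
            beta_sd=np.zeros(3), b_mean=np.zeros(1), sigma_e2_mean=1.0,
            sigma_e2_draws=np.ones(2), acceptance_rate=1.0, n_draws=2, model="bayesA",
        )
        with pytest.raises(ValueError):
            predict_genetic_values(s, np.ones((4, 5)))
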