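"""Gibbs samplers against the exhaustive enumeration oracle, prior
equivalences, and the summary/individual-level equivalence."""

import numpy as np
import pytest

import blrfine as bf
from blrfine.assoc import LDMatrix


def make_instance(n, m, causal, b, ld_rho, seed):
    G = bf.simulate_genotypes(n, m, ld_rho=ld_rho, seed=seed)
    W = bf.scale_genotypes(G)
    rng = np.random.default_rng(seed + 1)
    y = np.zeros(n)
    for c, eff in zip(causal, b):
        y += W.W[:, c] * eff
    y += rng.normal(0, 1, n)
    y /= y.std()
    ss = bf.gwas_linear(W, y)
    B = bf.compute_ld(W)
    return W, y, ss, B


class TestEnumerationOracle:
    def test_no_signal_pip_below_prior(self):
        # a Bayes factor <= 1 cannot raise inclusion odds above the prior
        ss = _toy_ss(beta=[0.0], se=[0.01], n=10_000)
        B = LDMatrix(ids=ss.ids, values=np.eye(1))
        pip = bf.exact_posterior_oracle(ss, B, pi=0.1, sigma_b2=0.01, sigma_e2=1.0)
        assert pip[0] < 0.1

    def test_exchangeable_duplicates_have_equal_pips(self):
        ss = _toy_ss(beta=[0.03, 0.03], se=[0.01, 0.01], n=10_000)
        B = LDMatrix(ids=ss.ids, values=np.array([[1.0, 1.0], [1.0, 1.0]]))
        pip = bf.exact_posterior_oracle(ss, B, pi=0.05, sigma_b2=0.01, sigma_e2=1.0)
        assert pip[0] == pytest.approx(pip[1], abs=1e-12)

    def test_refuses_large_m(self):
        ss = _toy_ss(beta=[0.0] * 13, se=[0.01] * 13, n=1000)
        B = LDMatrix(ids=ss.ids, values=np.eye(13))
        with pytest.raises(ValueError, match="12"):
            bf.exact_posterior_oracle(ss, B, 0.1, 0.01, 1.0)


class TestGibbsVsOracle:
    def test_single_variant_strong_signal(self):
        # z ~ 10: PIP > 0.99 and within 0.02 of the two-model posterior
        W, y, ss, B = make_instance(10_000, 1, [0], [0.1], 0.0, seed=21)
        z = ss.beta[0] / ss.se[0]
        assert abs(z) > 6
        pi, sb2, se2 = 0.01, 0.01, 1.0
        # closed-form two-model posterior, written out independently
        n = float(ss.n[0])
        xty = n * ss.beta[0]
        C = n + se2 / sb2
        logbf = 0.5 * (np.log(se2) - np.log(sb2) - np.log(C)) + 0.5 * xty**2 / (se2 * C)
        post = pi * np.exp(logbf) / (pi * np.exp(logbf) + 1 - pi)
        fit = bf.fit_blr(ss, B, bf.BayesCPrior(pi=pi, fix_sigma_b2=sb2, fix_sigma_e2=se2),
                         bf.MCMCOptions(n_iter=12_000, n_burnin=2_000, seed=1))
        assert fit.pip[0] > 0.99
        assert fit.pip[0] == pytest.approx(post, abs=0.02)

    def test_pips_match_enumeration_with_ld(self):
        W, y, ss, B = make_instance(5_000, 6, [2], [0.08], 0.7, seed=22)
        pi, sb2, se2 = 0.1, 0.01, 1.0
        oracle = bf.exact_posterior_oracle(ss, B, pi, sb2, se2)
        fit = bf.fit_blr(ss, B, bf.BayesCPrior(pi=pi, fix_sigma_b2=sb2, fix_sigma_e2=se2),
                         bf.MCMCOptions(n_iter=22_000, n_burnin=2_000, seed=2))
        assert np.abs(fit.pip - oracle).max() < 0.02

    def test_perfectly_correlated_pair_splits_inclusion_mass(self):
        # duplicate column: joint inclusion mass matches enumeration,
        # individual PIPs approximately equal
        G = bf.simulate_genotypes(5_000, 1, seed=23)
        W1 = bf.scale_genotypes(G)
        X = np.hstack([W1.W, W1.W])
        W = bf.ScaledDesign(W=X, ids=np.array(["a", "b"], dtype=object),
                            chrom=np.array(["1", "1"], dtype=object),
                            positions=np.array([1, 2]),
                            freqs=np.array([G.freqs[0]] * 2))
        rng = np.random.default_rng(24)
        y = X[:, 0] * 0.08 + rng.normal(0, 1, 5000)
        y /= y.std()
        ss = bf.gwas_linear(W, y)
        B = bf.compute_ld(W)
        pi, sb2, se2 = 0.05, 0.01, 1.0
        oracle = bf.exact_posterior_oracle(ss, B, pi, sb2, se2)
        # label swapping between perfect duplicates mixes slowly; average
        # over independent random-scan chains for the symmetry check
        fit = bf.fit_blr(ss, B, bf.BayesCPrior(pi=pi, fix_sigma_b2=sb2, fix_sigma_e2=se2),
                         bf.MCMCOptions(n_iter=30_000, n_burnin=2_000, nrun=12, seed=3))
        assert fit.pip.sum() == pytest.approx(oracle.sum(), abs=0.03)
        assert fit.pip[0] == pytest.approx(fit.pip[1], abs=0.15)

    def test_degenerate_prior_all_null(self, small_design, ga1_sim):
        _, W = small_design
        ss = bf.gwas_linear(W, ga1_sim.y)
        B = bf.compute_ld(W)
        fit = bf.fit_blr(ss, B, bf.BayesCPrior(pi=0.0, estimate_pi=False),
                         bf.MCMCOptions(n_iter=500, n_burnin=100, seed=4))
        assert np.all(fit.pip == 0.0)
        assert np.all(fit.b_mean == 0.0)


class TestPriorEquivalences:
    def test_bayesr_two_class_reproduces_bayesc(self):
        W, y, ss, B = make_instance(3_000, 8, [3], [0.1], 0.5, seed=25)
        opts = bf.MCMCOptions(n_iter=15_000, n_burnin=2_000, seed=5)
        fc = bf.fit_blr(ss, B, bf.BayesCPrior(pi=0.05), opts)
        fr = bf.fit_blr(ss, B, bf.BayesRPrior(gamma=(0.0, 1.0), pi=(0.95, 0.05),
                                              alpha=(1.0, 1.0)), opts)
        assert np.abs(fc.pip - fr.pip).max() < 0.02

    def test_bayesr_prior_vector_renormalized(self):
        prior = bf.BayesRPrior()
        _, pi, _ = prior.mixture()
        assert pi.sum() == pytest.approx(1.0)
        assert prior.pi_raw == (0.99, 0.06, 0.03, 0.01)
        assert pi[0] == pytest.approx(0.99 / 1.09)

    def test_bayesr_validation(self):
        with pytest.raises(ValueError, match="null"):
            bf.BayesRPrior(gamma=(0.1, 1.0), pi=(0.5, 0.5), alpha=(1, 1))


class TestGenomeWide:
    def test_banded_covering_band_equals_dense(self):
        W, y, ss, B = make_instance(3_000, 10, [4], [0.1], 0.6, seed=26)
        opts = bf.MCMCOptions(n_iter=20_000, n_burnin=2_000, seed=6)
        dense = bf.fit_blr(ss, B, bf.BayesCPrior(pi=0.05), opts)
        Bb = bf.compute_ld(W, half_bandwidth=10)
        banded = bf.fit_blr_genomewide(ss, Bb, bf.BayesCPrior(pi=0.05), opts)
        assert np.abs(dense.pip - banded.pip).max() < 0.05

    def test_all_null_pips_stay_low(self):
        G = bf.simulate_genotypes(4_000, 1000, ld_rho=0.5, seed=27)
        W = bf.scale_genotypes(G)
        y = np.random.default_rng(28).normal(size=4_000)
        y /= y.std()
        ss = bf.gwas_linear(W, y)
        Bb = bf.compute_ld(W, half_bandwidth=40)
        # spike-and-slab prior: the slab variance is identified, so null data
        # cannot inflate inclusion (the BayesR near-null variance class is
        # weakly identified on pure noise -- see the methods note)
        fit = bf.fit_blr_genomewide(ss, Bb, bf.BayesCPrior(estimate_pi=True),
                                    bf.MCMCOptions(n_iter=3_000, n_burnin=500, seed=7))
        assert fit.pip.max() < 0.2

    def test_chain_length_stability(self):
        W, y, ss, B = make_instance(3_000, 10, [4], [0.1], 0.6, seed=29)
        Bb = bf.compute_ld(W, half_bandwidth=10)
        prior = bf.BayesRPrior(estimate_pi=True)
        a = bf.fit_blr_genomewide(ss, Bb, prior,
                                  bf.MCMCOptions(n_iter=8_000, n_burnin=1_000, seed=8))
        b = bf.fit_blr_genomewide(ss, Bb, prior,
                                  bf.MCMCOptions(n_iter=16_000, n_burnin=1_000, seed=9))
        assert np.abs(a.pip - b.pip).max() < 0.05

    def test_scope_mismatch_errors_and_band_warning(self, small_design, ga1_sim):
        _, W = small_design
        ss = bf.gwas_linear(W, ga1_sim.y)
        dense = bf.compute_ld(W)
        banded = bf.compute_ld(W, half_bandwidth=5)
        with pytest.raises(ValueError, match="dense"):
            bf.fit_blr(ss, banded, bf.BayesCPrior())
        with pytest.raises(ValueError, match="banded"):
            bf.fit_blr_genomewide(ss, dense, bf.BayesCPrior())
        with pytest.warns(UserWarning, match="bandwidth"):
            bf.fit_blr_genomewide(ss, banded, bf.BayesCPrior(pi=0.0),
                                  bf.MCMCOptions(n_iter=200, n_burnin=50, seed=1),
                                  region_extent=20)


class TestSummaryVsIndividual:
    def test_summary_fit_matches_individual_fit(self):
        W, y, ss, B = make_instance(2_000, 50, [10, 30], [0.1, 0.08], 0.6, seed=30)
        opts = bf.MCMCOptions(n_iter=15_000, n_burnin=2_000, seed=10)
        prior = bf.BayesRPrior(estimate_pi=True)
        summ = bf.fit_blr(ss, B, prior, opts)
        indiv = bf.fit_blr_individual(W, y, prior, opts)
        assert np.abs(summ.pip - indiv.pip).max() < 0.02


class TestOptionsAndOutputs:
    def test_mcmc_options_validation(self):
        with pytest.raises(ValueError):
            bf.MCMCOptions(n_iter=100, n_burnin=100)
        with pytest.raises(ValueError):
            bf.MCMCOptions(nrun=0)

    def test_pip_is_nonnull_class_frequency(self, small_design, ga1_sim):
        _, W = small_design
        ss = bf.gwas_linear(W, ga1_sim.y)
        B = bf.compute_ld(W)
        fit = bf.fit_blr(ss, B, bf.BayesRPrior(estimate_pi=True),
                         bf.MCMCOptions(n_iter=2_000, n_burnin=500, seed=11))
        assert np.all((fit.pip >= 0) & (fit.pip <= 1))
        assert np.allclose(fit.pip, fit.class_freq[:, 1:].sum(axis=1), atol=1e-12)
        assert len(fit.chains["sigma_b2"]) == fit.n_kept

    def test_multirun_averages_and_reports_runs(self, small_design, ga1_sim):
        _, W = small_design
        ss = bf.gwas_linear(W, ga1_sim.y)
        B = bf.compute_ld(W)
        fit = bf.fit_blr(ss, B, bf.BayesCPrior(pi=0.05),
                         bf.MCMCOptions(n_iter=1_000, n_burnin=200, nrun=3, seed=12))
        assert len(fit.runs) == 3
        stacked = np.mean([r["pip"] for r in fit.runs], axis=0)
        assert np.allclose(fit.pip, stacked)


def _toy_ss(beta, se, n):
    m = len(beta)
    return bf.SummaryStats(
        ids=np.array([f"v{i}" for i in range(m)], dtype=object),
        chrom=np.array(["1"] * m, dtype=object),
        pos=np.arange(1, m + 1), a1=np.array(["A"] * m, dtype=object),
        a2=np.array(["G"] * m, dtype=object), freq=np.full(m, 0.3),
        beta=np.array(beta, dtype=float), se=np.array(se, dtype=float),
        n=np.full(m, float(n)), p=np.full(m, 0.5))
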