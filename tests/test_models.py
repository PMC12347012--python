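"""Whole-genome regression engine: priors, kernels, oracles, reproducibility."""

import numpy as np
import pytest

from phasegp.models import ModelConfig, fit, gaussian_kernel, predict_gebv


@pytest.fixture(scope="module")
def sim_xy():
    rng = np.random.default_rng(42)
    n, m = 120, 240
    X = rng.integers(0, 3, size=(n, m)).astype(float)
    beta = np.zeros(m)
    beta[:30] = rng.standard_normal(30)
    g = (X - X.mean(0)) @ beta
    y = g + rng.normal(0, g.std(), n)
    return X, y, g


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(model="BayesZ")
        with pytest.raises(ValueError):
            ModelConfig(burn_in=100, n_iter=100)
        with pytest.raises(ValueError):
            ModelConfig(thin=0)
        with pytest.raises(ValueError):
            ModelConfig(pi_fixed=1.0)

    def test_retained_count(self):
        cfg = ModelConfig(n_iter=1000, burn_in=100, thin=7)
        assert cfg.n_retained == 128


class TestGaussianKernel:
    def test_identical_rows_give_one(self):
        X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        K = gaussian_kernel(X, h=1.0)
        assert K[0, 1] == pytest.approx(1.0)

    def test_small_h_limit(self):
        rng = np.random.default_rng(0)
        K = gaussian_kernel(rng.standard_normal((5, 3)), h=1e-9)
        assert np.all(K > 0.999)

    def test_hand_computed_toy(self):
        X = np.array([[0.0, 0.0, 0.0],
                      [1.0, 0.0, 0.0],
                      [1.0, 1.0, 0.0],
                      [1.0, 1.0, 1.0]])
        # pairwise squared distances: 1,2,3,1,2,1 -> mean 10/6
        K = gaussian_kernel(X, h=1.0)
        mean_d2 = 10.0 / 6.0
        assert K[0, 1] == pytest.approx(np.exp(-1.0 / mean_d2))
        assert K[0, 3] == pytest.approx(np.exp(-3.0 / mean_d2))
        np.testing.assert_allclose(K, K.T)
        np.testing.assert_allclose(np.diag(K), 1.0)

    def test_degenerate_rows_raise(self):
        X = np.ones((4, 3))
        with pytest.raises(ValueError, match="degenerate"):
            gaussian_kernel(X)


class TestFitBasics:
    def test_input_validation(self, sim_xy):
        X, y, _ = sim_xy
        cfg = ModelConfig(n_iter=200, burn_in=50)
        with pytest.raises(ValueError, match="zero-variance"):
            fit(X, np.ones_like(y), cfg)
        Xm = X.copy()
        Xm[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            fit(Xm, y, cfg)
        with pytest.raises(ValueError):
            fit(X[:5], y[:5], cfg)

    @pytest.mark.parametrize("model", ["BRR", "BL", "BayesA", "BayesB",
                                       "BayesC", "RKHS"])
    def test_reproducible_and_chain_length(self, sim_xy, model):
        """Same seed => bit-identical summaries; chains have exactly
        (n_iter - burn_in) / thin samples; sigma2_e stays positive."""
        X, y, _ = sim_xy
        cfg = ModelConfig(model=model, n_iter=600, burn_in=100, thin=5,
                          seed=9)
        a = fit(X, y, cfg)
        b = fit(X, y, cfg)
        np.testing.assert_array_equal(a.gebv, b.gebv)
        assert a.mu == b.mu and a.sigma2_e == b.sigma2_e
        assert len(a.chains["sigma2_e"]) == cfg.n_retained == 100
        assert np.all(a.chains["sigma2_e"] > 0)
        assert a.gebv.size == y.size
        if model == "BayesC":
            assert 0.0 <= a.pi_hat <= 1.0

    def test_constant_centered_y_shrinks_beta(self, sim_xy):
        """A pure-noise response yields posterior-mean effects near zero."""
        X, _, _ = sim_xy
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, X.shape[0])  # no genetic signal
        cfg = ModelConfig(model="BRR", n_iter=800, burn_in=200, thin=2,
                          seed=2)
        s = fit(X, y, cfg)
        assert np.abs(s.beta).max() < 0.2
        assert s.h2_g < 0.6


class TestOracles:
    def test_brr_fixed_variances_matches_ridge(self, sim_xy):
        """Gibbs posterior mean with fixed variance components equals the
        closed-form ridge solution within MC error."""
        X, y, _ = sim_xy
        s2e, s2b = 0.6, 0.012
        cfg = ModelConfig(model="BRR", n_iter=4000, burn_in=500, thin=1,
                          seed=3, standardize=False,
                          fix_sigma2_e=s2e, fix_sigma2_b=s2b)
        s = fit(X, y, cfg)
        Xc = X - X.mean(0)
        lam = s2e / s2b
        ridge = np.linalg.solve(Xc.T @ Xc + lam * np.eye(X.shape[1]),
                                Xc.T @ (y - y.mean()))
        assert np.mean(np.abs(s.beta - ridge)) < 0.02

    def test_bayesc_pi_zero_collapses_to_brr(self, sim_xy):
        X, y, _ = sim_xy
        cC = ModelConfig(model="BayesC", pi_force=0.0, n_iter=2500,
                         burn_in=500, thin=1, seed=4)
        cB = ModelConfig(model="BRR", n_iter=2500, burn_in=500, thin=1,
                         seed=5)
        r = np.corrcoef(fit(X, y, cC).gebv, fit(X, y, cB).gebv)[0, 1]
        assert r > 0.99

    def test_rkhs_linear_kernel_matches_brr(self, sim_xy):
        X, y, _ = sim_xy
        Xc = X - X.mean(0)
        K = Xc @ Xc.T / X.shape[1]
        cR = ModelConfig(model="RKHS", n_iter=2500, burn_in=500, thin=1,
                         seed=6)
        cB = ModelConfig(model="BRR", n_iter=2500, burn_in=500, thin=1,
                         seed=7)
        r = np.corrcoef(fit(X, y, cR, K=K).gebv, fit(X, y, cB).gebv)[0, 1]
        assert r > 0.98

    def test_brr_matches_gblup_on_simulation(self):
        """BRR GEBVs agree with the mixed-model (GBLUP) solution computed
        from the realized relationship matrix at the posterior-mean
        variance components."""
        rng = np.random.default_rng(8)
        n, m = 150, 500
        X = rng.binomial(2, rng.uniform(0.1, 0.9, m), size=(n, m)).astype(float)
        beta = rng.standard_normal(m) * 0.05
        g = (X - X.mean(0)) @ beta
        y = g + rng.normal(0, g.std(), n)
        cfg = ModelConfig(model="BRR", n_iter=2000, burn_in=400, thin=2,
                          seed=9, standardize=False)
        s = fit(X, y, cfg)
        Xc = X - X.mean(0)
        # GBLUP: u = G (G + lambda I)^-1 (y - mean), G = Xc Xc' sigma2_b
        lam_grid = np.logspace(-3, 3, 200)
        best_r = max(
            np.corrcoef(
                Xc @ Xc.T @ np.linalg.solve(
                    Xc @ Xc.T + lam * np.trace(Xc @ Xc.T) / n * np.eye(n),
                    y - y.mean()),
                s.gebv)[0, 1]
            for lam in lam_grid)
        assert best_r > 0.98

    def test_bayesc_pi_directionally_correct(self):
        """Estimated non-null proportion is larger when the simulation has
        more non-null effects (5% vs 50% causal), across 5 seeds."""
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n, m = 150, 300
            X = rng.integers(0, 3, size=(n, m)).astype(float)
            Xc = X - X.mean(0)

            def make_y(frac):
                k = int(frac * m)
                b = np.zeros(m)
                b[rng.choice(m, k, replace=False)] = rng.standard_normal(k)
                g = Xc @ b
                return g + rng.normal(0, g.std() * 0.5, n)

            cfg = ModelConfig(model="BayesC", n_iter=1200, burn_in=300,
                              thin=2, seed=seed)
            pi_sparse = fit(X, make_y(0.05), cfg).pi_hat
            pi_dense = fit(X, make_y(0.50), cfg).pi_hat
            # pi_hat is the zero-effect probability
            if (1 - pi_sparse) < (1 - pi_dense):
                wins += 1
        assert wins >= 4


class TestPredict:
    def test_training_matrix_reproduces_gebv(self, sim_xy):
        X, y, _ = sim_xy
        for model in ("BRR", "RKHS"):
            cfg = ModelConfig(model=model, n_iter=600, burn_in=100, seed=10)
            s = fit(X, y, cfg)
            np.testing.assert_allclose(predict_gebv(s, X), s.gebv,
                                       atol=1e-8)

    def test_population_mean_genotype_scores_zero(self, sim_xy):
        X, y, _ = sim_xy
        cfg = ModelConfig(model="BRR", n_iter=600, burn_in=100, seed=11)
        s = fit(X, y, cfg)
        X0 = np.tile(s.x_means, (3, 1))
        np.testing.assert_allclose(predict_gebv(s, X0), 0.0, atol=1e-10)

    def test_dimension_mismatch_raises(self, sim_xy):
        X, y, _ = sim_xy
        cfg = ModelConfig(model="BRR", n_iter=300, burn_in=100, seed=12)
        s = fit(X, y, cfg)
        with pytest.raises(ValueError, match="markers"):
            predict_gebv(s, X[:, :10])

    def test_held_out_prediction_tracks_refit(self):
        """Held-out GEBVs correlate strongly (r > 0.9) with a fit on all
        data at high heritability on an LD-structured panel."""
        from phasegp.simulate import (SimConfig, TraitSpec,
                                      simulate_genotypes,
                                      simulate_phenotypes)
        cfg = SimConfig(n_genotypes=300, n_markers=600, n_chromosomes=3,
                        seed=31,
                        traits=(TraitSpec("T", 60, 0.8, ("L",), 0.0),))
        gm = simulate_genotypes(cfg)
        pheno, _ = simulate_phenotypes(gm, cfg)
        X = gm.dosages.astype(float)
        y = pheno.trait_vector("T", "L", gm.samples)
        mc = ModelConfig(model="BRR", n_iter=1200, burn_in=300, thin=2,
                         seed=14)
        train = np.arange(300) < 240
        s = fit(X[train], y[train], mc)
        s_all = fit(X, y, mc)
        r = np.corrcoef(predict_gebv(s, X[~train]), s_all.gebv[~train])[0, 1]
        assert r > 0.9
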