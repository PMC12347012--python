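"""Reproduction experiments: self-contained routines that exercise the
package end-to-end on synthetic panels and against independent oracles
(closed-form ridge, exact rank-test enumerations, model collapses).

Each routine generates its own inputs from a seed, runs the package's
public API, and returns plain numbers, so the same code backs both the
test suite and the results-reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .data import MISSING
from .evaluate import cross_validate
from .impute import impute, mode_impute
from .models import ModelConfig, fit
from .chip import rank_markers
from .simulate import SimConfig, TraitSpec, simulate_genotypes, simulate_phenotypes
from .stats import kruskal_wallis, mann_whitney_u

__all__ = [
    "ridge_oracle_gap",
    "bayesc_collapse_r",
    "rkhs_linear_kernel_r",
    "h2_recovery",
    "full_vs_causal_subset",
    "chip_retention",
    "imputation_gain",
    "kruskal_permutation_gap",
    "mannwhitney_exact_gap",
    "mse_train_test_gap",
]


def _toy_panel(seed: int, n: int = 100, m: int = 200):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 3, size=(n, m)).astype(float)
    beta = np.zeros(m)
    beta[: m // 10] = rng.standard_normal(m // 10)
    g = (X - X.mean(0)) @ beta
    y = g + rng.normal(0, g.std(), n)
    return X, y


def _sim_trait(seed: int, n: int, m: int, n_qtl: int, h2: float,
               n_chromosomes: int = 11):
    cfg = SimConfig(
        n_genotypes=n, n_markers=m, n_chromosomes=n_chromosomes, seed=seed,
        traits=(TraitSpec("T", n_qtl, h2, ("L",), 0.0),))
    geno = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotypes(geno, cfg)
    X = geno.dosages.astype(float)
    y = pheno.trait_vector("T", "L", geno.samples)
    return geno, X, y, truth


def ridge_oracle_gap(seed: int, n: int = 100, m: int = 200,
                     n_iter: int = 5000, burn_in: int = 500) -> float:
    """Mean |difference| between fixed-variance BRR posterior-mean effects
    and the closed-form ridge solution beta = (X'X + lam I)^-1 X'(y - ybar)
    with lam = sigma2_e / sigma2_beta."""
    X, y = _toy_panel(seed, n, m)
    s2e, s2b = 0.6, 0.012
    cfg = ModelConfig(model="BRR", n_iter=n_iter, burn_in=burn_in, thin=1,
                      seed=seed, standardize=False,
                      fix_sigma2_e=s2e, fix_sigma2_b=s2b)
    summ = fit(X, y, cfg)
    Xc = X - X.mean(0)
    ridge = np.linalg.solve(Xc.T @ Xc + (s2e / s2b) * np.eye(m),
                            Xc.T @ (y - y.mean()))
    return float(np.mean(np.abs(summ.beta - ridge)))


def bayesc_collapse_r(seed: int, n: int = 100, m: int = 200,
                      n_iter: int = 2500, burn_in: int = 500) -> float:
    """GEBV correlation between BayesC with the zero-effect probability
    forced to 0 and Bayesian ridge on the same data."""
    X, y = _toy_panel(seed, n, m)
    cC = ModelConfig(model="BayesC", pi_force=0.0, n_iter=n_iter,
                     burn_in=burn_in, thin=1, seed=seed)
    cB = ModelConfig(model="BRR", n_iter=n_iter, burn_in=burn_in, thin=1,
                     seed=seed + 1)
    return float(np.corrcoef(fit(X, y, cC).gebv, fit(X, y, cB).gebv)[0, 1])


def rkhs_linear_kernel_r(seed: int, n: int = 100, m: int = 200,
                         n_iter: int = 2500, burn_in: int = 500) -> float:
    """GEBV correlation between RKHS under the linear kernel K = XX'/m and
    Bayesian ridge."""
    X, y = _toy_panel(seed, n, m)
    Xc = X - X.mean(0)
    cR = ModelConfig(model="RKHS", n_iter=n_iter, burn_in=burn_in, thin=1,
                     seed=seed)
    cB = ModelConfig(model="BRR", n_iter=n_iter, burn_in=burn_in, thin=1,
                     seed=seed + 1)
    return float(np.corrcoef(fit(X, y, cR, K=Xc @ Xc.T / m).gebv,
                             fit(X, y, cB).gebv)[0, 1])


def h2_recovery(h2: float, seeds: range | list[int], n: int = 300,
                m: int = 2000, n_qtl: int = 300, n_iter: int = 3000,
                burn_in: int = 500) -> float:
    """Mean estimated genomic heritability (BayesC) on simulated traits of
    known heritability."""
    ests = []
    for seed in seeds:
        _, X, y, _ = _sim_trait(int(seed), n, m, n_qtl, h2)
        cfg = ModelConfig(model="BayesC", n_iter=n_iter, burn_in=burn_in,
                          thin=5, seed=int(seed))
        ests.append(fit(X, y, cfg).h2_g)
    return float(np.mean(ests))


def full_vs_causal_subset(seeds: range | list[int], n: int = 300,
                          m: int = 2000, n_qtl: int = 500,
                          subset_size: int = 50, h2: float = 0.5,
                          n_iter: int = 1500, burn_in: int = 300
                          ) -> tuple[float, float]:
    """Mean (over seeds) of five-fold CV median prediction ability using
    all markers vs a random subset of the causal loci (an emulated
    GWAS-associated marker list)."""
    full, sub = [], []
    for seed in seeds:
        seed = int(seed)
        _, X, y, truth = _sim_trait(seed, n, m, n_qtl, h2)
        rng = np.random.default_rng(seed)
        pick = np.sort(rng.choice(truth.qtl[("L", "T")], subset_size,
                                  replace=False))
        cfg = ModelConfig(model="BayesC", n_iter=n_iter, burn_in=burn_in,
                          thin=5, seed=seed)
        full.append(cross_validate(X, y, cfg, seed=seed).r_y_median)
        sub.append(cross_validate(X, y, cfg, seed=seed,
                                  marker_subset=pick).r_y_median)
    return float(np.mean(full)), float(np.mean(sub))


def chip_retention(seeds: range | list[int], n: int = 300, m: int = 5000,
                   n_qtl: int = 800, h2: float = 0.6, panel_size: int = 500,
                   n_iter: int = 1500, burn_in: int = 300
                   ) -> tuple[float, float, float]:
    """Mean CV prediction ability of the full marker set and of the
    beta-ranked panel of ``panel_size`` markers; returns (full, panel,
    panel/full)."""
    r_full, r_panel = [], []
    for seed in seeds:
        seed = int(seed)
        _, X, y, _ = _sim_trait(seed, n, m, n_qtl, h2)
        cfg = ModelConfig(model="BayesC", n_iter=n_iter, burn_in=burn_in,
                          thin=5, seed=seed)
        order = np.asarray(rank_markers(fit(X, y, cfg)), dtype=np.intp)
        r_full.append(
            cross_validate(X, y, cfg, seed=seed).folds["r_y"].mean())
        r_panel.append(
            cross_validate(X, y, cfg, seed=seed,
                           marker_subset=np.sort(order[:panel_size]))
            .folds["r_y"].mean())
    full = float(np.mean(r_full))
    panel = float(np.mean(r_panel))
    return full, panel, panel / full


def imputation_gain(seeds: range | list[int], n: int = 100, m: int = 600,
                    mask_rate: float = 0.10) -> tuple[float, float, float]:
    """Masked-entry accuracy of LD-kNN imputation vs marker-mode imputation
    on LD-block panels; returns (ld_acc, mode_acc, gain)."""
    acc_ld, acc_mode = [], []
    for seed in seeds:
        seed = int(seed)
        cfg = SimConfig(n_genotypes=n, n_markers=m, n_chromosomes=3,
                        missing_rate=0.0, seed=seed)
        truth = simulate_genotypes(cfg)
        g = truth.copy()
        rng = np.random.default_rng(seed + 10_000)
        mask = rng.random(g.shape) < mask_rate
        g.dosages[mask] = MISSING
        acc_ld.append(
            (impute(g).dosages[mask] == truth.dosages[mask]).mean())
        acc_mode.append(
            (mode_impute(g).dosages[mask] == truth.dosages[mask]).mean())
    ld, mode = float(np.mean(acc_ld)), float(np.mean(acc_mode))
    return ld, mode, ld - mode


def kruskal_permutation_gap(seed: int, n_per_group: int = 5,
                            n_perm: int = 10_000) -> float:
    """|chi-square p - permutation p| for a 3-group Kruskal-Wallis test."""
    rng = np.random.default_rng(seed)
    groups = [rng.normal(0, 1, n_per_group),
              rng.normal(0.5, 1, n_per_group),
              rng.normal(1.0, 1, n_per_group)]
    H_obs, p_chi2 = kruskal_wallis(groups)
    pooled = np.concatenate(groups)
    k = n_per_group
    rng2 = np.random.default_rng(seed + 1)
    count = 0
    for _ in range(n_perm):
        perm = rng2.permutation(pooled)
        H, _ = kruskal_wallis([perm[:k], perm[k:2 * k], perm[2 * k:]])
        if H >= H_obs - 1e-12:
            count += 1
    return abs(p_chi2 - count / n_perm)


def mannwhitney_exact_gap(seed: int, n_per_group: int = 8) -> float:
    """|asymptotic p - exact-enumeration p| for a two-sample rank test."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, n_per_group)
    b = rng.normal(0.8, 1, n_per_group)
    _, p_asym = mann_whitney_u(a, b)
    p_exact = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="exact").pvalue
    return abs(p_asym - float(p_exact))


def mse_train_test_gap(seeds: range | list[int], n: int = 120, m: int = 400,
                       n_qtl: int = 40, h2: float = 0.6, n_iter: int = 800,
                       burn_in: int = 200) -> float:
    """Mean over synthetic CV runs of (mse_train - mse_test); negative when
    training folds fit better than held-out folds, as expected."""
    gaps = []
    for seed in seeds:
        seed = int(seed)
        _, X, y, _ = _sim_trait(seed, n, m, n_qtl, h2, n_chromosomes=2)
        for model in ("BRR", "BayesC"):
            cfg = ModelConfig(model=model, n_iter=n_iter, burn_in=burn_in,
                              thin=2, seed=seed)
            res = cross_validate(X, y, cfg, seed=seed)
            gaps.append(res.folds["mse_train"].mean()
                        - res.folds["mse_test"].mean())
    return float(np.mean(gaps))
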