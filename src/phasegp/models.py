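"""Whole-genome regression by Gibbs sampling: the Bayesian alphabet
(BayesA/B/C), Bayesian LASSO, Bayesian ridge, and Gaussian-kernel RKHS.

All models share the linear model

    y = mu * 1 + X beta + eps,        eps ~ N(0, sigma2_e I)

and differ only in the prior on the marker effects beta:

======  =====================================================================
BRR     common Gaussian variance, scaled-inv-chi^2 hyperprior
BL      double-exponential via exponential mixing of per-marker variances,
        Gamma-distributed lambda^2 (Park & Casella parameterization)
BayesA  per-marker variances with scaled-inv-chi^2 prior (scaled-t marginal);
        every marker has a non-zero effect (pi = 0)
BayesB  point mass at zero + per-marker-variance slab, zero-effect
        probability pi fixed by the user
BayesC  point mass at zero + common slab variance, pi estimated under a
        uniform Beta prior
RKHS    genetic values u ~ N(0, sigma2_u K) fitted through the
        eigendecomposition of the kernel matrix K
======  =====================================================================

Hyperprior scales are resolved from ``prior_r2`` against var(y) following
the conventions of the standard Bayesian-regression software in this field
(degrees of freedom 5, scale set so the prior mode of the explained-variance
share equals ``prior_r2``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from ._samplers import update_effects_gaussian, update_effects_spike_slab

__all__ = [
    "MODELS",
    "ModelConfig",
    "PosteriorSummary",
    "fit",
    "gaussian_kernel",
    "predict_gebv",
]

MODELS = ("BRR", "BL", "BayesA", "BayesB", "BayesC", "RKHS")
ModelName = Literal["BRR", "BL", "BayesA", "BayesB", "BayesC", "RKHS"]


@dataclass
class ModelConfig:
    """MCMC and prior settings for one whole-genome regression fit.

    Attributes
    ----------
    model
        One of :data:`MODELS`.
    n_iter, burn_in, thin
        Gibbs sweeps, discarded warm-up sweeps, and thinning interval;
        exactly ``(n_iter - burn_in) // thin`` draws are retained.
    prior_r2
        Prior share of phenotypic variance attributed to markers; sets the
        hyperprior scales.
    df_prior
        Degrees of freedom of the scaled-inv-chi^2 variance hyperpriors.
    pi_fixed
        BayesB only: fixed prior probability that a marker has **zero**
        effect.
    pi_force
        BayesC only: when set, hold the zero-effect probability fixed at
        this value instead of estimating it (``pi_force=0`` collapses
        BayesC onto Bayesian ridge).
    kernel_h
        RKHS only: Gaussian-kernel bandwidth.
    standardize
        Z-score the response before fitting (posterior summaries are on the
        standardized scale; ``y_mean``/``y_sd`` are stored for reference).
    fix_sigma2_e, fix_sigma2_b
        Freeze variance components at the given values (used for oracle
        comparisons against closed-form ridge).
    """

    model: ModelName = "BayesC"
    n_iter: int = 10_000
    burn_in: int = 1_000
    thin: int = 5
    seed: int = 0
    prior_r2: float = 0.5
    df_prior: float = 5.0
    pi_fixed: float = 0.9
    pi_force: float | None = None
    kernel_h: float = 1.0
    standardize: bool = True
    fix_sigma2_e: float | None = None
    fix_sigma2_b: float | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0.0 < self.pi_fixed < 1.0:
            raise ValueError("pi_fixed must be in (0, 1)")
        if self.pi_force is not None and not 0.0 <= self.pi_force < 1.0:
            raise ValueError("pi_force must be in [0, 1)")
        if self.kernel_h <= 0:
            raise ValueError("kernel_h must be positive")
        if not 0.0 < self.prior_r2 < 1.0:
            raise ValueError("prior_r2 must be in (0, 1)")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorSummary:
    """Posterior means from one fit, plus scalar chains for diagnostics."""

    model: str
    mu: float
    sigma2_e: float
    sigma2_a: float
    gebv: np.ndarray
    beta: np.ndarray | None = None          # marker models
    u: np.ndarray | None = None             # RKHS
    pi_hat: float | None = None             # BayesB/C: P(effect == 0)
    chains: dict = field(default_factory=dict)
    x_means: np.ndarray | None = None       # training allele means (centering)
    y_mean: float = 0.0
    y_sd: float = 1.0
    config: ModelConfig | None = None
    _rkhs: dict | None = None               # internals for kernel prediction

    @property
    def h2_g(self) -> float:
        """Genomic heritability sigma2_a / (sigma2_a + sigma2_e)."""
        return self.sigma2_a / (self.sigma2_a + self.sigma2_e)


def _validate(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError(f"X is {X.shape}, y has length {y.size}")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 training samples")
    if not np.isfinite(X).all():
        raise ValueError("X contains missing or non-finite entries; impute first")
    if not np.isfinite(y).all():
        raise ValueError("y contains non-finite values")
    if np.var(y) == 0:
        raise ValueError("zero-variance response")
    return X, y


def gaussian_kernel(X: np.ndarray, h: float = 1.0) -> np.ndarray:
    """Gaussian kernel K_ij = exp(-h * d2_ij / mean(d2)) on genotype rows.

    ``d2`` is the squared Euclidean distance between rows of ``X`` (which
    should be column-standardized); the normalization by the mean
    off-diagonal squared distance makes ``h`` scale-free.  K_ii = 1.
    """
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    X = np.asarray(X, dtype=float)
    sq = (X * X).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.clip(d2, 0.0, None, out=d2)
    n = X.shape[0]
    off = d2[~np.eye(n, dtype=bool)]
    mean_d2 = off.mean() if off.size else 0.0
    if mean_d2 <= 0:
        raise ValueError("degenerate kernel: all genotype rows identical")
    K = np.exp(-h * d2 / mean_d2)
    np.fill_diagonal(K, 1.0)
    return K


def _scaled_inv_chi2(rng: np.random.Generator, df: float, S: float) -> float:
    """Draw sigma2 = S / chi2_df (BGLR-style scale-absorbing convention)."""
    return S / rng.chisquare(df)


def fit(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig,
    K: np.ndarray | None = None,
) -> PosteriorSummary:
    """Fit one whole-genome regression model by Gibbs sampling.

    Parameters
    ----------
    X
        ``(n, m)`` dosage matrix without missing entries.  Columns are
        centered internally; the training allele means are stored in the
        summary for later centering of prediction sets.
    y
        Length-``n`` phenotype vector (genotype means for one trait x
        locality).
    config
        Model, chain and prior settings.
    K
        Optional precomputed ``(n, n)`` kernel matrix (RKHS only); when
        absent the Gaussian kernel with bandwidth ``config.kernel_h`` is
        built from the column-standardized genotypes.

    Returns
    -------
    PosteriorSummary
        Posterior means of all parameters, GEBVs and scalar chains.
    """
    X, y = _validate(X, y)
    rng = np.random.default_rng(config.seed)

    y_mean, y_sd = float(np.mean(y)), float(np.std(y))
    if config.standardize:
        y_work = (y - y_mean) / y_sd
    else:
        y_work = y.copy()
    vy = float(np.var(y_work))
    n = y_work.size

    x_means = X.mean(axis=0)
    if config.model == "RKHS":
        return _fit_rkhs(X, y_work, config, rng, vy, K, x_means, y_mean, y_sd)

    Xc = np.asfortranarray(X - x_means)
    m = Xc.shape[1]
    x2 = (Xc * Xc).sum(axis=0)
    ms_x = float(np.sum(np.var(Xc, axis=0)))
    if ms_x <= 0:
        raise ValueError("all marker columns are constant")

    df0 = config.df_prior
    R2 = config.prior_r2
    S_e = vy * (1.0 - R2) * (df0 + 2.0)
    sigma2_e = (config.fix_sigma2_e if config.fix_sigma2_e is not None
                else vy * (1.0 - R2))

    model = config.model
    beta = np.zeros(m)
    e = y_work - y_work.mean()
    mu = float(y_work.mean())
    delta = np.ones(m, dtype=np.int64)

    # model-specific state
    if model == "BRR":
        S_b = vy * R2 / ms_x * (df0 + 2.0)
        sigma2_b = (config.fix_sigma2_b if config.fix_sigma2_b is not None
                    else vy * R2 / ms_x)
    elif model == "BayesA":
        S_b = vy * R2 / ms_x * (df0 + 2.0)
        marker_var = np.full(m, vy * R2 / ms_x)
    elif model == "BayesB":
        p_in = 1.0 - config.pi_fixed
        S_b = vy * R2 / (p_in * ms_x) * (df0 + 2.0)
        marker_var = np.full(m, vy * R2 / (p_in * ms_x))
        logit_in = float(np.log(p_in / config.pi_fixed))
    elif model == "BayesC":
        if config.pi_force is not None:
            p_in = min(max(1.0 - config.pi_force, 1e-6), 1.0 - 1e-6)
        else:
            p_in = 0.5  # prior mean inclusion under Beta(1, 1)
        S_b = vy * R2 / (p_in * ms_x) * (df0 + 2.0)
        sigma2_b = vy * R2 / (p_in * ms_x)
    elif model == "BL":
        lam2_0 = 2.0 * (1.0 - R2) / R2 * ms_x
        lam_shape = 1.1
        lam_rate = (lam_shape - 1.0) / lam2_0  # prior mode at lam2_0
        lam2 = lam2_0
        tau2 = np.full(m, R2 * vy / (ms_x * max(sigma2_e, 1e-12)))

    n_ret = config.n_retained
    beta_acc = np.zeros(m)
    gebv_acc = np.zeros(n)
    chain_mu = np.empty(n_ret)
    chain_se = np.empty(n_ret)
    chain_sa = np.empty(n_ret)
    chain_pi = np.empty(n_ret) if model in ("BayesB", "BayesC") else None
    kept = 0

    for it in range(1, config.n_iter + 1):
        # --- intercept (flat prior) ---
        mu_new = rng.normal(mu + e.mean(), np.sqrt(sigma2_e / n))
        e -= mu_new - mu
        mu = float(mu_new)

        # --- marker effects ---
        z = rng.standard_normal(m)
        if model == "BRR":
            update_effects_gaussian(Xc, e, beta, x2,
                                    np.full(m, sigma2_b), sigma2_e, z)
            if config.fix_sigma2_b is None:
                sigma2_b = _scaled_inv_chi2(
                    rng, df0 + m, S_b + float(beta @ beta))
        elif model == "BayesA":
            update_effects_gaussian(Xc, e, beta, x2, marker_var, sigma2_e, z)
            marker_var = (S_b + beta * beta) / rng.chisquare(df0 + 1.0, m)
        elif model == "BayesB":
            u_unif = rng.random(m)
            update_effects_spike_slab(Xc, e, beta, delta, x2, marker_var,
                                      sigma2_e, logit_in, z, u_unif)
            marker_var = (S_b + beta * beta) / rng.chisquare(df0 + delta, m)
        elif model == "BayesC":
            u_unif = rng.random(m)
            logit_in = float(np.log(p_in / (1.0 - p_in)))
            update_effects_spike_slab(Xc, e, beta, delta, x2,
                                      np.full(m, sigma2_b), sigma2_e,
                                      logit_in, z, u_unif)
            m_in = int(delta.sum())
            sigma2_b = _scaled_inv_chi2(
                rng, df0 + m_in, S_b + float(beta @ beta))
            if config.pi_force is None:
                p_in = float(rng.beta(1.0 + m_in, 1.0 + m - m_in))
                p_in = min(max(p_in, 1e-6), 1.0 - 1e-6)
        elif model == "BL":
            prior_var = tau2 * sigma2_e
            update_effects_gaussian(Xc, e, beta, x2, prior_var, sigma2_e, z)
            b2 = np.maximum(beta * beta, 1e-12)
            inv_tau2 = rng.wald(np.sqrt(lam2 * sigma2_e / b2), lam2)
            tau2 = 1.0 / np.maximum(inv_tau2, 1e-12)
            lam2 = rng.gamma(lam_shape + m, 1.0 / (lam_rate + tau2.sum() / 2.0))

        # --- residual variance ---
        if config.fix_sigma2_e is None:
            sse = float(e @ e)
            if model == "BL":
                # beta | tau2, sigma2_e ~ N(0, tau2*sigma2_e) couples the scales
                sse += float(np.sum(beta * beta / np.maximum(tau2, 1e-12)))
                sigma2_e = _scaled_inv_chi2(rng, df0 + n + m, S_e + sse)
            else:
                sigma2_e = _scaled_inv_chi2(rng, df0 + n, S_e + sse)

        # --- retain ---
        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            g = y_work - mu - e  # equals Xc @ beta without an extra matmul
            beta_acc += beta
            gebv_acc += g
            chain_mu[kept] = mu
            chain_se[kept] = sigma2_e
            chain_sa[kept] = float(np.var(g, ddof=1))
            if chain_pi is not None:
                chain_pi[kept] = (config.pi_fixed if model == "BayesB"
                                  else 1.0 - p_in)
            kept += 1

    assert kept == n_ret
    beta_hat = beta_acc / n_ret
    chains = {"mu": chain_mu, "sigma2_e": chain_se, "sigma2_a": chain_sa}
    if chain_pi is not None:
        chains["pi_zero"] = chain_pi
    return PosteriorSummary(
        model=model,
        mu=float(chain_mu.mean()),
        sigma2_e=float(chain_se.mean()),
        sigma2_a=float(chain_sa.mean()),
        gebv=gebv_acc / n_ret,
        beta=beta_hat,
        pi_hat=float(chain_pi.mean()) if chain_pi is not None else None,
        chains=chains,
        x_means=x_means,
        y_mean=y_mean,
        y_sd=y_sd,
        config=config,
    )


def _fit_rkhs(
    X: np.ndarray,
    y_work: np.ndarray,
    config: ModelConfig,
    rng: np.random.Generator,
    vy: float,
    K: np.ndarray | None,
    x_means: np.ndarray,
    y_mean: float,
    y_sd: float,
) -> PosteriorSummary:
    n = y_work.size
    x_sd = X.std(axis=0)
    x_sd_safe = np.where(x_sd > 0, x_sd, 1.0)
    Xs = (X - x_means) / x_sd_safe
    if K is None:
        K = gaussian_kernel(Xs, config.kernel_h)
    else:
        K = np.asarray(K, dtype=float)
        if K.shape != (n, n):
            raise ValueError(f"kernel must be {n}x{n}, got {K.shape}")

    evals, evecs = np.linalg.eigh(K)
    keep = evals > 1e-10 * evals.max()
    d = evals[keep]
    V = np.asfortranarray(evecs[:, keep])
    q = d.size
    ones_q = np.ones(q)

    df0, R2 = config.df_prior, config.prior_r2
    S_e = vy * (1.0 - R2) * (df0 + 2.0)
    mean_diag = float(np.mean(np.diag(K)))
    S_u = vy * R2 / mean_diag * (df0 + 2.0)
    sigma2_e = vy * (1.0 - R2)
    sigma2_u = vy * R2 / mean_diag

    deltas = np.zeros(q)
    mu = float(y_work.mean())
    e = y_work - mu

    n_ret = config.n_retained
    u_acc = np.zeros(n)
    chain_mu = np.empty(n_ret)
    chain_se = np.empty(n_ret)
    chain_sa = np.empty(n_ret)
    chain_su = np.empty(n_ret)
    kept = 0

    for it in range(1, config.n_iter + 1):
        mu_new = rng.normal(mu + e.mean(), np.sqrt(sigma2_e / n))
        e -= mu_new - mu
        mu = float(mu_new)

        z = rng.standard_normal(q)
        update_effects_gaussian(V, e, deltas, ones_q, sigma2_u * d,
                                sigma2_e, z)
        sigma2_u = _scaled_inv_chi2(
            rng, df0 + q, S_u + float(np.sum(deltas * deltas / d)))
        sigma2_e = _scaled_inv_chi2(rng, df0 + n, S_e + float(e @ e))

        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            u = y_work - mu - e  # = V @ deltas
            u_acc += u
            chain_mu[kept] = mu
            chain_se[kept] = sigma2_e
            chain_sa[kept] = float(np.var(u, ddof=1))
            chain_su[kept] = sigma2_u
            kept += 1

    u_hat = u_acc / n_ret
    # K^{-1} u on the retained eigenspace, for kernel prediction at new rows
    alpha = V @ ((V.T @ u_hat) / d)
    return PosteriorSummary(
        model="RKHS",
        mu=float(chain_mu.mean()),
        sigma2_e=float(chain_se.mean()),
        sigma2_a=float(chain_sa.mean()),
        gebv=u_hat,
        u=u_hat,
        chains={"mu": chain_mu, "sigma2_e": chain_se,
                "sigma2_a": chain_sa, "sigma2_u": chain_su},
        x_means=x_means,
        y_mean=y_mean,
        y_sd=y_sd,
        config=config,
        _rkhs={"X_std": Xs, "x_sd": x_sd_safe, "alpha": alpha,
               "h": config.kernel_h,
               "mean_d2": _mean_offdiag_d2(Xs)},
    )


def _mean_offdiag_d2(Xs: np.ndarray) -> float:
    sq = (Xs * Xs).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * Xs @ Xs.T
    n = Xs.shape[0]
    return float(d2[~np.eye(n, dtype=bool)].mean())


def predict_gebv(summary: PosteriorSummary, X_new: np.ndarray) -> np.ndarray:
    """GEBVs for new genotypes under a fitted model.

    Marker models return ``(X_new - training allele means) @ beta``; RKHS
    interpolates the genetic values through the Gaussian kernel between new
    and training rows.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2:
        raise ValueError("X_new must be 2-D")
    if summary.model == "RKHS":
        info = summary._rkhs
        if info is None:
            raise ValueError("RKHS summary lacks prediction internals")
        if X_new.shape[1] != summary.x_means.size:
            raise ValueError(
                f"X_new has {X_new.shape[1]} markers, model used "
                f"{summary.x_means.size}")
        Xs_new = (X_new - summary.x_means) / info["x_sd"]
        Xt = info["X_std"]
        d2 = ((Xs_new * Xs_new).sum(axis=1)[:, None]
              + (Xt * Xt).sum(axis=1)[None, :] - 2.0 * Xs_new @ Xt.T)
        np.clip(d2, 0.0, None, out=d2)
        K_nt = np.exp(-info["h"] * d2 / info["mean_d2"])
        return K_nt @ info["alpha"]
    if summary.beta is None:
        raise ValueError(f"model {summary.model} has no marker effects")
    if X_new.shape[1] != summary.beta.size:
        raise ValueError(
            f"X_new has {X_new.shape[1]} markers, model has "
            f"{summary.beta.size} effects")
    return (X_new - summary.x_means) @ summary.beta
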