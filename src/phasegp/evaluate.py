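"""Cross-validation and evaluation statistics for genomic prediction.

Prediction ability is the Pearson correlation between observed phenotypes
and GEBVs on held-out folds; genomic heritability is the variance-component
ratio sigma2_a / (sigma2_a + sigma2_e); missing heritability quantifies the
relative shortfall of a marker subset's heritability versus the full set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import ModelConfig, PosteriorSummary, fit, predict_gebv

__all__ = [
    "CVResult",
    "cross_validate",
    "make_folds",
    "prediction_ability",
    "mean_squared_error",
    "genomic_heritability",
    "missing_heritability",
]


def prediction_ability(y_obs: np.ndarray, gebv: np.ndarray) -> float:
    """Pearson correlation between observed phenotypes and GEBVs."""
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    gebv = np.asarray(gebv, dtype=float).ravel()
    if y_obs.size != gebv.size:
        raise ValueError("length mismatch")
    if y_obs.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(y_obs) == 0 or np.std(gebv) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(sps.pearsonr(y_obs, gebv).statistic)


def mean_squared_error(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of squared residuals."""
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.size != y_pred.size:
        raise ValueError("length mismatch")
    d = y_obs - y_pred
    return float(np.mean(d * d))


def genomic_heritability(sigma2_a: float, sigma2_e: float) -> float:
    """h2_g = sigma2_a / (sigma2_a + sigma2_e)."""
    if sigma2_a < 0 or sigma2_e < 0:
        raise ValueError("variances must be non-negative")
    total = sigma2_a + sigma2_e
    if total == 0:
        raise ValueError("h2_g undefined: both variances are zero")
    return sigma2_a / total


def missing_heritability(h2_full: float, h2_subset: float) -> float:
    """Relative heritability shortfall (h2_full - h2_subset) / h2_full.

    Negative when the subset estimate exceeds the full-set estimate.
    """
    if h2_full <= 0:
        raise ValueError("missing heritability undefined for h2_full <= 0")
    return (h2_full - h2_subset) / h2_full


@dataclass
class CVResult:
    """Per-fold cross-validation records and their aggregates."""

    folds: pd.DataFrame  # fold, r_y, mse_train, mse_test, h2_g
    seed: int
    model: str
    summaries: list[PosteriorSummary] = field(default_factory=list)

    @property
    def r_y_median(self) -> float:
        return float(self.folds["r_y"].median())

    @property
    def r_y_sd(self) -> float:
        return float(self.folds["r_y"].std(ddof=1))

    @property
    def h2_g_mean(self) -> float:
        return float(self.folds["h2_g"].mean())

    @property
    def mse_test_mean(self) -> float:
        return float(self.folds["mse_test"].mean())


def make_folds(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random disjoint fold assignment; fold sizes differ by at most one."""
    assign = np.arange(n) % n_folds
    rng.shuffle(assign)
    return assign


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig,
    n_folds: int = 5,
    seed: int | None = None,
    in_sample: bool = False,
    marker_subset: np.ndarray | None = None,
    keep_summaries: bool = False,
) -> CVResult:
    """K-fold cross-validation of one model on one trait x locality.

    Samples are partitioned once into ``n_folds`` disjoint folds drawn from
    ``seed`` (defaulting to ``config.seed``); per fold the model is fitted
    on the remainder and evaluated on the held-out fold.  Responses are
    z-scored using training-fold statistics, so MSEs are on the
    standardized scale.  ``in_sample=True`` reports r_y on the training
    fold instead of the held-out fold.

    ``marker_subset`` restricts the design to the given column indices.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 2 * n_folds:
        raise ValueError(f"need n >= {2 * n_folds} samples for {n_folds} folds")
    if marker_subset is not None:
        X = X[:, np.asarray(marker_subset, dtype=np.intp)]
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    assign = make_folds(n, n_folds, rng)

    records = []
    summaries = []
    for fold in range(n_folds):
        test = assign == fold
        train = ~test
        y_tr = y[train]
        y_sd = np.std(y_tr)
        if y_sd == 0:
            records.append({"fold": fold, "r_y": np.nan, "mse_train": np.nan,
                            "mse_test": np.nan, "h2_g": np.nan})
            continue
        summ = fit(X[train], y_tr, config)
        # evaluation on the scale the model was fitted on
        y_tr_s = (y_tr - summ.y_mean) / summ.y_sd
        y_te_s = (y[test] - summ.y_mean) / summ.y_sd
        gebv_te = predict_gebv(summ, X[test])
        gebv_tr = summ.gebv
        if in_sample:
            r_y = prediction_ability(y_tr_s, gebv_tr)
        else:
            r_y = prediction_ability(y_te_s, gebv_te)
        records.append({
            "fold": fold,
            "r_y": r_y,
            "mse_train": mean_squared_error(y_tr_s, summ.mu + gebv_tr),
            "mse_test": mean_squared_error(y_te_s, summ.mu + gebv_te),
            "h2_g": genomic_heritability(summ.sigma2_a, summ.sigma2_e),
        })
        if keep_summaries:
            summaries.append(summ)
    return CVResult(folds=pd.DataFrame(records), seed=seed,
                    model=config.model, summaries=summaries)
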