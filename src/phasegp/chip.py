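"""Beta-ranked SNP-chip design: saturation curves, plateau selection and
panel-overlap reports.

Markers are ranked by the absolute posterior-mean effect |beta| from a
marker-effect model fit; nested subsets of increasing size are re-fitted
under cross-validation to trace how prediction ability saturates with panel
size, and the plateau point defines the chip.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .data import GenotypeMatrix
from .evaluate import cross_validate
from .models import ModelConfig, PosteriorSummary, fit

logger = logging.getLogger(__name__)

__all__ = [
    "ChipPanel",
    "SaturationCurve",
    "rank_markers",
    "saturation_curve",
    "select_plateau",
    "overlap_summary",
]

#: Panel-size grid used for the saturation analysis (clipped at m).
DEFAULT_GRID = (25, 50, 100, 200, 300, 400, 500, 1000, 5000, 10_000, 15_645)
DEFAULT_SEEDS = (0, 1234, 2023)
DEFAULT_PANEL_SIZE = 500


@dataclass
class ChipPanel:
    """An ordered marker panel with its |beta| scores."""

    trait: str
    locality: str
    markers: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.markers) != self.scores.size:
            raise ValueError("markers and scores length mismatch")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate markers in panel")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.markers)

    def head(self, size: int) -> "ChipPanel":
        return ChipPanel(self.trait, self.locality,
                         self.markers[:size], self.scores[:size])


@dataclass
class SaturationCurve:
    """Per-(size, seed, fold) prediction abilities over a panel-size grid."""

    grid: tuple[int, ...]
    records: pd.DataFrame  # size, seed, fold, r_y

    def __post_init__(self) -> None:
        grid = tuple(self.grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("grid must be strictly increasing")
        self.grid = grid

    def per_size(self) -> pd.DataFrame:
        """Mean/min/max r_y per subset size."""
        g = (self.records.groupby("size")["r_y"]
             .agg(["mean", "min", "max", "std"]).reset_index())
        return g.sort_values("size").reset_index(drop=True)


def rank_markers(summary: PosteriorSummary,
                 geno: GenotypeMatrix | None = None) -> list[int] | list[str]:
    """Marker order by descending |posterior-mean beta|.

    Ties are broken by genome order, i.e. by column index (columns are
    sorted by chromosome and position).  Returns column indices, or marker
    IDs when a :class:`GenotypeMatrix` is supplied.
    """
    if summary.beta is None:
        raise ValueError(
            f"model {summary.model} has no marker effects to rank")
    absb = np.abs(summary.beta)
    order = np.lexsort((np.arange(absb.size), -absb))
    if geno is None:
        return [int(j) for j in order]
    if geno.n_markers != absb.size:
        raise ValueError("genotype matrix does not match the fitted model")
    ids = geno.marker_ids
    return [ids[j] for j in order]


def make_panel(summary: PosteriorSummary, geno: GenotypeMatrix,
               trait: str, locality: str,
               size: int = DEFAULT_PANEL_SIZE) -> ChipPanel:
    """Build a chip panel of the top-``size`` markers by |beta|."""
    order = rank_markers(summary)
    chosen = order[:size]
    ids = geno.marker_ids
    return ChipPanel(trait, locality,
                     [ids[j] for j in chosen],
                     np.abs(summary.beta)[chosen])


def saturation_curve(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig,
    grid: tuple[int, ...] = DEFAULT_GRID,
    seeds: tuple[int, ...] = DEFAULT_SEEDS,
    n_folds: int = 5,
    rank_within_fold: bool = False,
) -> SaturationCurve:
    """Prediction ability as a function of beta-ranked panel size.

    Per seed, markers are ranked from one fit on the full data, then each
    grid size is evaluated by ``n_folds``-fold cross-validation on the
    top-sized nested subset (the fold partition is fixed within a seed).
    ``rank_within_fold=True`` re-ranks markers inside each training fold
    instead — the leakage-safe variant.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[1]
    grid = tuple(sorted({min(s, m) for s in grid}))
    if any(s > m for s in grid):
        warnings.warn("grid sizes above m clipped")
    records = []
    for seed in seeds:
        cfg = ModelConfig(**{**config.__dict__, "seed": int(seed)})
        if not rank_within_fold:
            order = np.asarray(rank_markers(fit(X, y, cfg)), dtype=np.intp)
        for size in grid:
            if rank_within_fold:
                cv = _cv_rank_within_fold(X, y, cfg, size, n_folds, seed)
            else:
                # sorted: only membership matters, and genome order keeps
                # the size = m point identical to a plain full-marker CV
                cv = cross_validate(X, y, cfg, n_folds=n_folds, seed=seed,
                                    marker_subset=np.sort(order[:size]))
            for _, row in cv.folds.iterrows():
                records.append({"size": size, "seed": seed,
                                "fold": int(row["fold"]),
                                "r_y": row["r_y"]})
    return SaturationCurve(grid=grid, records=pd.DataFrame(records))


def _cv_rank_within_fold(X, y, cfg, size, n_folds, seed):
    from .evaluate import (CVResult, genomic_heritability, make_folds,
                           mean_squared_error, prediction_ability)
    from .models import predict_gebv

    rng = np.random.default_rng(seed)
    assign = make_folds(y.size, n_folds, rng)
    records = []
    for fold_i in range(n_folds):
        test = assign == fold_i
        train = ~test
        rank_fit = fit(X[train], y[train], cfg)
        order = np.asarray(rank_markers(rank_fit), dtype=np.intp)[:size]
        summ = fit(X[train][:, order], y[train], cfg)
        y_te_s = (y[test] - summ.y_mean) / summ.y_sd
        gebv_te = predict_gebv(summ, X[test][:, order])
        records.append({
            "fold": fold_i,
            "r_y": prediction_ability(y_te_s, gebv_te),
            "mse_train": np.nan,
            "mse_test": mean_squared_error(y_te_s, summ.mu + gebv_te),
            "h2_g": genomic_heritability(summ.sigma2_a, summ.sigma2_e),
        })
    return CVResult(folds=pd.DataFrame(records), seed=seed, model=cfg.model)


def select_plateau(curve: SaturationCurve, delta: float = 0.02) -> int:
    """Smallest grid size whose mean r_y is within ``delta`` (relative) of
    the best mean r_y over the whole grid."""
    per = curve.per_size()
    if per.empty:
        raise ValueError("empty saturation curve")
    best = per["mean"].max()
    ok = per[per["mean"] >= (1.0 - delta) * best]
    return int(ok["size"].min())


def overlap_summary(panels: list[ChipPanel], group_by: str = "locality"
                    ) -> dict:
    """Set-algebra report over two or more chip panels.

    Returns union size, per-panel exclusive counts, the count/percentage of
    markers present in >= 2 panels (relative to the union), and pairwise
    intersection counts.  ``group_by`` only labels the report.
    """
    if len(panels) < 2:
        raise ValueError("need at least 2 panels")
    sets = [set(p.markers) for p in panels]
    names = [f"{p.trait}@{p.locality}" for p in panels]
    union: set = set().union(*sets)
    counts = {mk: sum(mk in s for s in sets) for mk in union}
    shared = sum(1 for c in counts.values() if c >= 2)
    exclusive = {
        name: sum(1 for mk in s if counts[mk] == 1)
        for name, s in zip(names, sets)
    }
    pairwise = {
        f"{names[i]} & {names[j]}": len(sets[i] & sets[j])
        for i, j in combinations(range(len(sets)), 2)
    }
    return {
        "group_by": group_by,
        "panels": names,
        "union_size": len(union),
        "exclusive_counts": exclusive,
        "shared_in_2plus": shared,
        "shared_in_2plus_pct": 100.0 * shared / len(union) if union else 0.0,
        "pairwise_intersections": pairwise,
        "in_all": sum(1 for c in counts.values() if c == len(sets)),
    }
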