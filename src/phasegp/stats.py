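"""Nonparametric group comparisons and trait descriptive statistics.

Kruskal-Wallis and Mann-Whitney go through scipy; the Dunn post-hoc test
(pairwise mean-rank z tests with tie correction and Bonferroni adjustment)
is implemented here since no installed package provides it.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "kruskal_wallis",
    "dunn_posthoc",
    "mann_whitney_u",
    "one_way_anova",
    "trait_correlations",
    "uniformity_index",
]


def _check_groups(groups: list[np.ndarray]) -> list[np.ndarray]:
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    return groups


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value."""
    groups = _check_groups(groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with normal approximation, continuity and
    tie correction."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classic one-way ANOVA F test (secondary to the rank tests)."""
    groups = _check_groups(groups)
    res = sps.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def dunn_posthoc(groups: list[np.ndarray], adjust: str = "bonferroni"
                 ) -> pd.DataFrame:
    """Dunn's post-hoc pairwise test on mean ranks after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with
    the tie term T = sum(t^3 - t) / (12 (N - 1)).  Two-sided normal
    p-values are Bonferroni-multiplied by the number of pairs (capped at
    1).  Returns a symmetric DataFrame of adjusted p-values (diagonal 1).
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError("adjust must be 'bonferroni' or 'none'")
    groups = _check_groups(groups)
    k = len(groups)
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + g.size].mean())
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (N - 1))
    base_var = N * (N + 1) / 12.0 - tie_term
    n_pairs = k * (k - 1) // 2
    factor = n_pairs if adjust == "bonferroni" else 1

    out = np.ones((k, k))
    for i, j in combinations(range(k), 2):
        se = np.sqrt(base_var * (1.0 / groups[i].size + 1.0 / groups[j].size))
        if se == 0:
            p = 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = min(2.0 * sps.norm.sf(abs(z)) * factor, 1.0)
        out[i, j] = out[j, i] = p
    labels = [f"group{i}" for i in range(k)]
    return pd.DataFrame(out, index=labels, columns=labels)


def trait_correlations(
    pheno: PhenotypeTable, method: str = "pearson"
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Per-locality trait x trait correlation matrices with Bonferroni p.

    Correlations are computed on genotype means (pairwise-complete
    genotypes); adjusted p = raw p x number of trait pairs, capped at 1.
    Returns ``{locality: (coef matrix, adjusted-p matrix)}``; undefined
    pairs (constant trait or < 3 shared genotypes) are NaN.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    corr_fn = sps.pearsonr if method == "pearson" else sps.spearmanr
    means = pheno.genotype_means()
    out = {}
    for loc, sub in means.groupby("locality"):
        wide = sub.pivot(index="genotype_id", columns="trait", values="value")
        traits = list(wide.columns)
        t = len(traits)
        n_pairs = t * (t - 1) // 2
        coef = pd.DataFrame(np.eye(t), index=traits, columns=traits)
        pval = pd.DataFrame(np.zeros((t, t)), index=traits, columns=traits)
        for a, b in combinations(traits, 2):
            pair = wide[[a, b]].dropna()
            if len(pair) < 3 or pair[a].nunique() < 2 or pair[b].nunique() < 2:
                coef.loc[a, b] = coef.loc[b, a] = np.nan
                pval.loc[a, b] = pval.loc[b, a] = np.nan
                continue
            res = corr_fn(pair[a], pair[b])
            coef.loc[a, b] = coef.loc[b, a] = float(res.statistic)
            padj = min(float(res.pvalue) * max(n_pairs, 1), 1.0)
            pval.loc[a, b] = pval.loc[b, a] = padj
        out[str(loc)] = (coef, pval)
    return out


def uniformity_index(pheno: PhenotypeTable) -> pd.DataFrame:
    """Mean/variance performance-uniformity index per genotype.

    For each (genotype, locality, trait) with >= 2 replicates, the index is
    the replicate mean divided by the sample variance (n-1 denominator);
    high values flag genotypes that perform well and uniformly.  Zero
    replicate variance yields an infinite index: the value is capped at the
    largest finite index in the table and flagged.
    """
    rec = pheno.records
    rows = []
    for (gid, loc, trait), grp in rec.groupby(
            ["genotype_id", "locality", "trait"]):
        vals = grp["value"].to_numpy()
        if vals.size < 2:
            raise ValueError(
                f"uniformity index needs >= 2 replicates for "
                f"({gid}, {loc}, {trait})")
        var = float(np.var(vals, ddof=1))
        mean = float(np.mean(vals))
        rows.append({"genotype_id": gid, "locality": loc, "trait": trait,
                     "mean": mean, "variance": var,
                     "index": mean / var if var > 0 else np.inf,
                     "flagged": var == 0})
    df = pd.DataFrame(rows)
    if df["flagged"].any():
        finite = df.loc[~df["flagged"], "index"]
        cap = float(finite.max()) if len(finite) else 0.0
        logger.warning(
            "uniformity_index: %d zero-variance genotypes capped at %.4g",
            int(df["flagged"].sum()), cap)
        df.loc[df["flagged"], "index"] = cap
    return df
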