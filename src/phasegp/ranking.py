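"""GEBV-based genotype ranking and recommendation-domain set algebra.

The top-k genotypes by GEBV per trait x locality are intersected across
localities (recommendation domains: narrow adaptation when a genotype is
elite in >= 2 localities, broad when elite everywhere) and across traits
(multi-trait elites within one locality).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RankingTable",
    "top_genotypes",
    "recommendation_domains",
    "multi_trait_elites",
]

DEFAULT_TOP_K = 10


@dataclass
class RankingTable:
    """Genotypes sorted by GEBV (descending) for one trait x locality."""

    trait: str
    locality: str
    genotype_ids: list[str]
    gebv: np.ndarray
    k: int = DEFAULT_TOP_K

    def __post_init__(self) -> None:
        self.gebv = np.asarray(self.gebv, dtype=float)
        if len(self.genotype_ids) != self.gebv.size:
            raise ValueError("genotype_ids and gebv length mismatch")
        order = top_genotypes(self.gebv, self.genotype_ids,
                              k=len(self.genotype_ids))
        lookup = dict(zip(self.genotype_ids, self.gebv))
        self.genotype_ids = order
        self.gebv = np.array([lookup[g] for g in order])

    @property
    def top_k(self) -> set[str]:
        return set(self.genotype_ids[: min(self.k, len(self.genotype_ids))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, len(self.genotype_ids) + 1),
            "genotype_id": self.genotype_ids,
            "gebv": self.gebv,
            "trait": self.trait,
            "locality": self.locality,
        })


def top_genotypes(gebv: np.ndarray, genotype_ids: list[str],
                  k: int = DEFAULT_TOP_K) -> list[str]:
    """IDs of the k genotypes with the largest GEBVs.

    Boundary ties are broken by genotype ID order (sorted ascending) with a
    logged warning.
    """
    gebv = np.asarray(gebv, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if gebv.size != len(genotype_ids):
        raise ValueError("gebv and genotype_ids length mismatch")
    k_eff = min(k, gebv.size)
    order = sorted(range(gebv.size),
                   key=lambda i: (-gebv[i], genotype_ids[i]))
    if k_eff < gebv.size and gebv[order[k_eff - 1]] == gebv[order[k_eff]]:
        logger.warning(
            "top_genotypes: GEBV tie at the k=%d boundary broken by ID order",
            k)
    return [genotype_ids[i] for i in order[:k_eff]]


def _check_shared(tables: list[RankingTable], attr: str) -> None:
    values = {getattr(t, attr) for t in tables}
    if len(values) != 1:
        raise ValueError(f"tables must share the same {attr}, got {values}")


def recommendation_domains(tables: list[RankingTable]) -> pd.DataFrame:
    """Group one trait's top-k genotypes by how many localities share them.

    Returns a frame with columns ``genotype_id, localities, n_localities,
    recommended`` (elite in >= 2 localities) and ``broad_adaptation``
    (elite in all localities).  Output order is deterministic and
    independent of the input table order.
    """
    if not tables:
        raise ValueError("no ranking tables given")
    _check_shared(tables, "trait")
    n_loc = len({t.locality for t in tables})
    if n_loc != len(tables):
        raise ValueError("duplicate locality among tables")
    membership: dict[str, set[str]] = {}
    for t in tables:
        for g in t.top_k:
            membership.setdefault(g, set()).add(t.locality)
    rows = [
        {
            "genotype_id": g,
            "localities": tuple(sorted(locs)),
            "n_localities": len(locs),
            "recommended": len(locs) >= 2,
            "broad_adaptation": len(locs) == n_loc,
        }
        for g, locs in membership.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["n_localities", "genotype_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return df


def multi_trait_elites(tables: list[RankingTable]) -> pd.DataFrame:
    """Rank one locality's genotypes by the number of traits where they are
    top-k.

    Returns ``genotype_id, traits, n_traits, elite`` where ``elite`` marks
    the genotypes with the maximal trait count.
    """
    if not tables:
        raise ValueError("no ranking tables given")
    _check_shared(tables, "locality")
    if len({t.trait for t in tables}) != len(tables):
        raise ValueError("duplicate trait among tables")
    membership: dict[str, set[str]] = {}
    for t in tables:
        for g in t.top_k:
            membership.setdefault(g, set()).add(t.trait)
    max_count = max(len(v) for v in membership.values())
    rows = [
        {
            "genotype_id": g,
            "traits": tuple(sorted(trs)),
            "n_traits": len(trs),
            "elite": len(trs) == max_count,
        }
        for g, trs in membership.items()
    ]
    return pd.DataFrame(rows).sort_values(
        ["n_traits", "genotype_id"], ascending=[False, True]
    ).reset_index(drop=True)
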