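"""Core containers: genotype dosage matrices and replicate-level phenotype tables.

Dosages are coded as the count of the alternate allele (0, 1, 2) with
:data:`MISSING` (= -1) marking unobserved genotypes.  Marker maps follow the
VCF convention of 1-based inclusive coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for an unobserved dosage entry.
MISSING: int = -1


@dataclass(frozen=True)
class MarkerInfo:
    """A biallelic SNP: identifier, map position and alleles."""

    marker_id: str
    chromosome: str
    position: int  # 1-based
    ref_allele: str = "A"
    alt_allele: str = "T"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(
                f"marker {self.marker_id}: position must be >= 1, got {self.position}"
            )


@dataclass
class GenotypeMatrix:
    """An n-samples x m-markers dosage matrix with its marker map.

    Attributes
    ----------
    samples
        Sample identifiers (rows).
    markers
        Per-column :class:`MarkerInfo`, sorted by (chromosome, position).
    dosages
        ``(n, m)`` integer array with entries in ``{0, 1, 2, MISSING}``.
    depth
        Optional ``(n, m)`` read-depth array; absent for plain dosage CSVs.
    """

    samples: list[str]
    markers: list[MarkerInfo]
    dosages: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        n, m = self.dosages.shape
        if n != len(self.samples):
            raise ValueError(f"{len(self.samples)} samples but {n} dosage rows")
        if m != len(self.markers):
            raise ValueError(f"{len(self.markers)} markers but {m} dosage columns")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        ids = [mk.marker_id for mk in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker IDs")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.dosages[~valid][0]
            raise ValueError(f"invalid dosage value {bad}; expected 0/1/2/{MISSING}")
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.dosages.shape:
                raise ValueError("depth layer shape does not match dosages")
            if (self.depth < 0).any():
                raise ValueError("negative read depth")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape

    @property
    def marker_ids(self) -> list[str]:
        return [mk.marker_id for mk in self.markers]

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([mk.chromosome for mk in self.markers])

    @property
    def positions(self) -> np.ndarray:
        return np.array([mk.position for mk in self.markers], dtype=np.int64)

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def is_sorted(self) -> bool:
        keys = [(mk.chromosome, mk.position) for mk in self.markers]
        return keys == sorted(keys)

    def sort_markers(self) -> "GenotypeMatrix":
        """Return a copy with markers sorted by (chromosome, position)."""
        order = sorted(range(self.n_markers),
                       key=lambda j: (self.markers[j].chromosome,
                                      self.markers[j].position))
        return self.take_markers(order)

    def take_markers(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=np.intp)
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=[self.markers[j] for j in index],
            dosages=self.dosages[:, index].copy(),
            depth=None if self.depth is None else self.depth[:, index].copy(),
        )

    def take_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=np.intp)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            markers=list(self.markers),
            dosages=self.dosages[index, :].copy(),
            depth=None if self.depth is None else self.depth[index, :].copy(),
        )

    def subset_by_marker_id(self, marker_ids: Iterable[str]) -> "GenotypeMatrix":
        wanted = list(marker_ids)
        pos = {mid: j for j, mid in enumerate(self.marker_ids)}
        missing = [mid for mid in wanted if mid not in pos]
        if missing:
            raise KeyError(f"markers not in matrix: {missing[:5]}")
        return self.take_markers([pos[mid] for mid in wanted])

    def to_float(self) -> np.ndarray:
        """Dosages as float with MISSING mapped to NaN."""
        out = self.dosages.astype(float)
        out[self.dosages == MISSING] = np.nan
        return out

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=list(self.markers),
            dosages=self.dosages.copy(),
            depth=None if self.depth is None else self.depth.copy(),
        )


PHENO_COLUMNS = ["genotype_id", "locality", "trait", "replicate", "value"]


@dataclass
class PhenotypeTable:
    """Replicate-level trait records from a multi-locality trial.

    The underlying frame has columns ``genotype_id, locality, trait,
    replicate, value``.  Genotype-level values (replicate means) are derived
    on demand via :meth:`genotype_means`.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        missing_cols = [c for c in PHENO_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"phenotype table missing columns {missing_cols}")
        df = df[PHENO_COLUMNS].copy()
        df["value"] = df["value"].astype(float)
        if not np.isfinite(df["value"]).all():
            raise ValueError("non-finite phenotype values")
        self.records = df.reset_index(drop=True)

    @property
    def traits(self) -> list[str]:
        return sorted(self.records["trait"].unique())

    @property
    def localities(self) -> list[str]:
        return sorted(self.records["locality"].unique())

    @property
    def genotype_ids(self) -> list[str]:
        return sorted(self.records["genotype_id"].unique())

    def genotype_means(self) -> pd.DataFrame:
        """Average replicates per (genotype, locality, trait).

        Returns a frame with columns ``genotype_id, locality, trait, value,
        n_reps``; exactly one row per combination.
        """
        g = (
            self.records.groupby(["genotype_id", "locality", "trait"], sort=True)[
                "value"
            ]
            .agg(value="mean", n_reps="count")
            .reset_index()
        )
        return g

    def trait_vector(
        self, trait: str, locality: str, sample_order: Sequence[str]
    ) -> np.ndarray:
        """Genotype-mean values for one trait x locality, aligned to samples.

        Raises if any requested sample lacks a value.
        """
        means = self.genotype_means()
        sub = means[(means["trait"] == trait) & (means["locality"] == locality)]
        lookup = dict(zip(sub["genotype_id"], sub["value"]))
        absent = [s for s in sample_order if s not in lookup]
        if absent:
            raise KeyError(
                f"no phenotype for {trait}@{locality}: samples {absent[:5]}"
            )
        return np.array([lookup[s] for s in sample_order], dtype=float)

    def check_against(self, geno: GenotypeMatrix) -> None:
        """Validate that every phenotyped genotype is in the genotype matrix."""
        unknown = set(self.records["genotype_id"]) - set(geno.samples)
        if unknown:
            raise ValueError(
                f"phenotype genotypes absent from genotype matrix: {sorted(unknown)[:5]}"
            )
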