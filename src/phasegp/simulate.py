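"""Synthetic genotype/phenotype generator emulating an admixed GBS panel.

Genotypes are built from two ancestral allele-frequency pools (a
Balding-Nichols-style divergence model): each chromosome is tiled with LD
blocks, each block carries a small number of founder haplotypes per pool,
and every individual haplotype copies one founder per block (with a small
mutation rate), its pool chosen by the individual's admixture proportion.
Block copying yields the strong within-block LD that the LD-kNN imputer
and the beta-ranking analyses rely on.

Phenotypes follow the additive model y = mu + X beta + eps per locality x
trait, with locality-specific QTL sets whose pairwise sharing fraction is
controlled, and replicate-level plot noise on top of the genotype-level
residual.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix, MarkerInfo, PhenotypeTable
from .io import write_genotypes, write_phenotypes

__all__ = [
    "SimConfig",
    "TraitSpec",
    "GroundTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "export_fixture",
    "default_traits",
]

#: Localities of the emulated trial (two dry, one humid).
LOCALITIES = ("CarmenDeBolivar", "Motilonia", "Turipana")
TRAITS = ("YLP", "NP", "NS", "SB", "VB")


@dataclass(frozen=True)
class TraitSpec:
    """Architecture of one simulated trait.

    ``qtl_share`` is the pairwise fraction of QTL common to every locality;
    the remainder are locality-exclusive, mirroring locality-dependent
    polygenic adaptation.
    """

    name: str
    n_qtl: int = 300
    h2: float = 0.5
    localities: tuple[str, ...] = LOCALITIES
    qtl_share: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if not 0.0 <= self.qtl_share <= 1.0:
            raise ValueError("qtl_share must be in [0, 1]")


def default_traits(n_qtl: int = 300, h2: float = 0.5,
                   qtl_share: float = 0.1) -> tuple[TraitSpec, ...]:
    """The five yield/biomass traits; the two biomass traits are scored in
    the two dry localities only, as in the emulated trial."""
    return (
        TraitSpec("YLP", n_qtl, h2, LOCALITIES, qtl_share),
        TraitSpec("NP", n_qtl, h2, LOCALITIES, qtl_share),
        TraitSpec("NS", n_qtl, h2, LOCALITIES, qtl_share),
        TraitSpec("SB", n_qtl, h2, ("CarmenDeBolivar", "Motilonia"), qtl_share),
        TraitSpec("VB", n_qtl, h2, ("CarmenDeBolivar", "Motilonia"), qtl_share),
    )


@dataclass
class SimConfig:
    """Panel and trait-architecture settings for the generator."""

    n_genotypes: int = 87
    n_markers: int = 2000
    n_chromosomes: int = 11
    ld_block_len: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    n_pools: int = 2
    n_founders: int = 4          # founder haplotypes per pool per block
    mutation_rate: float = 0.01  # per-site copy error off the founder
    divergence: float = 0.2      # Balding-Nichols F between pools
    traits: tuple[TraitSpec, ...] = field(default_factory=default_traits)
    n_reps: int = 3
    seed: int = 0
    marker_spacing: int = 50_000  # bp between adjacent markers

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range bounds must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for t in self.traits:
            if t.n_qtl > self.n_markers:
                raise ValueError(
                    f"trait {t.name}: n_qtl {t.n_qtl} exceeds n_markers")


@dataclass
class GroundTruth:
    """Generative truth: per-(locality, trait) effects, GEBVs and QTL maps."""

    beta: dict[tuple[str, str], np.ndarray]
    gebv: dict[tuple[str, str], np.ndarray]
    realized_h2: dict[tuple[str, str], float]
    qtl: dict[tuple[str, str], np.ndarray]
    shared_qtl: dict[str, np.ndarray]
    sigma2_e: dict[tuple[str, str], float]


def _block_slices(cfg: SimConfig) -> list[tuple[int, int, int]]:
    """(chromosome index, start, stop) column ranges of the LD blocks."""
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_markers // cfg.n_chromosomes)
    per_chrom[: cfg.n_markers % cfg.n_chromosomes] += 1
    out = []
    start = 0
    for c, count in enumerate(per_chrom):
        pos = start
        while pos < start + count:
            stop = min(pos + cfg.ld_block_len, start + count)
            out.append((c, pos, stop))
            pos = stop
        start += count
    return out


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw an admixed, LD-structured dosage matrix.

    Realized per-marker MAF is enforced inside ``config.maf_range`` by
    redrawing (and, as a last resort, balancing) founder alleles of
    violating markers; missing entries are then masked uniformly at
    ``config.missing_rate``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genotypes
    lo, hi = cfg.maf_range

    # marker map
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_markers // cfg.n_chromosomes)
    per_chrom[: cfg.n_markers % cfg.n_chromosomes] += 1
    markers = []
    for c, count in enumerate(per_chrom, start=1):
        for i in range(count):
            pos = (i + 1) * cfg.marker_spacing
            markers.append(MarkerInfo(f"S{c}_{pos}", str(c), pos, "A", "T"))

    admixture = rng.beta(2.0, 2.0, size=n)
    F = cfg.divergence
    dosages = np.empty((n, cfg.n_markers), dtype=np.int16)

    for _, start, stop in _block_slices(cfg):
        blk = stop - start
        # pool allele frequencies around a common ancestral frequency
        p_anc = rng.uniform(0.15, 0.85, size=blk)
        # shared founder base keeps the number of distinct block haplotypes
        # small (strong within-block LD); pool-specific flips at a rate set
        # by the divergence parameter differentiate the ancestry pools
        base = (rng.random((cfg.n_founders, blk)) < p_anc).astype(np.int8)
        pool_flip = (rng.random((cfg.n_pools, cfg.n_founders, blk))
                     < 0.2 * F)
        founders = base[None, :, :] ^ pool_flip

        # per-haplotype pool and founder assignment (2 haplotypes/individual)
        pool_pick = (rng.random((n, 2)) < admixture[:, None]).astype(np.intp)
        founder_pick = rng.integers(cfg.n_founders, size=(n, 2))
        haps = founders[pool_pick, founder_pick, :]  # (n, 2, blk)
        flips = rng.random((n, 2, blk)) < cfg.mutation_rate
        haps = haps ^ flips
        block_dos = haps.sum(axis=1).astype(np.int16)

        # MAF enforcement per marker within the block
        freq = block_dos.mean(axis=0) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        bad = np.flatnonzero((maf < lo) | (maf > hi))
        for j in bad:
            ok = False
            for _try in range(50):
                fa = (rng.random((cfg.n_pools, cfg.n_founders))
                      < rng.uniform(max(lo * 2, 0.2), 0.8)).astype(np.int8)
                col = fa[pool_pick, founder_pick]
                col = col ^ (rng.random((n, 2)) < cfg.mutation_rate)
                d = col.sum(axis=1).astype(np.int16)
                f = d.mean() / 2.0
                if lo <= min(f, 1.0 - f) <= hi:
                    block_dos[:, j] = d
                    ok = True
                    break
            if not ok:
                # balanced founders guarantee an intermediate frequency
                fa = np.zeros((cfg.n_pools, cfg.n_founders), dtype=np.int8)
                fa[:, ::2] = 1
                d = fa[pool_pick, founder_pick].sum(axis=1).astype(np.int16)
                block_dos[:, j] = d
        dosages[:, start:stop] = block_dos

    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = MISSING

    samples = [f"G{i + 1}" for i in range(n)]
    return GenotypeMatrix(samples, markers, dosages)


def simulate_phenotypes(
    geno: GenotypeMatrix, config: SimConfig
) -> tuple[PhenotypeTable, GroundTruth]:
    """Draw locality-specific additive traits on a complete genotype matrix.

    Per trait, a fraction ``qtl_share`` of the QTL (with identical effects)
    is common to all of the trait's localities; the rest are
    locality-exclusive with independent effects.  The genotype-level
    residual variance is set so the generative heritability equals the
    trait's ``h2``; replicate plot noise has variance ``n_reps *
    sigma2_e`` so genotype means retain that heritability.
    """
    if geno.missing_mask().any():
        raise ValueError("genotype matrix has missing entries; impute first "
                         "or simulate with missing_rate=0")
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1)  # independent of genotype draw
    X = geno.dosages.astype(float)
    Xc = X - X.mean(axis=0)
    n, m = X.shape

    beta_d, gebv_d, h2_d, qtl_d, sig_d, shared_d = {}, {}, {}, {}, {}, {}
    records = []
    for spec in cfg.traits:
        locs = spec.localities
        n_shared = int(round(spec.qtl_share * spec.n_qtl))
        n_excl = spec.n_qtl - n_shared
        need = n_shared + n_excl * len(locs)
        if need > m:
            raise ValueError(
                f"trait {spec.name}: {need} distinct QTL needed but only "
                f"{m} markers available")
        chosen = rng.choice(m, size=need, replace=False)
        shared = np.sort(chosen[:n_shared])
        shared_d[spec.name] = shared
        shared_eff = rng.standard_normal(n_shared)
        for li, loc in enumerate(locs):
            excl = np.sort(chosen[n_shared + li * n_excl:
                                  n_shared + (li + 1) * n_excl])
            beta = np.zeros(m)
            beta[shared] = shared_eff
            beta[excl] = rng.standard_normal(n_excl)
            g = Xc @ beta
            var_g = float(np.var(g, ddof=1))
            h2_eff = max(spec.h2, 1e-6)
            sigma2_e = var_g * (1.0 - h2_eff) / h2_eff
            mu = 10.0
            plot_sd = np.sqrt(cfg.n_reps * sigma2_e)
            noise = rng.normal(0.0, plot_sd, size=(n, cfg.n_reps))
            for i, gid in enumerate(geno.samples):
                for r in range(cfg.n_reps):
                    records.append({
                        "genotype_id": gid, "locality": loc,
                        "trait": spec.name, "replicate": r + 1,
                        "value": mu + g[i] + noise[i, r],
                    })
            key = (loc, spec.name)
            beta_d[key] = beta
            gebv_d[key] = g
            h2_d[key] = var_g / (var_g + sigma2_e)
            qtl_d[key] = np.sort(np.concatenate([shared, excl]))
            sig_d[key] = sigma2_e

    pheno = PhenotypeTable(pd.DataFrame(records))
    truth = GroundTruth(beta=beta_d, gebv=gebv_d, realized_h2=h2_d,
                        qtl=qtl_d, shared_qtl=shared_d, sigma2_e=sig_d)
    return pheno, truth


def export_fixture(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    truth: GroundTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write VCF + phenotype CSV + ground-truth JSON; deterministic bytes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.vcf",
        "phenotypes": outdir / "phenotypes.csv",
        "truth": outdir / "truth.json",
    }
    write_genotypes(geno, paths["genotypes"], format="vcf")
    write_phenotypes(pheno, paths["phenotypes"])
    payload = {
        "traits": sorted({t for _, t in truth.beta}),
        "localities": sorted({l for l, _ in truth.beta}),
        "entries": [
            {
                "locality": loc,
                "trait": trait,
                "qtl_indices": truth.qtl[(loc, trait)].tolist(),
                "n_qtl": int(truth.qtl[(loc, trait)].size),
                "realized_h2": truth.realized_h2[(loc, trait)],
                "sigma2_e": truth.sigma2_e[(loc, trait)],
                "beta": truth.beta[(loc, trait)].tolist(),
                "gebv": truth.gebv[(loc, trait)].tolist(),
            }
            for (loc, trait) in sorted(truth.beta)
        ],
    }
    paths["truth"].write_text(json.dumps(payload))
    return paths
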