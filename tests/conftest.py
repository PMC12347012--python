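import numpy as np
import pandas as pd
import pytest

from phasegp.data import MISSING, GenotypeMatrix, MarkerInfo, PhenotypeTable
from phasegp.simulate import SimConfig, TraitSpec, simulate_genotypes, simulate_phenotypes


def make_matrix(dosages, chrom=None, pos=None, samples=None, depth=None):
    """Small GenotypeMatrix helper for hand-built fixtures."""
    dosages = np.asarray(dosages, dtype=np.int16)
    n, m = dosages.shape
    chrom = chrom or ["1"] * m
    pos = pos or [1000 * (j + 1) for j in range(m)]
    markers = [MarkerInfo(f"S{chrom[j]}_{pos[j]}", str(chrom[j]), int(pos[j]))
               for j in range(m)]
    samples = samples or [f"G{i + 1}" for i in range(n)]
    return GenotypeMatrix(samples, markers, dosages, depth=depth)


@pytest.fixture(scope="session")
def ld_panel():
    """Complete LD-structured panel (no missingness), 100 x 600."""
    cfg = SimConfig(n_genotypes=100, n_markers=600, n_chromosomes=3,
                    missing_rate=0.0, seed=11)
    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def trait_sim():
    """One simulated trait with ground truth (n=150, m=600, h2=0.6)."""
    cfg = SimConfig(
        n_genotypes=150, n_markers=600, n_chromosomes=3, missing_rate=0.0,
        seed=21,
        traits=(TraitSpec("YLP", n_qtl=60, h2=0.6, localities=("L1",),
                          qtl_share=0.0),),
    )
    geno = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotypes(geno, cfg)
    X = geno.dosages.astype(float)
    y = pheno.trait_vector("YLP", "L1", geno.samples)
    return geno, X, y, truth


@pytest.fixture()
def pheno_table():
    rows = []
    rng = np.random.default_rng(3)
    for gid in ("G1", "G2", "G3", "G4", "G5"):
        for loc in ("A", "B"):
            for trait in ("YLP", "NP"):
                base = rng.normal(10, 2)
                for rep in (1, 2, 3):
                    rows.append({"genotype_id": gid, "locality": loc,
                                 "trait": trait, "replicate": rep,
                                 "value": base + rng.normal(0, 0.5)})
    return PhenotypeTable(pd.DataFrame(rows))
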