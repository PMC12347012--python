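# phasegp

Multi-locality **genomic prediction** for interspecific bean panels
(*Phaseolus vulgaris* × *P. acutifolius*), built for breeding programs that
need to rank hybrid genotypes for locality-specific adaptation from
genotyping-by-sequencing (GBS) marker data and multi-environment field
trials.

The package covers the full analysis a genomic-selection study of this kind
runs:

- **IO & quality control** — VCF / HapMap / dosage-CSV genotype matrices;
  depth, missingness (≤ 20% per locus and per sample) and MAF (≥ 5%)
  filters.
- **LD-kNN imputation** — missing dosages filled from the modal genotype of
  the k nearest samples, with distances computed over the sites in highest
  linkage disequilibrium with the focal marker (defaults: k = 10, 30 LD
  sites, 10 Mb maximum distance).
- **Whole-genome regression** — six Bayesian/semiparametric models fitted
  by Gibbs sampling: Bayesian ridge (BRR), Bayesian LASSO (BL), BayesA,
  BayesB, BayesC and Gaussian-kernel RKHS, all under the linear model

  `y = μ1 + Xβ + ε,  ε ~ N(0, σ²ₑI)`

  differing only in the prior on the marker effects β (common Gaussian,
  double-exponential, per-marker variances, spike-and-slab with fixed or
  estimated π).
- **Evaluation** — five-fold cross-validated prediction ability
  `r_y = cor(y, GEBV)`, genomic heritability
  `h²g = σ²ₐ/(σ²ₐ+σ²ₑ)`, missing heritability
  `h²ₘ = (h²_G − h²_GWAS)/h²_G`, and MSE; Kruskal–Wallis, Dunn/Bonferroni
  and Mann–Whitney model comparisons.
- **SNP-chip design** — markers ranked by |β|, saturation curves over
  nested panel sizes, plateau selection (the 500-marker chip), and
  panel-overlap set algebra across traits and localities.
- **Genotype recommendation** — top-10 genotypes by GEBV per trait ×
  locality, with narrow/broad recommendation domains and multi-trait
  elites.
- **Synthetic panels** — an admixed, LD-block-structured generator with
  locality-specific polygenic architectures and known ground truth, so the
  whole pipeline is testable without any external download.

## Worked example

```python
import numpy as np
from phasegp import (SimConfig, TraitSpec, simulate_genotypes,
                     simulate_phenotypes, ModelConfig, cross_validate, fit,
                     top_genotypes)

cfg = SimConfig(
    n_genotypes=87, n_markers=2000, missing_rate=0.0, seed=42,
    traits=(TraitSpec("YLP", n_qtl=300, h2=0.6,
                      localities=("Motilonia",), qtl_share=0.0),),
)
geno = simulate_genotypes(cfg)
pheno, truth = simulate_phenotypes(geno, cfg)

X = geno.dosages.astype(float)
y = pheno.trait_vector("YLP", "Motilonia", geno.samples)

model = ModelConfig(model="BayesC", n_iter=3000, burn_in=500, seed=1234)
cv = cross_validate(X, y, model, n_folds=5, seed=1234)
print(f"median prediction ability r_y = {cv.r_y_median:.2f} "
      f"(+/- {cv.r_y_sd:.2f})")
print(f"mean genomic heritability h2_g = {cv.h2_g_mean:.2f}")
print(f"mean held-out MSE = {cv.mse_test_mean:.2f}")

summ = fit(X, y, model)
best = top_genotypes(summ.gebv, geno.samples, k=5)
print("top-5 genotypes by GEBV:", ", ".join(best))
```

Output:

```
median prediction ability r_y = 0.32 (+/- 0.23)
mean genomic heritability h2_g = 0.50
mean held-out MSE = 0.97
top-5 genotypes by GEBV: G22, G38, G62, G23, G13
```

The simulated trait has heritability 0.6 and 300 QTL; with only 87
genotypes the cross-validated prediction ability is modest (0.32) while the
genomic heritability estimate (0.50) tracks the generative value — exactly
the gap between variance captured and out-of-sample ranking accuracy that
motivates comparing models and optimizing marker panels before committing
to a breeding decision. MSEs are on the z-standardized trait scale.

The same analysis runs from the shell:

```bash
phasegp simulate --seed 42 --out fixtures/
phasegp filter --geno fixtures/genotypes.vcf --out filtered.vcf
phasegp impute --in filtered.vcf --out imputed.vcf
phasegp cv --geno imputed.vcf --pheno fixtures/phenotypes.csv \
           --trait YLP --locality Motilonia --model BayesC --out cv.tsv
phasegp run --config pipeline.yaml --out results/   # full pipeline
```

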