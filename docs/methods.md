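# Methods

## The model

All six regression models share the additive linear model

    y = μ·1ₙ + Xβ + ε,    ε ~ N(0, σ²ₑ Iₙ)

where `y` holds genotype-mean phenotypes for one trait in one locality, `X`
is the n×m dosage matrix (count of the alternate allele, columns centered
on the training allele means) and `β` the marker effects. The models differ
only in the prior on `β`:

| model  | prior on marker effects |
|--------|-------------------------|
| BRR    | βⱼ ~ N(0, σ²β), common variance with scaled-inv-χ² hyperprior |
| BL     | double-exponential via βⱼ ~ N(0, τ²ⱼσ²ₑ), τ²ⱼ ~ Exp(λ²/2), λ² ~ Gamma |
| BayesA | βⱼ ~ N(0, σ²ⱼ), per-marker scaled-inv-χ² variances (scaled-t marginal) |
| BayesB | point mass at 0 with probability π (fixed, default 0.9) + BayesA-style slab |
| BayesC | point mass at 0 + common slab variance; π estimated under Beta(1, 1) |
| RKHS   | genetic values u ~ N(0, σ²ᵤK), Gaussian kernel K |

Fitting is single-site Gibbs sampling (numba inner loops; all random
variates drawn from one seeded numpy Generator, so chains are
bit-reproducible). RKHS is sampled in the eigenbasis of K, where the
coordinates have independent conditionals. Defaults are 10,000 sweeps with
1,000 burn-in and thinning 5; the analyses below use shorter chains
(1,500–3,000 sweeps) after checking that the oracle agreements hold there.

**Hyperpriors.** Scaled-inverse-χ² variances use the scale-absorbing
convention σ² = S/χ²_df with df = 5. Scales are resolved from a prior
explained-variance share `prior_r2 = 0.5` against var(y):
S_e = var(y)(1−R²)(df+2), and for the effect variance
S_b = var(y)R²/MSx·(df+2) with MSx the summed column variances of the
centered design (BayesB and BayesC divide by the prior inclusion
probability). The Bayesian LASSO follows the Park–Casella Gibbs updates
with λ² ~ Gamma(1.1, rate set so the prior mode equals 2(1−R²)/R²·MSx).

**Kernel.** K_ij = exp(−h·d²ij / mean(d²)) on column-standardized
genotypes, with d² the squared Euclidean row distance and the mean taken
over off-diagonal pairs; the normalization makes the bandwidth h (default
1) scale-free. `fit(..., K=...)` accepts any precomputed PSD kernel, which
is how the linear-kernel equivalence with BRR is checked.

**Derived quantities.** GEBV = Xβ̂ (posterior-mean effects) for marker
models, û for RKHS. σ²ₐ is the sample variance (n−1) of Xβ across training
individuals per retained draw, averaged over draws; genomic heritability is
h²g = σ²ₐ/(σ²ₐ+σ²ₑ) at the posterior means. Missing heritability compares a
marker subset against the full set: h²ₘ = (h²_G − h²_GWAS)/h²_G (negative
when the subset estimate is larger).

**Response scaling.** Phenotypes are z-standardized per trait × locality
inside `fit` (a `standardize=False` flag fits on the raw scale). Prediction
ability is scale-invariant; MSEs are reported on the standardized scale.

## Cross-validation

Five folds, drawn once per seed with fold sizes differing by at most one;
per fold the model is refit on the remainder and r_y / MSE are evaluated on
the held-out fold (an `in_sample` flag reports the training-fold
correlation instead). Aggregates are the median and SD of r_y across folds.
Held-out RKHS predictions interpolate the genetic values through the
cross-kernel between new and training rows.

## Quality filters and imputation

Filters run in a fixed order — depth mask (< 3× set missing; skipped with a
warning when no depth layer exists, e.g. dosage CSVs) → marker missingness
(≤ 20%) → sample missingness (≤ 20%) → MAF (≥ 5%, folded to the minor
allele) — and a report counts removals per rule. The order is a package
choice; filtering is idempotent.

LD-kNN imputation scores donor samples by the mean squared dosage
difference over the focal marker's 30 highest-r² same-chromosome sites
within 10 Mb (pairwise-complete), takes the k = 10 nearest donors observed
at the focal marker, and fills with their modal dosage. All ties are fixed
(neighbor ties by sample order, mode ties toward the smaller dosage), so
the procedure is deterministic; a marker with no usable LD set falls back
to the marker mode with a warning. Distance-weighted voting is deliberately
omitted — the parameterization used here specifies only (k, l, max
distance).

## SNP-chip design and genotype recommendation

Markers are ranked by |posterior-mean β| (ties by genome order). The
saturation analysis re-fits nested top-s subsets under CV over a size grid
(default 25…15,645, clipped at m) for three seeds (0, 1234, 2023), with the
fold partition fixed within a seed. The β-ranking fit is done on the full
data before CV, matching the saturation analysis this package reproduces;
`rank_within_fold=True` gives the leakage-safe variant. The plateau is the
smallest size whose mean r_y is within δ = 2% of the best size's mean.
Panel overlap reports union size, per-panel exclusive counts and the
shared-in-≥2 percentage **relative to the union** — the convention that
makes the printed per-locality chip totals self-consistent.

Recommendation domains: per trait, the top-10 GEBV genotypes of each
locality are intersected; genotypes elite in ≥ 2 localities are recommended
(narrow adaptation), in all localities broadly adapted. Per locality,
multi-trait elites are ranked by the number of traits whose top-10 they
enter. k = 10 is the visual inflection-point heuristic of the original
analysis; it is a parameter here.

## The synthetic generator

The generator emulates an 87-genotype × 15,645-SNP admixed GBS panel at
test-friendly scale (default m = 2,000 over 11 chromosomes; the full-scale
configuration is available but not exercised by the test suite, which runs
at the sizes given below to stay within desktop budgets).

- **Genotypes.** Chromosomes are tiled with LD blocks (50 markers,
  ~50 kb spacing). Each block carries 4 founder haplotypes drawn from a
  common base (ancestral frequency U(0.15, 0.85)) and differentiated
  between two ancestry pools by flips at rate 0.2·F (F = 0.2,
  Balding–Nichols-style). Each individual haplotype copies one founder per
  block — pool chosen by the individual's Beta(2, 2) admixture proportion —
  with 1% per-site copy error. The small founder count produces the strong
  within-block LD that autogamous bean panels show; realized MAF is
  enforced into [0.05, 0.5]; missingness is masked uniformly (≤ 20%,
  matching the post-filter regime).
- **Phenotypes.** Per trait × locality, y = μ + Xβ + ε with a fraction
  `qtl_share` of QTL (identical effects) common to all localities and the
  rest locality-exclusive with independent N(0, 1) effects — locality
  adaptation is modeled through QTL sharing rather than genetic
  correlations, because that is the quantity the chip-overlap analysis
  measures. σ²ₑ is set from the realized var(Xβ) so the genotype-mean
  heritability equals the target h²; replicate plot noise has variance
  n_reps·σ²ₑ so means of n_reps = 3 replicates retain it. Defaults: five
  traits (YLP, NP, NS in three localities; SB, VB in the two dry ones),
  300 QTL, h² = 0.5, qtl_share = 0.1 — a low-sharing regime consistent
  with the few-percent cross-locality chip overlap the analysis is built
  around.
- **What it does not emulate:** the real panel's pedigree (backcross
  structure and resulting long-range relatedness), selection, genotype ×
  management interactions, depth-dependent genotyping error, and LD decay
  *between* blocks. Passing tests therefore demonstrate correctness of the
  machinery and qualitative orderings (full vs subset, chip retention,
  imputation gain), not the field study's absolute prediction abilities,
  which depend on the real panel's relatedness structure.

## Numerical choices and degenerate inputs

- Fixed update order (intercept → effects in genome order → variances);
  scan order affects MC noise only, and subsets are passed in genome order
  so a full-size subset reproduces the plain fit exactly.
- Log-odds for spike-and-slab inclusion are clamped at ±35 before
  exponentiation; BayesC's estimated inclusion probability is clamped to
  (10⁻⁶, 1−10⁻⁶); BL guards β² below 10⁻¹² in the inverse-Gaussian mean.
- Kernel eigenvalues below 10⁻¹⁰ × max are dropped; an all-identical
  genotype panel raises a degenerate-kernel error rather than returning a
  constant kernel.
- Zero-variance responses, incomplete matrices passed to `fit`, all-missing
  markers, and empty post-filter matrices all raise explicit errors;
  `fit` refuses missing genotypes rather than silently mean-imputing.
- Zero-variance uniformity indices are capped at the largest finite index
  and flagged rather than propagating infinities.

## Problem sizes used by the reproduction script and test suite

Oracle equivalences run at n = 100, m = 200; heritability recovery at
n = 300, m = 2,000, 300 QTL, chains 3,000/500, 5 seeds; marker-set
orderings at n = 300 with m = 2,000 (500 QTL) and m = 5,000 (800 QTL),
chains 1,500/300; imputation masking at n = 100, m = 600, 10% masked,
5 seeds. These sizes were chosen so each check isolates the property being
measured while completing in minutes.

## Known limitations

- BayesB estimates no π (fixed by design, as in the classical definition);
  the variance-updating BayesB variant is out of scope.
- The missing-heritability aggregation across localities reported by the
  original study cannot be reconstructed from its per-locality table;
  this package reports per-locality values and their mean and leaves the
  aggregation to the user.
- Chains store scalar traces (μ, σ²ₑ, σ²ₐ, π) for diagnostics, not full
  per-marker effect chains.
- The pipeline's "associated markers" set is consumed as a plain ID list;
  no GWAS is performed here.
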