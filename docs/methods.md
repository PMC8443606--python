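# Methods

## Population and genome model

The simulator is forward-in-time throughout. Loci are abstract biallelic
markers on a genetic map; there is no sequence, and no coalescent shortcut
is used for the historical phase.

**Historical phase.** All loci start segregating at frequency 0.5
(independent Bernoulli alleles in every founder). Each of the 400 historical
generations (constant size 1000; 500 males, 500 females) is produced by
drawing, per offspring, a sire uniformly among males and a dam uniformly
among females. This leaves drift, recombination and recurrent mutation
(per-locus, per-gamete Bernoulli flip at 2.5 × 10⁻⁸) to shape the
allele-frequency spectrum and linkage disequilibrium. Offspring sexes are
assigned to hit the male/female counts exactly. The 0.5 initialization is a
deliberate choice: with 400 generations at N = 1000 it leaves the large
majority of loci polymorphic, matching the intended "informative SNPs
everywhere" design without importing an external frequency spectrum.

**Meiosis.** Per chromosome, the crossover count is Poisson with mean equal
to the map length in Morgans, crossover positions are uniform on the map and
there is no interference (Haldane model); the starting strand is chosen
fairly. Mutation uses an exact Bernoulli mask at appreciable rates and a
binomial-count approximation (collision probability vanishing) at the
default tiny rate.

**Breeding phase.** G0 is 50 sires + 50 dams drawn uniformly from the last
historical generation; the pedigree treats them as unrelated founders. G01
is produced by random 1:1 pairing of all G0 parents. From G02 on, the top 50
males and top 50 females by selection EBV are paired randomly 1:1 into 50
full-sib matings (ties broken by individual id for reproducibility). Family
sizes are fixed (equal contribution, S1) or i.i.d. categorical (unequal
contribution, S2). Offspring sex is Bernoulli(0.5).

**Selection EBVs.** Parent selection uses single-trait pedigree BLUP on all
phenotypes recorded so far (G01 up to the current generation), with the
*true* simulated variance components — one Cholesky solve per generation, no
REML. This mirrors a breeding program whose operational evaluation knows its
variance components well, and keeps the selection machinery independent of
the REML used for the accuracy experiments. G0 itself carries no phenotypes;
its EBVs are uniform, so G01 parentage is effectively random mating.

## Trait model

Phenotypes are `y = μ + u_qtl + u_poly + e` with μ = 0 and phenotypic
variance standardized to 1. Per heritability the additive variance is split
2:1 between the QTL and polygenic components:

| h²   | var(QTL) | var(polygenic) | var(residual) |
|------|----------|----------------|----------------|
| 0.05 | 0.03     | 0.02           | 0.95           |
| 0.3  | 0.2      | 0.1            | 0.7            |
| 0.5  | 0.3      | 0.2            | 0.5            |

The 0.3 row is the anchoring case (a third of the additive variance
polygenic); the same ratio is generalized to the other heritabilities so
that total additive variance equals h² exactly.

QTL allele-substitution effects are drawn once per dataset from a standard
normal and rescaled by a single constant so the sample variance of QTL
breeding values in G0 equals var(QTL) exactly (and centered so G0's mean
breeding value is 0); effects are then fixed for all generations, so later
selection, drift and fixation genuinely erode the realized additive
variance. The polygenic value of an offspring is the mid-parent value plus a
Mendelian-sampling deviation N(0, var_poly/2 · (1 − (F_s + F_d)/2)), with
parental inbreeding F taken from the pedigree NRM diagonal — the standard
infinitesimal-model bookkeeping.

## Genotyping error model

Observed genotypes are drawn per entry from the 3×3 transition probability
matrix row of the true genotype class. The built-in matrices use diagonal
1 − rate with the off-diagonal pattern 3:2 (homozygote rows) and 1:1
(heterozygote row); at 1 % this is rows (0.990, 0.006, 0.004) /
(0.005, 0.990, 0.005) / (0.004, 0.006, 0.990), and at 10 % the same ×10.
A published variant of the 5 % matrix has off-diagonals an order of
magnitude too small for its diagonal (rows summing to 0.955); the default
treats this as a typographic slip and uses the consistent pattern
(realized error exactly 5 %), with the row-renormalized as-printed variant
available via `build_transition_matrix(0.05, five_percent_as_printed=True)`
(realized error ≈ 0.53 %). Errors are i.i.d. across individuals and loci,
injected after panel sampling, on training and test animals alike.

## Relationship matrices and prediction

The GRM is `G = WW′/c` with `W = X + 1 − 2p` (X coded −1/0/1) and
`c = 2Σ p_j(1 − p_j)`; allele frequencies are estimated from the observed
(post-error) genotypes of the generation being analysed — there is no
external frequency reference, so the error model perturbs both W and c, as
it would in practice. Monomorphic(-after-error) loci contribute zero to both
numerator and c and are retained, keeping panel-size labels exact. A
per-locus-standardized variant (each locus divided by its own √(2pq)) is
available behind `compute_grm(..., standardized=True)`; all shipped analyses
use the `WW′/c` form. The NRM uses the tabular method over the full pedigree
(founders at G0) and is then restricted to the generation being analysed, so
ancestral relationships propagate into the within-generation block.

The mixed model `y = 1μ + u + e`, u ~ N(0, K σ²_u), is fitted by REML,
profiling the restricted likelihood over δ = σ²_e/σ²_u on a log grid via a
spectral decomposition of the intercept-projected training kernel (the
`mixed.solve` approach: double-centering K + I isolates the intercept
direction as the single null eigenvalue). Test individuals get
`K[test,train](K[train,train] + δI)⁻¹(y − μ̂)`. Numerical policy: kernels
with smallest eigenvalue below −10⁻⁶ are rejected as non-PSD; smaller
violations are clamped/jittered at 10⁻⁸; the δ search is bounded at
10^±10, and a boundary optimum (effectively h² → 0 or 1) is a valid
estimate, not an error. GBLUP predictions are algebraically identical to
marker-effect ridge regression with penalty c·σ²_e/σ²_u, and the test suite
holds the two routes to 10⁻⁸ on small instances.

The 30 % test split is round-half-away-from-zero of n × 0.30 per generation
(5000 → 1500/3500), drawn uniformly; one split per generation is shared
across all panel and error cells so that cell contrasts are paired.

## Evaluation

Accuracy is the sample Pearson correlation of (G)EBV with TBV on the test
set. Replicate summaries report mean ± SE with SE = sd/√n, using the n−1
sample standard deviation. Lin's concordance correlation coefficient uses
1/n moment estimators, `ρ_c = 2s_xy/(s_x² + s_y² + (x̄ − ȳ)²)`, computed on
the strict upper triangles of the error-free versus error-corrupted GRM of
the same panel; |CCC| ≤ |r| always, with equality only under matched means
and variances. Cells with a single observation report a missing SE rather
than zero.

## Profiles and problem sizes

The `full` profile carries the complete design (44 chromosomes, 400 × 1000
history, 5000 per generation, panels up to 20 K, 960 grid cells) and is
configuration-checked but not routinely executed — its counts
(52,800 / 3,740 loci; 960 / 240 / 60 datasets; 5000 → 1500/3500 splits) are
verified as arithmetic. Executed experiments use:

* `desk` — 4 chromosomes × (300 SNPs + 20 QTLs), 100 historical generations
  of 200, 50 families of ~20 (S2 sizes are the full-scale distribution ÷ 5,
  keeping S2's expected generation size aligned with S1's, as in the
  full-scale design), 3 replicates, panels {200, 1000}, errors {0, 10 %}.
  One base dataset simulates and analyses in a few seconds; the headline
  heritability contrast (12 base datasets) runs in about a minute.
* `tiny` — 2 chromosomes × (250 + 15), 40 × 100 history, 20 families of
  ~10 — used by the test suite's directional-trend checks.

At reduced scale the post-QC SNP count can drift below a nominal panel size;
the pipeline then uses all available SNPs while keeping the nominal label
(`sample_panel` itself is strict).

## What the generator does and does not emulate

It reproduces the design's population structure (closed historical
population, full-sib families, truncation selection with a 1:1 mating
ratio), trait architecture and error mechanism. It does not model
overlapping generations, mortality or fecundity differences, parentage
misassignment, locus-specific or depth-dependent genotyping error, dominance
or epistasis. Passing tests therefore speak to the statistical machinery and
to qualitative design conclusions (density, error and heritability trends),
not to absolute accuracy levels in any real hatchery population.

**Scale caveat.** Sib-training accuracy depends strongly on the number of
phenotyped sibs per family (~14 at desk scale versus ~70 at full scale).
With few sibs, the family-mean signal for a lowly heritable trait is poorly
estimated and low-h² accuracy drops disproportionately, so the *relative*
accuracy gain from raising heritability is systematically larger at reduced
scale (the desk-profile contrast computed by `scripts/acceptance.py` lands
around +55 to +75 % across seeds, versus much smaller relative gains
expected at full scale). Conversely, at very small effective sizes
(`tiny`), strong selection on a highly heritable trait erodes additive
variance within a few generations and can locally invert the heritability
ranking of accuracies in late generations. Comparisons across scales should
therefore be directional, not numeric.

## Known limitations

* Dense-matrix algebra only: pedigree BLUP over the cumulative pedigree is
  O(n³) per generation, which is why the full profile's 25,000-individual
  pedigrees are out of routine reach; no sparse Henderson inverse is
  provided.
* REML is single-kernel (no separate QTL/polygenic decomposition in the
  evaluation model), matching the analysis model of the study design rather
  than the generative model.
* The historical phase is the dominant runtime cost at full scale; the
  simulator is vectorized per generation but makes no attempt at
  multi-threading.
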