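# Methods

## Estimator

The trait model is **Y** = **G**β + ε with an n × m standardized dosage
matrix **G**, m ≫ n.  Fitting the full regression is both intractable and
ill-posed, so **G**′**G** is approximated as block-diagonal: the columns
are partitioned into K blocks with p_k ≪ n and each block is fitted by
OLS independently.  Per block, the heritability contribution is the
adjusted R̄²_k = 1 − (1 − R²_k)(n−1)/(n−p_k−1) with R²_k = ŷ′ŷ/y′y, and
the total is ĥ² = Σ_k R̄²_k.  Negative R̄²_k values are retained: under
the null E[R̄²_k] = 0 exactly, and truncating at zero would bias the sum
upward.

Block fits use a pivoted QR factorization rather than the explicit
normal-equations inverse; rank-deficient blocks (duplicated or collinear
rare columns) drop dependent columns and use the effective rank as p_k,
with a warning.  Both y and the design are standardized to mean 0, so no
intercept is fitted and the residual degrees of freedom are n − p_k − 1
throughout.

The sampling variance of R²_k uses the asymptotic (Algina-type) form
4R²(1−R²)²(n−p_k−1)²/((n²−1)(n+3)); the published formula writes the df
factor with an index symbol that collides with the block index, and it is
read here as the block's predictor count p_k, consistent with the
adjustment factor ((n−1)/(n−p_k−1))² used for Var(R̄²_k).  Var(ĥ²) is the
sum of per-block variances, which presumes between-block correlation has
been removed by pruning; the CI is the Wald interval ĥ² ± 1.96·√Var(ĥ²).
This plug-in variance is accurate at moderate per-block R² but overstates
the spread near the null, where the sample R² of a p_k-predictor block is
biased upward by ≈ p_k/n — see "Power" below for the consequence.

Gene-level inference uses the F statistic (R²/p_k)/((1−R²)/(n−p_k−1)) on
(p_k, n−p_k−1) df; raw R² is used because adjusted R² has no standard F
reference.  The default multiplicity correction is Bonferroni over the
number of genes tested (0.05/18,214 = 2.75 × 10⁻⁶ at whole-exome scale).
Stratum comparisons (e.g. sex) use a two-sample z-test on
(ĥ²_a − ĥ²_b)/√(Var_a + Var_b), valid only for disjoint strata.

## Genotype processing

Dosages are additive counts of the minor allele; multi-allelic sites are
collapsed to presence/absence of any alternate allele (hom-alt → 2,
compound het of two different alts → 1).  Variant filters run in a fixed
order — monomorphic, missingness > 10%, exact Hardy-Weinberg p < 5×10⁻⁶,
MAC ≤ 2, MAF ≥ ceiling (default 1%, optionally enforced across
reference-population MAFs) — and each variant is counted against the
first filter it fails, so the QC report reconciles exactly.  The HWE test
is the exact conditional (Levene/Haldane) enumeration, appropriate where
the chi-square approximation fails for rare genotype classes.  MAF and
MAC are computed on observed calls; missing genotypes are then
mean-imputed and columns standardized with the population-variance
denominator, giving |mean| < 1e-8 and |var − 1| < 1e-8 per column.

Pruning is a greedy single pass per chromosome: candidates are visited in
position order (or descending score in clump mode) and dropped on the
first violation of r² > r2_max against an already-retained variant within
the window.  Because every candidate is checked against all retained
variants in its window, one pass establishes the pairwise post-condition
globally; the configured step size is carried for provenance only, since
the pairwise distance check subsumes window stepping.  r² is the squared
Pearson correlation of mean-imputed standardized dosages, matching the
estimator's design matrix.  Tie-breaking is deterministic: lower position
first, then lexicographic variant id.

Exome blocks merge a final remainder smaller than max(100,
target_size/10) into its predecessor to avoid unstably small designs.
Gene blocks assign a multi-gene-annotated variant to each of its genes
(accepting the slight double-counting this implies for gene-wise totals);
exome blocks use each variant once.  Burden scores are per-sample sums of
raw (un-standardized) allele counts over a gene, standardized afterwards;
constant burden columns (no carriers) are dropped with a log message.

## Phenotype preparation

Fixed order: winsorize at configured value limits → mean-impute missing
values → rank-based inverse-normal transform (Blom offset 3/8, average
ranks for ties) → OLS residualization on covariates with intercept →
standardize.  The output is exactly orthogonal to every covariate column
and invariant to monotone transforms of the raw trait.  Covariate
rank-deficiency is reported with the offending column names.  Covariate
degrees of freedom are deliberately ignored in the estimator's n (the
two-stage design residualizes first), so block df remain n − p_k − 1.
Medication corrections precede everything: statin users' LDL/ApoB ÷ 0.7,
total cholesterol ÷ 0.8, ApoA-I ÷ 1.06, HDL ÷ 1.05; +10 / +15 mmHg for
DBP/SBP under antihypertensives; samples on glucose-lowering drugs are
excluded.

## Synthetic-data generator

Dosages are Binomial(2, MAF) with MAF ~ Uniform over the configured range
and a resampling floor of MAC > 2; positions are evenly spaced with
contiguous gene assignments.  Two LD models plant correlation by
per-sample mixture copying (partner equals source with probability r,
else a fresh draw with the same MAF, giving Corr ≈ r): `BlockLd`
correlates adjacent variants (a chain with geometrically decaying LD) and
`LongRange` correlates disjoint variant pairs a fixed genomic distance
apart, emulating long-range LD.  Phenotypes are Gβ + ε with β standard
normal on the causal set — a fraction of variants inside a fraction of
genes — rescaled so the realized genetic variance equals the target h²
exactly, and ε ~ N(0, 1−h²); effect sizes are independent of MAF on the
standardized scale.  All randomness flows from a single seed.

What the generator does *not* emulate: realistic site-frequency spectra,
coalescent LD structure, population stratification, relatedness, or
genotype error.  Passing calibration tests therefore demonstrate the
estimator's arithmetic and its response to the planted LD structures, not
robustness to every feature of real cohorts.

## Calibration experiments

`run_calibration` generates genotypes, prunes under each scenario, builds
exome blocks, and estimates 20 simulated phenotypes per scenario.  With
`simulate_on="pruned"` (pruning-parameter calibration) causal variants
are drawn from the retained set, so bias isolates residual between-block
LD: lax pruning (r² > 0.9, 1 Mb) on long-range-correlated genotypes
leaves correlated partners in different blocks and inflates ĥ², while the
stringent preset removes them.  With `simulate_on="full"` (architecture
experiments) phenotypes are simulated on the full matrix before pruning;
causal variants can then be pruned away and are only partially recaptured
through retained LD partners (a fraction ≈ r² of each lost variant's
contribution).  Under a chain-LD genotype model this loss applies at any
causal density; the sparse-architecture experiment (< 1% of genes causal)
uses it to reproduce the direction of the known underestimation when the
causal set is very small.

## Power

Biobank-scale power avoids genotype simulation: under per-block
heritability h²_k, the block F statistic is approximately non-central
F(p_k, n−p_k−1; λ_k) with λ_k = n·h²_k/(1−h²) — the standard fixed-design
R² noncentrality — and h²_k is allocated ∝ p_k (homogeneous per-variant
contribution).  Draws convert to R²_k = p_k F_k/(p_k F_k + n−p_k−1), then
to ĥ².  The Wald test's SE is the *empirical* SD of the simulated ĥ²
within each (n, h²) condition: the per-block plug-in variance evaluated
at the sample R² overstates the null spread (type-I ≈ 0.014 instead of
0.05), while the empirical SE restores type-I ≈ α and is what the power
figures use.  The p-value is one-sided (heritability is non-negative
under the alternative).  A cross-check against direct genotype simulation
(n = 2,000, four blocks of 200, h² = 0.10) agrees within Monte-Carlo
error.

## Enrichment

Variants are ordered loss-of-function first (by position; within-LoF
ordering by score is not meaningful since most LoF lack missense
calibrated scores), then missense by descending pathogenicity score.  For
each expanding percentile subset the pipeline is: score-aware LD clumping
(r² > 0.1, 50 Mb, keep the higher-scored member), gene-wise blocks,
block-sum ĥ².  Proportions are taken against the full set pushed through
the identical clumped pipeline, so numerator and denominator share the
pruning regime and the final point is exactly (1, 1).  Negative per-gene
values are retained in both sums.  Recommended binary cut-offs (CADD 20,
M-CAP 0.025, REVEL 0.5) and the last-LoF fraction are attached to the
curve for plotting.

## Problem sizes and numerical choices

Experiments in the test-suite and the acceptance script use scaled-down
cohorts chosen to keep Monte-Carlo error well below the effects being
measured: calibration recovery at n = 5,000 with 2,000 variants in blocks
of 500; long-range-LD scenarios at n = 3,000 with 600 variants; CI
coverage and burden comparisons at n = 2,000; null calibration at
n = 400–1,000; power at the full n = 167,348 via the non-central-F
shortcut (2,000 replicates).  The orthogonal-design equivalence check
(Σ R̄²_k vs whole-design R̄²) is exact for R² and holds for adjusted R²
up to a df correction of order R²·(m − p_k)/n; it is verified at
n = 2×10⁵, m = 120 with low per-fit R², where that term sits below the
1e-6 tolerance.  Standardization and orthogonality contracts use 1e-8;
rank detection uses the usual max(n,p)·eps·|R₁₁| threshold on the QR
diagonal.

## Known limitations

Continuous traits only — dichotomous traits would need a liability-scale
transformation.  The block-sum variance assumes between-block
independence, which the stringent pruning enforces only approximately.
Gene-wise totals double-count variants annotated to overlapping genes.
The generator's uniform-MAF, architecture-free effect model is a
deliberate simplification; conclusions about real cohorts require the
real-data pipeline (QC, pruning, covariate residualization) applied to
sequencing data.
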