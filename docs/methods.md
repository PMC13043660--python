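# Methods

`cytopred` implements a leakage-controlled analysis pipeline for
stimulated-cytokine cohort studies: a synthetic-cohort generator with
recorded ground truth, variant QC, univariate and canonical-correlation
multivariate GWAS, matrix-completion phenotype imputation, immunotype
clustering, clumping+thresholding (C+T) polygenic prediction inside a
nested cross-validation benchmark, permutation feature importance, and
polygenic-score (PGS) association testing. This note documents the models,
the defaults and why they were chosen, and what the synthetic data do and
do not establish.

## Synthetic cohort model

Real stimulated-cytokine cohorts are controlled-access; every stage is
therefore exercised on synthetic cohorts whose statistical structure
matches the assumptions of the downstream methods, with all planted
effects recorded in a `Truth` object.

**Genotypes.** Variants come in LD blocks. Each block holds a pool of
`haplotype_pool_size` (default 8) haplotypes; per-variant ALT frequencies
are drawn uniformly from `maf_range` (default 0.05–0.5, the post-QC
regime) and each haplotype carries a Bernoulli draw per variant, re-flipped
if a variant would be monomorphic in the pool. An individual's block
dosage is the sum of two independent pool draws, so within-block LD is
strong and block-structured (pool size 2 gives r² = 1 by construction)
while blocks are independent (cross-block E[r²] ≈ 1/n). Defaults are 50
blocks × 40 variants; blocks span < 250 kb with > 1 Mb gaps so the C+T
window logic is exercised realistically. The haplotype pools depend only
on the config seed; replication cohorts redraw individuals from the same
pools, which keeps the variant panel and causal effects shared across
cohorts.

**Covariates.** Age uniform 20–60; sex Bernoulli(0.5); BMI truncated
normal (23.5, sd 2.5, bounds 17–32); collection day uniform 1–365; five
immune cell counts and three sex hormones log-normal (hormone log-means
sex-dependent); CMV seropositivity Bernoulli(0.35). These are plausible
healthy-adult magnitudes; only their relative effect sizes matter for the
pipeline's behavior.

**Cytokine traits** are generated on the log2 scale as

    y = intercept + Σ β_j g_j + γ_age·z(age) + γ_cmv·CMV + a·s1 + b·s2
        + γ_mono·z(monocytes) + γ_sex·sex + ε,   ε ~ N(0, σ²)

with s1 = sin(2π·doy/365), s2 = cos(2π·doy/365). Causal βs are drawn
normal and rescaled so the planted-SNP component contributes exactly
`h2_genetic` of unit total variance; when `noise_sd` is unset it absorbs
the remaining variance. Realized per-source variance fractions are
recorded empirically in `Truth`.

Two archetypes encode the study's central dichotomy. `TCR_LIKE`
(adaptive-response-like): 5 causal variants, h² = 0.25, modest age/CMV/sex
effects, no seasonality or monocyte effect. `TLR_LIKE`
(innate-response-like): h² = 0.02 spread over 50 tiny effects, strong
seasonality ((a² + b²)/2 ≈ 0.25), monocyte fraction 0.15, small age/sex
effects. `NULL` is pure noise. Missingness is MCAR only; the mechanism in
real panels is uncharacterized, so nothing fancier is defensible.

**What passing on synthetic data shows.** That the machinery is correct
and calibrated: selection is leakage-free, tests have their nominal size,
planted structure is recovered. It does not show that real cytokine traits
have these variance partitions, nor does the generator model population
structure, genotype-imputation uncertainty, assay floor/ceiling effects,
or informative missingness.

## Preprocessing

Variant QC removes variants with call rate ≤ 0.95 (implemented as
missingness ≥ 5%), MAF < 0.05 (strict: exactly 0.05 is retained), or
exact Hardy-Weinberg p < 0.001. The HWE test is the conditional exact
test on heterozygote counts (standard, not mid-p), validated to 1e-12
against a rational-arithmetic enumeration oracle. The three filters
commute.

The inverse rank-normal transform uses the Blom offset c = 3/8 with
average ranks on ties; the offset choice is conventional and immaterial at
cohort sizes here. Residualization is ordinary least squares on
[intercept | covariates] with constant columns dropped and rank deficiency
reported by naming collinear columns. Genotype PCA runs on mean-imputed,
column-standardized dosages of the analysis cohort itself (no external
reference panel; the covariate role of ancestry PCs is preserved).
Scalers are always fitted on training data only and applied unchanged to
test data.

## GWAS

Univariate association is per-variant simple linear regression of the
adjusted (residualized, inverse-rank-normalized) trait on dosage, two-sided
p from t on n−2 df, complete cases per variant; monomorphic variants emit
missing results. An exact fit (zero residual variance) reports p = 0
rather than missing. Implementation is closed-form and vectorized;
correctness is checked against statsmodels OLS and a normal-equations
oracle to 1e-10.

The multivariate test associates one variant with a "cytokine network":
the central trait plus every trait with |Pearson r| > 0.2 against it. For
a single dosage vector g and trait matrix Y, the squared canonical
correlation ρ² equals the R² of regressing g on Y; Wilks' Λ = 1 − ρ² and
F = ((n−q−1)/q)·ρ²/(1−ρ²) on (q, n−q−1) df, which is exact in this rank-1
case. Loadings are the coefficient vector scaled to unit norm with the
largest-magnitude loading positive (the sign is otherwise arbitrary).
Validated against an independent generalized-eigenvalue solution and, at
q = 1, against the univariate p.

Lead SNPs: greedily take the smallest p below 5×10⁻⁸, mask ±500 kb on the
same chromosome, repeat; ties break by (chrom, pos, ID), making the output
row-order invariant. Genomic inflation λ_GC is the median association χ²₁
over its null median. Calibration checks (KS uniformity of null p-values)
are run on LD-free synthetic panels because the KS test presumes
independent p-values; LD-blocked panels have marginally uniform but
dependent p-values that inflate the KS statistic without any miscalibration
of the per-variant test.

## C+T prediction and the benchmark

Clumping is greedy by ascending p: variants below p1 seed clumps and
absorb unassigned variants below p2 within the window whose r² with the
index exceeds the threshold; r² is computed in the cohort split being used
for selection (training split in the honest protocol). Defaults are the
genome-scale convention p1 = 1e-5, p2 = 1e-2, r² > 0.5, 250 kb. The
package also ships `DESK_SCALE_CLUMP` (p1 = 1e-2, p2 = 5e-2): on the
default 2,000–5,000-variant synthetic panels the genome-scale p1 would
select essentially nothing, so the desk-scale threshold is set to keep the
*expected number of chance-passing variants* comparable to the
genome-scale setting (5,000 × 1e-2 = 50 ≈ 4.8M × 1e-5 = 48). This was
fixed analytically when the panels were sized, and all synthetic benchmark
runs use it.

The C+T score is the unweighted sum of β × effect-allele dosage over index
variants (clumped members are discarded). Rank-based evaluation is
invariant to positive rescaling, so sum-vs-mean conventions do not affect
results. Allele matching: effect allele equal to ALT uses the dosage,
equal to REF uses 2 − dosage, anything else is skipped and logged — strand
flips are never guessed, because silent strand guessing corrupts scores.
Missing dosages contribute the scored cohort's mean dosage.

The benchmark runs 5-fold cross-validation. Per fold, the trait is
residualized and normalized on the selection cohort, a univariate GWAS
plus clumping selects markers, and features (selected dosages, optionally
plus z-scored covariates with seasonality encoded as s1/s2) and targets
are z-scored with training-fold parameters. `TRAIN_ONLY` re-runs selection
inside each training split; `FULL_COHORT` deliberately selects once on
everyone to expose leakage. An audit log records which individuals each
stage touched; tests assert the honest protocol never lets test
individuals into selection or fitting, and that the two leakage arms
differ *only* in the selection stage.

Model zoo: OLS, ridge, elastic net, random forest (500 trees), gradient
boosted trees, and a multilayer perceptron, with the hyperparameter grids
fixed in `HYPER_GRIDS` and randomized search over up to 25 configurations
scored by inner 5-fold Spearman. The MLP uses scikit-learn's
`MLPRegressor` with early stopping on a 10% validation split (patience 10,
max 500 epochs); scikit-learn supports an L2 penalty only, so the grid has
no separate L1 axis. When a fold's selection yields zero variants the
genetic feature set is empty: C+T emits a missing result and learners fall
back to intercept-only predictions — silently relaxing p1 would change the
method. Prediction never uses imputed cytokine values; complete cases
only.

## Evaluation

Performance is Spearman correlation between predictions and held-out
observations (average ranks on ties; constant vectors yield a missing
result). Models are compared across traits with Friedman's test on
within-trait ranks; the p-value uses the Iman–Davenport F refinement of
the χ² approximation, which simulation shows is better calibrated at the
9-model × 11-trait scale (rejection 4.5% vs 3.5% at nominal 5%). Conover
post-hoc t statistics on rank sums are Holm-corrected; models whose
pairwise comparisons are not rejected at α form connected groups (the
critical-difference-diagram convention).

Permutation importance permutes one feature's test column at a time
(seeded), re-predicts, and averages the drop in test Spearman over 50
permutations; constant columns score exactly 0. All selected variants are
summed into a single "SNPs" category; s1/s2 sum into "seasonality"; other
features are singleton categories. Scores are reported as raw mean Δρ,
not normalized. All permuted copies are stacked into one model-predict
call per fold, which matters for tree ensembles whose predict cost is
dominated by per-call overhead.

Cross-cohort validation trains on the full first cohort and predicts the
second over the shared covariates (no hormones, matching the variables
available across cohorts) and the shared-variant intersection, with
first-cohort scalers applied unchanged. A constant log-scale intercept
shift between cohorts (e.g. differing stimulus concentration) leaves
Spearman evaluation exactly unchanged, which the tests assert as an exact
equality.

## Phenotype imputation

SoftImpute: missing cells start at 0 on standardized inputs; each
iteration soft-thresholds the singular values of the current completion by
λ, rebuilds, and restores observed cells; convergence is a relative
Frobenius change of the missing block below 1e-5 (max 500 iterations,
non-convergence flagged, not fatal — both values are conservative choices,
logged in the result). Observed entries are never modified and the
nuclear-norm objective is non-increasing across iterations (asserted in
tests). Candidate penalties are σ₁/K for K ∈ {1.5, 2, 4, 10, 50, 100};
tuning masks one observed value per column per repeat and minimizes masked
MSE. The desk-scale default is 100 repeats (tests use fewer); production
runs would use 1,000. Accuracy is summarized as the RMSE skill
1 − RMSE_model/RMSE_mean against column-mean imputation. Imputed traits
feed only the GWAS stage.

## Immunotype clustering

Individuals are clustered hierarchically (Ward linkage, Euclidean) on
inverse-rank-normalized cytokine responses, all k from one linkage tree.
Cluster number is chosen by the average silhouette over k = 2..15 and
supported by the gap statistic with B = 100 uniform reference datasets
drawn over each feature's observed range and passed through the same
normalization; both the full curves and the 1-SE rule (smallest k with
gap_k ≥ gap_{k+1} − s_{k+1}) are reported, and the gap never silently
overrides the silhouette choice. Ward is used for individuals (the
linkage for that use is a free choice); average linkage is the convention
for reordering trait-correlation heatmaps. Cluster contrasts use
Mann-Whitney U for continuous and χ² without continuity correction for
categorical variables (omnibus Kruskal-Wallis/χ² beyond two clusters),
Bonferroni-adjusted across variables.

## PGS association

Scores are weighted sums of effect-allele dosages from PGS-Catalog-style
weight files, with the same allele-matching rules as C+T scoring and
matched/flipped/skipped counts reported. Significance of a PGS–trait
Spearman correlation uses a permutation null (trait permuted 1,000 times)
with the +1 smoothing convention p = (1 + #{|ρ_perm| ≥ |ρ_obs|})/(n_perm+1),
so p is never exactly 0 and the test is two-sided by construction. PGS
columns are standardized before entering prediction feature tables.

## Problem sizes and numerical choices

Synthetic benchmark runs use n = 400 individuals; leakage experiments use
5,000-variant panels (125 blocks), other benchmarks the 2,000-variant
default; forests always grow the grid's 500 trees. Benchmark-scale runs
use the fixed default hyperparameter configurations rather than the
randomized search (the search is exercised separately); these sizes give
stable qualitative results at single-CPU scale. Tie-breaks everywhere are
lexicographic (p, chrom, pos, ID) so outputs are independent of input row
order. All randomness flows through seeded NumPy generators;
`SeedSequence.spawn` separates structural (haplotype-pool) from
individual-level randomness so replication cohorts share variants without
sharing individuals.

## Known limitations

Single-CPU, dense-matrix implementation: panels beyond ~10⁵ variants ×
10³ individuals would need chunked or sparse genotype storage. The MLP
lacks an L1 penalty. The gap statistic uses the uniform-over-range
reference (not the PCA-aligned variant). No mixed-model association, no
relatedness or sex-chromosome QC, no genome-build liftover. The leakage
experiment quantifies selection-on-test-data leakage only; other leakage
channels (e.g. global normalization before splitting) are prevented by
construction rather than measured.
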