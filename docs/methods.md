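# Methods

## The heterozygosity statistic

For individual *i*, over the QC-passed autosomal SNPs that are
non-missing in *i*,

    t_i = (# heterozygous genotypes) / Σ_m 2 p_m (1 − p_m),

with p_m the cohort major-allele frequency (the expression is symmetric
in p vs 1 − p, so allele orientation is immaterial).  Restricting both
numerator and denominator to the individual's called loci keeps
E[t] = 1 under missingness-at-random; the alternative (denominator over
the full panel) would deflate t for individuals with more missing calls.
Frequencies are computed per cohort from QC-passed study samples,
before outlier/relatedness exclusions (order configurable in
`pipeline`).  Standardization uses the sample SD (n − 1 denominator).

Two properties carry the design:

- E[t] ≈ 1 under Hardy–Weinberg equilibrium, and E[t] ≈ 1 − f for an
  individual with inbreeding coefficient f (heterozygosity deficit).
- SD(t) ∝ 1/√M for a panel of M SNPs under HWE, which is why raw Cox
  betas on t are not comparable between genotyping arrays.

## SNP and sample QC

SNP exclusions: monomorphic; missing fraction strictly greater than
0.5% (exactly 0.5% retained; the fraction is computed from counts so the
boundary compares exactly); MAF ≤ 10% (boundary excluded); HWE p-value
below 0.001 (1-df chi-square by default, conditional exact test
available); non-autosomal chromosomes; and an optional external
exclusion list (one SNP id per line), which is how annotation-dependent
rules (non-unique genome mapping, retired array probes) are honored
without shipping annotation resources.  A printed formulation of the HWE
rule as "exclude p ≥ 0.001" — which would discard essentially all SNPs —
is implemented verbatim behind `literal_hwe_rule=True`; the default is
the universal convention.

Sample QC: genotypes are standardized ((g − 2q)/√(2q(1−q)), missing
imputed to the mean), PCA is computed by exact SVD of the combined
study + reference matrix, and each sample's distance from the matching
reference-population centroid in the first 3 PCs is computed with
squared PC deviations weighted by the explained-variance fractions:

    d_i = sqrt( Σ_{j≤3} v_j (s_ij − c_j)² ).

The SD of d over the reference samples sets the scale; samples with
d > 10 SD are genetic outliers.  (Weighting the squared deviations,
rather than the distances, is a design choice; with v_j fixed it only
rescales the axis weights, and the rule is invariant to PC sign flips.)
A per-subgroup mode computes centroid and SD per reference group and
excludes only samples outlying with respect to every group.

Relatedness: pairwise kinship by the standardized-genotype correlation
estimator, φ̂ = (1/2M) Σ (g_i − 2q)(g_j − 2q)/(2q(1−q)) over shared
called loci (≈0.5 duplicates/MZ, ≈0.25 parent–offspring, ≈0.125
second degree).  Greedy pruning above the conventional second-degree
boundary 2^(−7/2) ≈ 0.0884: repeatedly drop the sample with the most
over-threshold partners, ties broken by dropping the lexicographically
larger id, so runs are reproducible.

## Survival model

Stratified Cox proportional hazards on the age scale with left
truncation: individual i is in the risk set of an event at age u within
its stratum iff entry_i < u ≤ exit_i.  Strata are the cross-
classification of sex, education (five levels, "Missing" is a level,
not dropped), income and collection center — each stratum has its own
baseline hazard, one shared coefficient vector; event-free strata
contribute nothing.  Sex enters as a stratification factor (a flag-free
design choice; subsetting by sex is how the per-sex analyses are run).
Covariates: the raw heterozygosity statistic t, BMI, and the first 10
PCs, entered linearly and unstandardized — effect-size standardization
happens after the fit (below).

Numerics: Efron's tie correction (ages in fractional years make ties
rare but possible); Newton–Raphson from β = 0 with step-halving on
likelihood decrease (the improvement test uses a relative tolerance,
1e−10·|ll|, so rounding noise in a large log-likelihood cannot stall a
step); convergence when max|score| < 1e−8, at most 50 iterations; SE
from the inverse observed information.  Risk-set sums are computed by
suffix sums over exit-sorted and entry-sorted arrays (the risk set is
{exit ≥ u} minus {entry ≥ u}), making each evaluation O(n p²) after an
O(n log n) setup.  Monotone likelihoods (separation) are detected by
coefficient divergence and reported as errors rather than returned.
The module also carries a deliberately naive transcription of the
partial likelihood (`partial_log_likelihood`) used by the tests to
cross-check the solver by direct maximization, alongside a lifelines
comparison.

Cause-specific analyses recode deaths from other causes as censored at
their exit age.  Per-chromosome analyses recompute t from one
chromosome's SNPs and refit.

## Meta-analysis

Each cohort contributes (β, se, z = β/se, deaths, SD(t)).  Two tracks:

- **Significance**: Stouffer's weighted Z = Σ w_k z_k / √(Σ w_k²) with
  w_k = cohort death count, two-sided normal p.  Since z is invariant
  to rescaling of the covariate, this track is free of the array-size
  bias (√deaths weighting available as an option).
- **Effect size**: β_std = β·SD(t), se_std = se·SD(t), pooled by
  fixed-effect inverse-variance weighting (weights 1/se²); reported as
  HR = exp(β_std) per SD and percent risk change (1 − HR)·100.  This
  only partially removes the bias but yields an interpretable per-SD
  effect.  Random-effects models are deliberately out of scope.

Heterogeneity: Cochran's Q with df = K − 1, I² = max(0, (Q − df)/Q)·100.
Subgroup comparisons pool each group by IVW and apply Q across the
group-level estimates (for two groups this equals the squared
z-difference test).  Output tables report both the IVW weight share and
the death count per cohort.

## The synthetic-data generator

The generator emulates the study conditions; its defaults are the
package's fixed reference scenario, not tuning knobs.

- **Genotypes**: per-SNP minor-allele frequencies uniform on
  (0.15, 0.5); per-individual inbreeding coefficient f_i ~ Normal(0.02,
  0.02²) truncated to [0, 1) (out-of-range draws are resampled).  Given
  f_i, genotype probabilities are {p² + pqf, 2pq(1 − f), q² + pqf},
  independent across loci.  The f_i channel is what gives t real
  variance beyond binomial noise — without it a planted hazard effect
  on standardized heterozygosity would be undetectable.  The chosen
  mean/SD keep cohort-level HWE distortion small enough that the HWE
  filter removes only a few SNPs (E[χ²] grows like n·f̄²).
- **Ancestry**: cohorts are assigned to two synthetic reference
  populations (default 75% "EUR" / 25% "AFR", mirroring the typical
  13-vs-4 cohort split of such consortia); the second population's
  frequencies are a Balding–Nichols draw at F_ST = 0.05.  Each cohort
  is ancestry-homogeneous and carries reference-panel samples (f = 0)
  from every population for the PCA/outlier stage.
- **Survival**: hazard λ_i(a) = k λ^k a^(k−1)·exp(β·z_i + covariate
  terms) with z_i the within-cohort standardized heterozygosity;
  default exponential baseline (k = 1, rate 0.012/year), Weibull
  optional.  Death ages are drawn by inverting the cumulative hazard
  conditional on surviving to the entry age (uniform 50–70), with
  administrative censoring at 95 — giving death fractions near 40%,
  the order observed in aging cohorts.  Causes (cancer/CVD/other,
  0.35/0.35/0.30) are competing exponential sub-hazards, independent of
  heterozygosity by default, with a per-cause effect override for power
  tests.  Default planted effect: β = ln 0.98 per SD (a ~2% risk
  reduction, the magnitude such studies report).
- **Covariates**: sex (log-HR +0.4 for males), BMI (Normal(27, 4.5²),
  +0.02/unit), education (5 levels incl. "Missing", small effects),
  income and center (no effect; strata only).  Missing genotype calls
  at rate 0.2% completely at random.

What the generator does **not** emulate: linkage disequilibrium (loci
are independent given f_i), genotyping batch artifacts, age-varying
covariates, informative censoring, admixed individuals within a cohort,
and any real-data allele-frequency spectrum.  Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to those real-data features.

## Problem sizes used by the test and acceptance runs

The replicate experiments are scaled to interactive sizes, with the
statistical bounds computed at the scale actually run (exact binomial
intervals at the replicate counts; Monte-Carlo SEs from the data):
metric calibration at n = 2,000 with M = 5,000 vs 20,000; Cox
permutation null with 500 refits at n = 200; array-size bias with
1k-vs-8k-SNP cohorts of n = 400 over 60 replicates; end-to-end recovery
with 6 cohorts × 1,000 individuals × 800 SNPs over 60 (coverage) and
100 (null-calibration) replicates; subgroup-test calibration over 500
replicates at the estimate level.  The 1,000-individual floor matters:
with ~60 strata and 16 covariates, cohorts much smaller than that leave
so few subjects per stratum that the Wald z is visibly over-dispersed
(measured SD ≈ 1.09 at n = 700), which would distort the calibration
experiments for reasons unrelated to the method itself.  The acceptance script additionally
runs the full demo study (4 cohorts × 2,000 × 5,000).

## Known limitations

- The IVW effect-size track inherits the residual array-size bias the
  standardization only partially corrects; its p-values are
  anti-conservative by construction, which is why significance is
  always taken from the Stouffer track.
- The exact HWE test enumerates heterozygote counts and is meant for
  per-SNP use, not vectorized scans.
- The Cox solver targets the data sizes of this design (thousands of
  rows, tens of covariates, many small strata); it does not implement
  robust variance, weights, or time-varying covariates.
- PCA is exact SVD; for panels far larger than the demo scale a
  randomized solver would be the natural drop-in.
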