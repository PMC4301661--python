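# hetsurv — genome-wide heterozygosity and human survival

`hetsurv` implements, end to end, a heterozygosity–fitness-correlation
(HFC) survival study of the kind run on large prospective genotyping
cohorts: does an individual's genome-wide heterozygosity predict their
risk of death?  Because the real cohorts behind such studies are
restricted-access, the package ships a first-class synthetic-data
generator that emulates their structure (multiple cohorts on different
genotyping arrays, ancestry structure with reference panels, covariates,
left-truncated survival with administrative censoring and competing
causes of death), so that every stage of the analysis is testable
against known ground truth.

It is written for statistical geneticists and biostatisticians who want
a reproducible, fully tested reference implementation of this design —
or who want to run the same pipeline on their own genotype + phenotype
data (VCF / PLINK / TSV in, TSV + JSON out).

## The statistic and the model

**Heterozygosity metric.** For individual *i* with QC-passed autosomal
genotypes, using the cohort major-allele frequency *p<sub>m</sub>* at
locus *m*,

> *t<sub>i</sub>* = (number of heterozygous loci) / Σ<sub>m</sub> 2 *p<sub>m</sub>* (1 − *p<sub>m</sub>*)

The denominator is the Hardy–Weinberg expectation of the numerator, so
E[*t*] ≈ 1 under random mating, and loci with a low a-priori chance of
heterozygosity (low MAF) are up-weighted.  Both sums run over each
individual's non-missing loci.

**Cohort model.** Within each cohort, a Cox proportional-hazards model
on the age scale: entry at study-entry age (left truncation), exit at
death or last follow-up, covariates *t*, BMI and 10 principal
components, and stratification (separate baseline hazards) by sex ×
education × income × collection center.  Efron tie handling;
Newton–Raphson with step-halving; SE from the inverse observed
information.

**Meta-analysis, two tracks.** Because SD(*t*) shrinks like 1/√M with
the SNP-panel size M, raw betas are not comparable across arrays.
Significance is therefore assessed by Stouffer's weighted Z over cohort
z-scores (weights = death counts), which is invariant to covariate
scale; the interpretable effect size comes from fixed-effect
inverse-variance pooling of SD-standardized betas
(β<sub>std</sub> = β · SD(*t*)), reported as a hazard ratio and percent
risk change per +1 SD of heterozygosity.  Cochran's Q / I² quantify
heterogeneity, and subgroup analyses (ancestry, chromosome, cause of
death, sex) use a between-group Q test on the pooled group estimates.

## Worked example

The `analysis/` scripts run the whole study on a simulated 4-cohort
dataset (1,200 individuals × 2,500 SNPs each, planted log-HR per SD
= ln 0.98 ≈ −2% risk per SD):

```bash
python analysis/01_simulate_cohorts.py   # cohorts -> results/cohorts/
python analysis/02_snp_qc.py             # SNP exclusion rules
python analysis/03_sample_qc.py          # PCA, outliers, relatedness
python analysis/04_heterozygosity.py     # t scores, genome + per chromosome
python analysis/05_cohort_cox.py         # stratified left-truncated Cox fits
python analysis/06_meta_analysis.py      # two-track meta-analysis
python analysis/07_recovery_and_bias.py  # calibration experiments
```

The meta-analysis step prints (this exact run):

```
overall (4 cohorts, 4800 individuals, 1933 deaths):
  risk change per +1 SD heterozygosity: +1.56% (HR 0.9844)
  Stouffer Z = -0.66, p = 0.508
  heterogeneity: Q = 1.88 (df 3), I^2 = 0%
  between-ancestry difference: p = 0.35
  between-cause difference: p = 0.72
  between-sex difference: p = 0.69
  between-chromosome difference: p = 0.15
```

Reading: the pooled standardized estimate recovers the planted ~2% risk
reduction per SD of heterozygosity (at this sample size the Stouffer
test is under-powered, as expected — detecting a 2% per-SD effect takes
tens of thousands of deaths); there is no heterogeneity across cohorts
and no subgroup difference, matching how the data were generated.  The
calibration step then shows the point of the design: inverse-variance
pooling of *raw* betas across arrays with 1k vs 8k SNPs lands at −6.9
(a scale artifact), while the SD-standardized pool lands at −0.21
against a truth of −0.22, and end-to-end CIs cover the truth at ~95%.

A `hetsurv` CLI exposes the same stages for external data
(`hetsurv simulate|qc-snps|qc-samples|het|cox|meta|run --help`).

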