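# imputeqc

Genotype imputation and imputation quality control for inbred diploid panels
(for example *Arabidopsis thaliana* accessions), with a cross-validation
estimator of per-variant imputation accuracy, validation machinery that
compares that estimator against the model-based allelic R² (AR2), and a
mixed-model GWAS to assess downstream consequences of imputation quality.

## The problem

A large *reference panel* of inbred accessions is fully sequenced; a larger
*target panel* is genotyped only at a sparse set of chip SNPs. Imputation
fills in the untyped variants in the target panel by exploiting haplotype
sharing with the reference. Two questions then matter in practice:

1. **How accurate is each imputed variant?** Imputation software reports a
   model-based quality score (AR2), but AR2 is computed from the imputation's
   own posterior probabilities and inherits its model assumptions. An
   alternative is empirical: repeatedly split the reference panel in half,
   hide the non-chip variants in one half, impute them from the other half,
   and record the fraction recovered correctly — the **CV accuracy** of each
   variant.
2. **Which variants should be kept?** Thresholding on the per-variant CV
   accuracy removes poorly imputed variants before downstream analyses such
   as genome-wide association.

This package provides the full loop on synthetic panels with known truth:
panel simulation, a haplotype-copying imputer, accuracy metrics, the CV
estimator, an outer validation study (how well do CV accuracy and AR2 predict
the accuracy actually observed on held-out accessions?), QC thresholding, and
an EMMAX-style linear mixed-model association scan.

## Model and statistics

**Genotypes.** Inbred accessions are effectively haploid: dosages are 0 or 2
(heterozygotes are unexpected and handled by policy), missing is a sentinel.

**Imputation.** A haploid Li–Stephens haplotype-copying HMM: the hidden state
is which of the *H* reference haplotypes the target copies at each site;
between adjacent sites at genetic distance *d* bp the copying haplotype
switches with probability ρ(d) = 1 − exp(−4·Nₑ·r·d / H), uniformly over
haplotypes; emission matches the copied allele with probability 1 − ε. The
posterior allele probability q at each untyped site comes from a scaled
forward–backward pass; the genotype posterior is (1 − q, 0, q) and the call
is the argmax. Chromosomes are processed in overlapping windows (200 kb,
12 kb overlap by default) with each variant taken from its nearest window
center.

**Accuracy metrics.** Per variant, over evaluated (held-out) cells:
SNP accuracy = fraction of correct calls; minor-allele (resp. major-allele)
accuracy = the same fraction restricted to accessions carrying the minor
(resp. major) allele. These satisfy the identity
`snp = minor·MAF + major·(1 − MAF)` where MAF is measured over the evaluated
cells. Summaries are reported by MAF class and in 100 kb genomic bins.

**AR2.** The squared correlation between best-guess dosage and expected
dosage implied by the posteriors, the standard allelic-R² estimator.

**CV accuracy.** 30 rounds (default) of random equal halving of the
reference panel; in each round the non-chip variants of one half are hidden
and imputed from the other half; per-variant accuracy is averaged over
rounds.

**Validation.** Outer splits hold out 20 % of accessions as a pseudo-target
panel with known truth; observed accuracies there are correlated (Pearson,
per MAF class) with the inner-CV accuracy and with AR2. A calibration table
bins imputed cells by maximum posterior probability and compares the
empirical correct fraction to the bin midpoint.

**GWAS.** y = α + xβ + u + e with u ~ N(0, σ²_A·K), e ~ N(0, σ²_E·I), K the
centered dosage cross-product kinship. Variance components are fit once on
the null model by ML in the eigenbasis of K (EMMAX approximation); each
marker is tested by GLS with per-marker residual scale (t-test, n − 2 df), so
with the kinship path disabled the test reduces exactly to OLS. Genome-wide
thresholds: Bonferroni −log10(0.05/m) and the 95th percentile of the maximum
−log10 p over 200 phenotype permutations.

## Worked example

`examples/01_simulate_and_impute.py` simulates 120 accessions × 1500 variants
from a mosaic-of-founders model, keeps 100 accessions as reference, types the
remaining 20 on the 30 % chip only, and imputes the rest:

```
imputed 21000 genotypes at 1050 untyped variants
mean SNP accuracy:          0.9711
mean minor-allele accuracy: 0.8319
mean major-allele accuracy: 0.9890

accuracy by MAF class (rare variants are hardest):
  maf_class  n_variants  snp_accuracy_mean  minor_allele_accuracy_mean
[0.01,0.05)           0                NaN                         NaN
 [0.05,0.1)          97           0.981959                    0.680412
 [0.1,0.25)         242           0.967975                    0.816116
 [0.25,0.5)         368           0.943342                    0.882271
```

`examples/02_cv_accuracy.py` checks the CV estimator against an imputer with
known per-variant error rates:

```
840 untyped variants, 30 CV rounds of random panel halving
mean |CV accuracy - true accuracy|: 0.0061
max  |CV accuracy - true accuracy|: 0.0295
corr(CV accuracy, true accuracy):   0.9976
```

`examples/04_qc_filtering.py` shows QC thresholding: filtering at CV ≥ 0.90
retains 76.6 % of variants and lifts the mean observed SNP accuracy of the
retained set from 0.9335 to 1.0000 in that scenario.

`examples/05_gwas.py` plants a causal effect at a common marker and recovers
it (−log10 p = 9.89 against a Bonferroni threshold of 4.03 and a permutation
threshold of 3.49); `examples/03_validate_estimators.py` runs a small
estimator-validation study and a calibration check.

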