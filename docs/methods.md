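# Methods note

This note records the statistical model, the parameter choices and their
rationale, what the synthetic-data generator does and does not emulate, and
the numerical decisions made in the implementation. No empirical claim here
goes beyond what the test suite and `scripts/acceptance.py` compute.

## Genotype model

Panels are inbred diploids: each accession is effectively a single haplotype
and dosages take values in {0, 2}. Heterozygous calls are unexpected; VCF
reading offers three policies (`missing` — the default, set the cell missing;
`drop_variant`; `keep`). Missingness is a sentinel value (−1) in an int8
matrix of shape (accessions × variants). Multi-allelic records and indels are
skipped at read time and counted.

## Haplotype-copying imputation

The imputer is a haploid Li–Stephens copying HMM.

- **States**: the H reference haplotypes.
- **Transitions**: between adjacent reference sites separated by d bp the
  chain switches to a uniformly chosen haplotype with probability
  ρ(d) = 1 − exp(−4·Nₑ·r·d / H), else stays. Because the switch destination
  is uniform, the transition is a rank-one update and the forward/backward
  recursions cost O(H) per site rather than O(H²).
- **Emissions**: the observed allele equals the copied haplotype's allele
  with probability 1 − ε, otherwise ε. Sites untyped in the target emit
  uniformly (no information). Missing *reference* alleles emit 0.5 and
  contribute 0.5 to the posterior allele expectation.
- **Posterior**: a scaled linear-space forward–backward pass yields the
  copying-state posterior; the allele posterior q is the expectation of the
  copied allele; the genotype posterior is (1 − q, 0, q).

Defaults: ε = 10⁻³ (a generic genotyping/copying error rate; results are
insensitive to its order of magnitude), Nₑ = 250 000 and r = 10⁻⁸ per bp
(standard effective-population-size and recombination-rate figures for
selfing Arabidopsis panels; their product sets the switch-rate scale),
windows of 200 kb with 12 kb overlap (matching common imputation-software
window defaults; each variant's posterior is taken from the window whose
center is nearest, ties going to the earlier window). Typed target sites pass
through unchanged with point-mass posteriors.

**Numerical choice — scaling vs log space.** The forward–backward pass uses
per-site scaling in linear space (normalizing α each site and carrying the
same convention through β). This is the numerically standard alternative to
log-space recursions: it avoids per-site log/exp costs, and the rank-one
transition keeps everything vectorizable over target accessions. The
implementation was verified against exhaustive path enumeration on small
instances (max abs error ≈ 3×10⁻¹⁵; enforced to 10⁻¹⁰ in the acceptance
suite).

**Decoding.** Best-guess genotype is the posterior argmax; a heterozygous
argmax (impossible here but allowed by the data type) falls back to the
larger of the two homozygous masses; an exact p₀ = p₂ tie decodes to 0 and is
logged. For (p, 0, 1 − p) posteriors this reduces to `0 if p0 ≥ p2 else 2`.

## Accuracy metrics

Per variant over evaluated cells (truth non-missing, inside the evaluation
mask): SNP accuracy, minor-allele accuracy and major-allele accuracy, with
MAF measured over the same cells. The exact decomposition
snp = minor·MAF + major·(1 − MAF) holds by construction and is enforced as a
property test (10⁻¹² tolerance) on randomized records. Summaries use MAF
classes [0.01, 0.05), [0.05, 0.1), [0.1, 0.25), [0.25, 0.5] (last edge
closed) and 100 kb genomic bins flagged when mean SNP accuracy < 0.95.
Quantiles use the `median_unbiased` estimator.

## AR2

For each variant, with best-guess dosage b and posterior-expected dosage
e = p₁ + 2p₂ and second moment z = p₁ + 4p₂ over the imputed cells,
AR2 = [Σbe − ΣbΣe/n]² / ([Σb² − (Σb)²/n]·[Σz − (Σe)²/n]), NaN when either
variance term is ≤ 10⁻¹². This matches the standard allelic-R² estimator
computed by imputation software; it is verified against an independent
compensated-summation evaluation of the same formula.

## CV accuracy estimator

`make_split_plans` draws 30 rounds (default) of random equal halving of the
reference accessions (⌈n/2⌉ / ⌊n/2⌋). Per round, the non-chip variants of the
target half are hidden and imputed from the other half; per-variant correct
fractions are averaged over rounds (NaN-safe: a variant absent from a round
contributes nothing). The estimator's bookkeeping is validated against mock
imputers with known per-variant and per-accession error rates, including a
closed-form case with deterministic (rate-1) accession errors.

## Validation study

Outer splits (default 40; desk-scale runs use 5) hold out 20 % of accessions,
impute their non-chip variants from the rest, and record observed accuracies,
the run's AR2 and the inner-CV accuracies (computed within the training set).
Pearson correlations of each estimator with each observed accuracy are
computed per MAF class (NaN when fewer than 3 finite pairs or zero variance)
and averaged over splits. Calibration bins evaluated cells by maximum
posterior into (lo, hi] bins of width 0.05. A chip-only target panel can be
assessed by a half-split scheme with role swap, masking 20 % of chip SNPs.

## QC thresholding

Variants are retained when CV accuracy ≥ threshold (grid 0.80–0.95).
Summaries report the distribution of observed accuracies over retained
variants and the fraction "accurate" (observed SNP accuracy strictly > 0.95).
Monotonicity of retention in the threshold is a property test.

## Mixed-model GWAS

EMMAX-style: variance components (σ²_A, σ²_E) are estimated once on the null
model y = α + u + e by profiled ML over δ = σ²_E/σ²_A in the eigenbasis of
the kinship matrix K (centered dosage cross-product over marker count,
mean-imputed missing dosages), with log δ bounded in [−12, 12] and the upper
boundary mapped to σ²_A = 0. Each marker is then tested by GLS with the null
covariance fixed but the residual scale re-estimated per marker, giving a
two-sided t-test on n − 2 df. This per-marker rescaling makes the K = None
path *exactly* per-marker OLS (enforced to 10⁻¹⁰), at the cost of a slight
departure from the textbook EMMAX Wald test. Markers below the MAF floor
(0.05 default) are skipped. Thresholds: Bonferroni −log10(0.05/m) over the m
tested markers, and the empirical 95th percentile of the per-permutation
maximum −log10 p over 200 phenotype permutations.

## Synthetic panel generator

Accessions are mosaics of F founder haplotypes: founder allele frequencies
are Beta(0.5, 0.5) (U-shaped, so both rare and common variants exist after
folding to MAF), positions are uniform without replacement on the chromosome,
founder segments switch at rate 10⁻⁵ per bp (mean segment 100 kb, comparable
to the HMM's switch-rate scale 4·Nₑ·r/H), and per-site mutations flip alleles
at rate 10⁻³. Defaults: 20 founders, 200 accessions, 3000 variants on 1 Mb,
30 % of variants on the chip. These sizes are the package's own desk-scale
choice: large enough that MAF classes are populated and the HMM has real
haplotype sharing to exploit, small enough that the full validation loop runs
in seconds to minutes.

**What the generator emulates**: haplotype sharing, LD decay with distance,
a realistic folded allele-frequency spectrum, chip-vs-untyped structure, and
controlled ground truth for every estimator.

**What it does not emulate**: spatial heterogeneity. Recombination intensity
is a single scalar, there are no centromeres, SNP-density troughs or
reference-bias hotspots, so imputation difficulty is nearly uniform along the
chromosome. One consequence is measured, not hypothesized: major-allele
accuracy at low MAF is ≈ 0.999 everywhere, its per-split observed variation
is mostly binomial noise over the ~40 test accessions, and AR2 — computed
from the *same* imputation run as the observed accuracy — correlates with
that noise while the CV estimate (independent inner splits) cannot. On this
generator CV therefore does not out-predict AR2 for *major*-allele accuracy
in the lowest MAF class, while it clearly does for *minor*-allele accuracy
(acceptance run, seed 1: correlations 0.59 vs 0.19 for minor; 0.09 vs 0.17
for major). On real panels, where difficulty is spatially heterogeneous and
many markers impute far below 0.95, the variant-intrinsic signal that CV
captures is much larger. The corresponding acceptance test asserts the
directional claim for major-allele accuracy and is left failing rather than
retuning the generator after the fact.

**Mock imputers**: return the truth at masked cells flipped with controlled
per-variant/per-accession rates (combined as 1 − (1−p_v)(1−p_a)). With
`honest_posteriors` the stated confidence is 1 − rate on the returned call,
making the mock perfectly calibrated by construction — the oracle for the
calibration machinery.

## Limitations

- Haploid-only HMM: no heterozygote posteriors, no phasing of outbred data.
- The EMMAX approximation fixes variance components at the null; markers
  explaining a large trait fraction get slightly conservative/liberal tests
  relative to exact per-marker REML.
- AR2-vs-CV comparisons on this generator understate CV's advantage for the
  reasons above; conclusions about real panels should come from real panels.
- Window stitching takes each variant from one window (nearest center); no
  posterior averaging across overlapping windows.
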