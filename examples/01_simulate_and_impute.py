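"""Simulate an inbred panel, hide the non-chip variants in some accessions,
impute them back with the haplotype-copying HMM, and score the result."""

import numpy as np

from imputeqc import (MISSING, HaplotypeCopyingImputer, SimConfig,
                      score_variants, simulate_panel, summarize_by_maf_class)

truth = simulate_panel(SimConfig(n_accessions=120, n_variants=1500, seed=5))
panel = truth.full_panel
chip = set(truth.chip_variant_ids)
masked_ids = [v for v in panel.vids if v not in chip]

# 100 reference accessions with full genotypes, 20 targets typed on the chip only
reference = panel.subset(accessions=panel.accessions[:100])
target_truth = panel.subset(accessions=panel.accessions[100:])
target = target_truth.copy()
target.dosages[:, target.variant_index(masked_ids)] = MISSING

result = HaplotypeCopyingImputer()(reference, target)

mask = target.dosages == MISSING
records = score_variants(target_truth, result.best_guess, mask=mask)
records = records[records.vid.isin(set(masked_ids))]
print(f"imputed {mask.sum()} genotypes at {len(records)} untyped variants")
print(f"mean SNP accuracy:          {records.snp_accuracy.mean():.4f}")
print(f"mean minor-allele accuracy: {records.minor_allele_accuracy.mean():.4f}")
print(f"mean major-allele accuracy: {records.major_allele_accuracy.mean():.4f}")

print("\naccuracy by MAF class (rare variants are hardest):")
cols = ["maf_class", "n_variants", "snp_accuracy_mean", "minor_allele_accuracy_mean"]
print(summarize_by_maf_class(records)[cols].to_string(index=False))
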