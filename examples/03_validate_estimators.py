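"""Compare two accuracy estimators — inner-CV accuracy and the allelic
R-squared (AR2) from posterior probabilities — as predictors of the accuracy
actually observed on held-out accessions, and check posterior calibration."""

import numpy as np

from imputeqc import (HaplotypeCopyingImputer, SimConfig, calibration,
                      mock_imputer, outer_validation, simulate_panel)

truth = simulate_panel(SimConfig(n_accessions=120, n_variants=1200, seed=4))

report = outer_validation(truth.full_panel, truth.chip_variant_ids,
                          HaplotypeCopyingImputer(), n_splits=3,
                          inner_rounds=8, seed=0)
mc = report.mean_correlations()
print("mean Pearson correlation with observed accuracy, per MAF class:")
sel = mc[mc.metric == "minor_allele_accuracy"]
print(sel.pivot(index="maf_class", columns="estimator",
                values="correlation").round(3).to_string())

# calibration: an imputer with honest posteriors lands on the diagonal
rng = np.random.default_rng(7)
panel = truth.full_panel
rates = dict(zip(panel.vids, rng.uniform(0.0, 0.5, panel.n_variants)))
honest = mock_imputer(panel, variant_error=rates, seed=8, honest_posteriors=True)
target = panel.copy()
target.dosages[:] = -1
res = honest(panel, target)
table = calibration(res.posteriors, panel, np.ones(panel.dosages.shape, bool))
big = table[table.n_cells >= 500]
dev = np.abs(big.empirical_correct_fraction - big.bin_mid)
print(f"\ncalibration of an honest imputer over {big.n_cells.sum()} cells:")
print(f"max |empirical correctness - bin midpoint| = {dev.max():.4f}")
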