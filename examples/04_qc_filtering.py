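"""Quality control: retain only variants whose CV accuracy clears a
threshold, and report how the observed accuracy distribution improves."""

import numpy as np

from imputeqc import (SimConfig, cv_accuracy, filter_by_cv, make_split_plans,
                      mock_imputer, qc_summary, score_variants, simulate_panel)

truth = simulate_panel(SimConfig(n_accessions=150, n_variants=1500, seed=6))
panel = truth.full_panel
chip = set(truth.chip_variant_ids)
masked_ids = [v for v in panel.vids if v not in chip]

# an imputer that is poor at some variants and perfect at others
rng = np.random.default_rng(0)
rates = dict(zip(masked_ids,
                 np.where(rng.random(len(masked_ids)) < 0.25,
                          rng.uniform(0.1, 0.5, len(masked_ids)), 0.0)))
imputer = mock_imputer(panel, variant_error=rates, seed=1)

plans = make_split_plans(panel, chip, n_rounds=30, seed=2)
cv = cv_accuracy(panel, chip, imputer, plans)

# observed accuracy on a separate realization of the same error process
target = panel.copy()
target.dosages[:, target.variant_index(masked_ids)] = -1
res = mock_imputer(panel, variant_error=rates, seed=99)(panel, target)
obs = score_variants(panel, res.best_guess, mask=target.dosages == -1)
obs = obs[obs.vid.isin(set(masked_ids))]

summary = qc_summary(cv, obs)
snp = summary[summary.metric == "snp_accuracy"]
cols = ["threshold", "n_retained", "pct_retained", "mean", "q05", "pct_accurate"]
print("observed SNP accuracy of retained variants per CV threshold")
print("(threshold NaN = no filtering):")
print(snp[cols].round(4).to_string(index=False))

kept = filter_by_cv(cv, 0.95)
print(f"\nfilter_by_cv(0.95) keeps {len(kept)} of {len(cv)} untyped variants")
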