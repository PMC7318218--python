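"""Quality control of imputed variants by CV-accuracy thresholding.

A variant is retained iff its CV accuracy is at or above the threshold
(variants *below* the threshold are removed, so equality keeps).  Summary
tables report, per threshold, the distribution of the observed accuracies
over retained variants, the fraction of retained variants that are
"accurate" (observed SNP accuracy strictly above a cutoff, 0.95 by default)
and the fraction of all variants retained.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import PanelError

DEFAULT_THRESHOLD_GRID = [0.80, 0.85, 0.90, 0.95]
DEFAULT_ACCURATE_CUTOFF = 0.95


def filter_by_cv(cv_records: pd.DataFrame, threshold: float) -> set[str]:
    """Variant ids with cv_accuracy >= threshold (NaN removed)."""
    if not 0.0 <= threshold <= 1.0:
        raise PanelError("threshold must be in [0, 1]")
    acc = cv_records["cv_accuracy"].to_numpy(float)
    keep = np.isfinite(acc) & (acc >= threshold)
    return set(cv_records["vid"].to_numpy()[keep])


def qc_summary(cv_records: pd.DataFrame, observed_records: pd.DataFrame,
               thresholds=DEFAULT_THRESHOLD_GRID,
               accurate_cutoff: float = DEFAULT_ACCURATE_CUTOFF) -> pd.DataFrame:
    """Retention summaries over a grid of CV-accuracy thresholds.

    One row per threshold and metric, plus no-filter rows (threshold NaN).
    Statistics (mean, SD, 5% and 10% quantiles, median-unbiased) are computed
    over the *observed* records of retained variants.  ``pct_accurate`` is
    the fraction of retained variants whose observed SNP accuracy is strictly
    above ``accurate_cutoff``; ``pct_retained`` is relative to all variants
    in ``observed_records``.
    """
    obs = observed_records.set_index("vid")
    n_all = len(obs)
    rows = []
    for thr in [None] + list(thresholds):
        if thr is None:
            retained = list(obs.index)
        else:
            keep = filter_by_cv(cv_records, thr)
            retained = [v for v in obs.index if v in keep]
        sub = obs.loc[retained]
        snp = sub["snp_accuracy"].to_numpy(float)
        snp_ok = snp[np.isfinite(snp)]
        n_acc = int((snp_ok > accurate_cutoff).sum())
        for metric in ("snp_accuracy", "minor_allele_accuracy", "major_allele_accuracy"):
            vals = sub[metric].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            rows.append({
                "threshold": np.nan if thr is None else thr,
                "metric": metric,
                "mean": vals.mean() if len(vals) else np.nan,
                "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                "q05": np.quantile(vals, 0.05, method="median_unbiased") if len(vals) else np.nan,
                "q10": np.quantile(vals, 0.10, method="median_unbiased") if len(vals) else np.nan,
                "n_retained": len(retained),
                "n_accurate": n_acc,
                "pct_accurate": n_acc / len(snp_ok) if len(snp_ok) else np.nan,
                "pct_retained": len(retained) / n_all if n_all else np.nan,
            })
    return pd.DataFrame(rows)
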