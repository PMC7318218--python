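"""Outer validation of accuracy estimators and posterior calibration.

Two per-variant estimators of imputation accuracy are compared as predictors
of the accuracy actually observed on held-out accessions: the allelic
R-squared (AR2) computed from posterior genotype probabilities, and the
cross-validation (CV) accuracy computed by inner masking rounds within the
training set.  Per outer split the panel is divided into test and training
accessions (20% / 80% by default, 40 splits), non-chip variants are hidden
in the test set and imputed from the training set, and per MAF class the
Pearson correlation of each estimator with each observed accuracy is
recorded.

A calibration table bins imputed genotypes by their maximum posterior
probability and reports the empirical fraction decoded correctly per bin; a
well-calibrated imputer puts that fraction at the bin midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accuracy import DEFAULT_MAF_EDGES, assign_maf_class, maf_class_labels, score_accessions, score_variants
from .cv import cv_accuracy, make_split_plans
from .genotype_io import MISSING, GenotypePanel, PanelError, PosteriorGenotypes
from .hmm import decode_genotype


@dataclass
class ValidationReport:
    """Per-split observed/estimated accuracy tables and per-class correlations."""

    per_split: list[pd.DataFrame]          # merged observed + ar2 + cv per variant
    correlations: pd.DataFrame             # split x maf_class x estimator x metric
    maf_class_edges: list[float]

    def mean_correlations(self) -> pd.DataFrame:
        """Average correlations over splits, per class/estimator/metric."""
        return (self.correlations
                .groupby(["maf_class", "estimator", "metric"], sort=False)["correlation"]
                .mean().reset_index())


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return np.nan
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def outer_validation(reference: GenotypePanel, chip_variants, imputer,
                     n_splits: int = 40, test_fraction: float = 0.2,
                     inner_rounds: int = 30, seed: int = 0,
                     maf_class_edges=DEFAULT_MAF_EDGES) -> ValidationReport:
    """Compare AR2 and CV accuracy as predictors of observed accuracy.

    Per split: a random ``test_fraction`` of accessions forms the test set;
    non-chip variants are hidden there and imputed from the remaining
    training accessions; observed per-variant accuracies, the imputation's
    AR2, and the inner-CV accuracies (``inner_rounds`` rounds within the
    training set) are collected; Pearson correlations of each estimator with
    each observed accuracy are computed per MAF class over variants where
    both are defined.
    """
    if not 0.0 < test_fraction < 1.0:
        raise PanelError("test_fraction must be in (0, 1)")
    chip = set(chip_variants)
    masked_ids = [v for v in reference.vids if v not in chip]
    rng = np.random.default_rng(seed)
    n = reference.n_accessions
    n_test = max(1, int(round(test_fraction * n)))

    pairs = [("cv_accuracy", "snp_accuracy"),
             ("cv_minor_accuracy", "minor_allele_accuracy"),
             ("cv_major_accuracy", "major_allele_accuracy"),
             ("ar2", "snp_accuracy"),
             ("ar2", "minor_allele_accuracy"),
             ("ar2", "major_allele_accuracy")]

    per_split, corr_rows = [], []
    labels = maf_class_labels(maf_class_edges)
    for split in range(n_splits):
        perm = rng.permutation(n)
        test_ids = [reference.accessions[i] for i in perm[:n_test]]
        train_ids = [reference.accessions[i] for i in perm[n_test:]]
        train = reference.subset(accessions=train_ids)
        truth = reference.subset(accessions=test_ids)
        target = truth.copy()
        target.dosages[:, target.variant_index(masked_ids)] = MISSING
        result = imputer(train, target)

        mask = np.zeros(truth.dosages.shape, dtype=bool)
        mcols = truth.variant_index(masked_ids)
        mask[:, mcols] = truth.dosages[:, mcols] != MISSING
        imputed = result.best_guess.subset(variant_ids=truth.vids)
        obs = score_variants(truth, imputed, mask=mask).set_index("vid")

        ar2 = pd.Series(result.ar2, index=result.best_guess.vids).reindex(obs.index)
        inner_seed = int(rng.integers(0, 2**31 - 1))
        plans = make_split_plans(train, chip, n_rounds=inner_rounds, seed=inner_seed)
        cv = cv_accuracy(train, chip, imputer, plans).set_index("vid")

        table = obs.copy()
        table["ar2"] = ar2
        for c in ("cv_accuracy", "cv_minor_accuracy", "cv_major_accuracy"):
            table[c] = cv[c].reindex(obs.index)
        table["split"] = split
        per_split.append(table.reset_index())

        sub = table.loc[table.index.isin(set(masked_ids))]
        cls = assign_maf_class(sub["maf"].to_numpy(), maf_class_edges)
        for c, label in enumerate(labels):
            grp = sub[cls == c]
            for est, met in pairs:
                x, y = grp[est].to_numpy(float), grp[met].to_numpy(float)
                ok = np.isfinite(x) & np.isfinite(y)
                corr_rows.append({
                    "split": split, "maf_class": label, "estimator": est,
                    "metric": met, "n": int(ok.sum()),
                    "correlation": _pearson(x, y),
                })
    return ValidationReport(per_split, pd.DataFrame(corr_rows), list(maf_class_edges))


DEFAULT_CALIBRATION_EDGES = np.round(np.arange(0.0, 1.0001, 0.05), 10)


def calibration(posteriors: PosteriorGenotypes, truth: GenotypePanel, mask,
                bin_edges=DEFAULT_CALIBRATION_EDGES) -> pd.DataFrame:
    """Reliability table of posterior confidence versus correctness.

    Each evaluated cell contributes its maximum posterior probability and an
    indicator that the decoded genotype equals the truth; cells are binned by
    that probability into (lo, hi] bins over (0, 1].  Empty bins are emitted
    with ``n_cells`` 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != truth.dosages.shape:
        raise PanelError("mask shape mismatch")
    mask = mask & (truth.dosages != MISSING)
    rows, cols = np.nonzero(mask)
    p = posteriors.probs[rows, cols]            # (k, 3)
    maxp = p.max(axis=1)
    # the decode rule reduces to comparing the homozygous posteriors: a
    # heterozygous argmax falls back to the larger of p0/p2, ties go to 0
    decoded = np.where(p[:, 0] >= p[:, 2], 0, 2)
    correct = decoded == truth.dosages[rows, cols]
    edges = np.asarray(bin_edges, dtype=float)
    which = np.searchsorted(edges, maxp, side="left") - 1
    which = np.clip(which, 0, len(edges) - 2)
    out = []
    for b in range(len(edges) - 1):
        sel = which == b
        n = int(sel.sum())
        out.append({
            "bin_lo": edges[b], "bin_hi": edges[b + 1],
            "bin_mid": (edges[b] + edges[b + 1]) / 2.0,
            "n_cells": n,
            "empirical_correct_fraction": float(correct[sel].mean()) if n else np.nan,
        })
    return pd.DataFrame(out)


def target_panel_validation(target_chip_panel: GenotypePanel, imputer,
                            mask_fraction: float = 0.2, seed: int = 0) -> pd.DataFrame:
    """Half-split accession-accuracy scheme for a chip-only panel.

    The accessions are halved; in the target half a uniform random
    ``mask_fraction`` of the chip variants is hidden and imputed from the
    other half, and per-accession accuracy is scored on the masked cells.
    Roles are then swapped so every accession is scored.
    """
    if not 0.0 < mask_fraction < 1.0:
        raise PanelError("mask_fraction must be in (0, 1)")
    panel = target_chip_panel
    if panel.n_accessions < 4:
        raise PanelError("need at least 4 accessions")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(panel.n_accessions)
    half = (panel.n_accessions + 1) // 2
    groups = [perm[:half], perm[half:]]
    records = []
    for g in (0, 1):
        ref_ids = [panel.accessions[i] for i in groups[1 - g]]
        tgt_ids = [panel.accessions[i] for i in groups[g]]
        ref = panel.subset(accessions=ref_ids)
        truth = panel.subset(accessions=tgt_ids)
        n_mask = int(round(mask_fraction * panel.n_variants))
        mcols = np.sort(rng.choice(panel.n_variants, size=n_mask, replace=False))
        target = truth.copy()
        target.dosages[:, mcols] = MISSING
        result = imputer(ref, target)
        mask = np.zeros(truth.dosages.shape, dtype=bool)
        mask[:, mcols] = truth.dosages[:, mcols] != MISSING
        imputed = result.best_guess.subset(variant_ids=truth.vids)
        rec = score_accessions(truth, imputed, mask=mask)
        rec["role_swap"] = g
        records.append(rec)
    return pd.concat(records, ignore_index=True)
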