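"""Cross-validation estimate of per-variant imputation accuracy.

The accuracy of imputing a variant into chip-typed accessions cannot be
observed directly (the truth is unknown), but it can be estimated inside the
sequenced reference panel: repeatedly split the reference accessions into
equally large inner reference and inner target halves, hide the non-chip
variants in the inner target, impute them from the inner reference, and
average the observed accuracy over rounds (30 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accuracy import score_variants
from .genotype_io import MISSING, GenotypePanel, PanelError

DEFAULT_ROUNDS = 30


@dataclass
class SplitPlan:
    """One masking round: a random halving of the reference accessions."""

    round: int
    inner_reference_ids: list[str]
    inner_target_ids: list[str]
    masked_variant_ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        if set(self.inner_reference_ids) & set(self.inner_target_ids):
            raise PanelError("inner reference and target sets overlap")
        if abs(len(self.inner_reference_ids) - len(self.inner_target_ids)) > 1:
            raise PanelError("split halves differ by more than one accession")


def make_split_plans(reference: GenotypePanel, chip_variants, n_rounds: int = DEFAULT_ROUNDS,
                     seed: int = 0) -> list[SplitPlan]:
    """Independent uniform random halvings of the reference accessions.

    With an odd accession count, the extra accession goes to the inner
    reference.  The masked variants are the reference variants absent from
    the chip, identical across rounds.
    """
    if reference.n_accessions < 2:
        raise PanelError("need at least 2 reference accessions to split")
    if n_rounds < 1:
        raise PanelError("n_rounds must be >= 1")
    chip = set(chip_variants)
    unknown = chip - set(reference.vids)
    if unknown:
        raise PanelError(f"chip variants not in reference: {sorted(unknown)[:5]}")
    masked = [v for v in reference.vids if v not in chip]
    rng = np.random.default_rng(seed)
    n = reference.n_accessions
    n_ref = (n + 1) // 2
    plans = []
    for r in range(n_rounds):
        perm = rng.permutation(n)
        plans.append(SplitPlan(
            round=r,
            inner_reference_ids=[reference.accessions[i] for i in perm[:n_ref]],
            inner_target_ids=[reference.accessions[i] for i in perm[n_ref:]],
            masked_variant_ids=masked,
            seed=seed,
        ))
    return plans


def cv_accuracy(reference: GenotypePanel, chip_variants, imputer,
                plans: list[SplitPlan]) -> pd.DataFrame:
    """Round-averaged CV accuracy per non-chip variant.

    Per round, the non-chip variants are hidden in the inner target half and
    imputed from the inner reference half; observed per-variant accuracies
    are then averaged over rounds (NaN rounds excluded, with the usable round
    count recorded per statistic).  Across-round standard deviations are
    reported as diagnostics.
    """
    chip = set(chip_variants)
    masked_ids = [v for v in reference.vids if v not in chip]
    if not masked_ids:
        raise PanelError("no non-chip variants to cross-validate")
    masked_cols = reference.variant_index(masked_ids)

    per_round = {k: [] for k in ("snp_accuracy", "minor_allele_accuracy", "major_allele_accuracy")}
    for plan in plans:
        inner_ref = reference.subset(accessions=plan.inner_reference_ids)
        truth = reference.subset(accessions=plan.inner_target_ids)
        target = truth.copy()
        target.dosages[:, target.variant_index(plan.masked_variant_ids)] = MISSING
        try:
            result = imputer(inner_ref, target)
        except Exception as exc:
            raise RuntimeError(f"imputer failed in CV round {plan.round}: {exc}") from exc
        mask = np.zeros(truth.dosages.shape, dtype=bool)
        mask[:, truth.variant_index(plan.masked_variant_ids)] = truth.dosages[
            :, truth.variant_index(plan.masked_variant_ids)] != MISSING
        imputed = result.best_guess.subset(variant_ids=truth.vids)
        rec = score_variants(truth, imputed, mask=mask)
        rec = rec.set_index("vid")
        for k in per_round:
            per_round[k].append(rec[k].reindex(reference.vids).to_numpy())

    out = {"vid": reference.vids}
    name_map = {"snp_accuracy": "cv_accuracy",
                "minor_allele_accuracy": "cv_minor_accuracy",
                "major_allele_accuracy": "cv_major_accuracy"}
    for k, cvname in name_map.items():
        stack = np.vstack(per_round[k])  # (rounds, variants)
        ok = ~np.isnan(stack)
        n_used = ok.sum(axis=0)
        denom = np.maximum(n_used, 1).astype(float)
        mean = np.where(ok, stack, 0.0).sum(axis=0) / denom
        var = np.where(ok, (np.where(ok, stack, 0.0) - mean[None, :]) ** 2, 0.0).sum(axis=0) / denom
        out[cvname] = np.where(n_used > 0, mean, np.nan)
        out[cvname + "_sd"] = np.where(n_used > 0, np.sqrt(var), np.nan)
        out[cvname + "_n_rounds"] = n_used
    df = pd.DataFrame(out)
    # CV records exist exactly for non-chip reference variants
    return df[df["vid"].isin(set(masked_ids))].reset_index(drop=True)
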