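"""Pre-imputation quality control: merge a chip panel with a sequenced panel.

Chip-genotyped accessions overlap a densely sequenced panel; before imputing
the chip-only accessions, variants typed in both panels must agree on the
shared accessions, chip-only variants are dropped (they cannot be checked or
re-imputed from the reference), and rare variants are removed from the
reference by a minor-allele-frequency threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np

from .genotype_io import MISSING, GenotypePanel, PanelError, allele_frequencies

logger = logging.getLogger(__name__)


@dataclass
class HarmonizationReport:
    n_shared_accessions: int
    n_chip_only_variants_removed: int
    n_inconsistent_variants_removed: int
    n_maf_removed: int
    n_variants_retained_reference: int
    n_variants_available_for_imputation: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _variant_keys(panel: GenotypePanel) -> list[tuple]:
    return list(
        zip(panel.variants["chrom"], panel.variants["pos"], panel.variants["ref"], panel.variants["alt"])
    )


def harmonize(chip: GenotypePanel, seq: GenotypePanel, maf_threshold: float = 0.01):
    """Harmonize a chip panel against a sequenced reference panel.

    Variants are matched by (chrom, pos, ref, alt); a mismatched ref/alt pair
    counts as a different variant (no strand-flip recovery).  A variant shared
    by both panels is removed from both if any shared accession has unequal
    non-missing dosages (missing calls are not discordant).  Chip-only
    variants are removed, then variants with MAF below ``maf_threshold`` in
    the sequenced panel are removed.

    Returns ``(reference, target, report)`` where reference is the sequenced
    panel restricted to retained variants and target holds the chip-only
    accessions at the retained chip variants.
    """
    if len(set(chip.accessions)) != chip.n_accessions or len(set(seq.accessions)) != seq.n_accessions:
        raise PanelError("duplicate accession ids")
    shared_acc = [a for a in chip.accessions if a in set(seq.accessions)]
    if not shared_acc:
        raise PanelError("no shared accessions: consistency check impossible")

    chip_keys = _variant_keys(chip)
    seq_keys = _variant_keys(seq)
    seq_key_to_col = {k: j for j, k in enumerate(seq_keys)}

    chip_rows = chip.accession_index(shared_acc)
    seq_rows = seq.accession_index(shared_acc)

    inconsistent = set()
    shared_variant_keys = []
    chip_only = []
    for jc, key in enumerate(chip_keys):
        js = seq_key_to_col.get(key)
        if js is None:
            chip_only.append(key)
            continue
        shared_variant_keys.append(key)
        c = chip.dosages[chip_rows, jc]
        s = seq.dosages[seq_rows, js]
        both = (c != MISSING) & (s != MISSING)
        if np.any(c[both] != s[both]):
            inconsistent.add(key)

    # reference keeps seq variants that are not inconsistent and pass MAF
    freq = allele_frequencies(seq)
    maf = freq["maf"].to_numpy()
    keep_ref = []
    n_maf_removed = 0
    for j, key in enumerate(seq_keys):
        if key in inconsistent:
            continue
        if not np.isfinite(maf[j]) or maf[j] < maf_threshold:
            n_maf_removed += 1
            continue
        keep_ref.append(j)

    retained_ref_keys = {seq_keys[j] for j in keep_ref}
    keep_chip = [
        j for j, key in enumerate(chip_keys)
        if key not in inconsistent and key in retained_ref_keys
    ]

    reference = seq.subset(variant_ids=[seq.vids[j] for j in keep_ref])
    target_accessions = [a for a in chip.accessions if a not in set(seq.accessions)]
    target = chip.subset(
        accessions=target_accessions,
        variant_ids=[chip.vids[j] for j in keep_chip],
    )
    report = HarmonizationReport(
        n_shared_accessions=len(shared_acc),
        n_chip_only_variants_removed=len(chip_only),
        n_inconsistent_variants_removed=len(inconsistent),
        n_maf_removed=n_maf_removed,
        n_variants_retained_reference=reference.n_variants,
        n_variants_available_for_imputation=target.n_variants,
    )
    logger.info("harmonize report:\n%s", report.to_json())
    return reference, target, report
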