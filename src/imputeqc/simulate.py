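"""Synthetic inbred panels with known truth, plus controllable mock imputers.

Accessions are simulated as mosaics of a small set of founder haplotypes:
founder allele frequencies are drawn from a Beta law, each accession copies
founder segments whose boundaries follow a Poisson recombination process
along the chromosome, and per-site mutations flip alleles at a low rate.
This produces the haplotype sharing and LD decay that haplotype-copying
imputation exploits, with the full truth retained so that every accuracy
estimator can be validated offline.  A random subset of variants plays the
role of the genotyping chip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypePanel, ImputationResult, PanelError, PosteriorGenotypes


@dataclass
class SimConfig:
    """Study conditions for a synthetic panel.

    Defaults are sized for desk-scale experiments: 20 founders, 200
    accessions and 3000 variants on a 1 Mb chromosome, with a U-shaped
    Beta(0.5, 0.5) founder allele-frequency law (plenty of both rare and
    common variants after folding to MAF), a mosaic switch rate of 1e-5 per
    bp (mean founder-segment length 100 kb) and a 1e-3 per-site mutation
    rate.  30% of variants are placed on the simulated chip.
    """

    n_founders: int = 20
    n_accessions: int = 200
    n_variants: int = 3000
    chrom_length_bp: int = 1_000_000
    founder_af_beta: tuple[float, float] = (0.5, 0.5)
    switch_rate_per_bp: float = 1e-5
    mutation_rate: float = 1e-3
    chip_fraction: float = 0.3
    seed: int = 0
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.n_founders < 1:
            raise PanelError("n_founders must be >= 1")
        if not 0.0 <= self.switch_rate_per_bp <= 1.0 or not 0.0 <= self.mutation_rate <= 1.0:
            raise PanelError("rates must be in [0, 1]")
        if not 0.0 < self.chip_fraction <= 1.0:
            raise PanelError("chip_fraction must be in (0, 1]")
        if self.n_variants > self.chrom_length_bp:
            raise PanelError("more variants than base pairs")


@dataclass
class SimTruth:
    """A simulated panel with its chip subset and founder diagnostics."""

    full_panel: GenotypePanel
    chip_variant_ids: list[str]
    founder_assignments: np.ndarray  # (n_accessions, n_variants) founder index
    founder_afs: np.ndarray = field(default=None)  # per-variant Beta draws

    def chip_panel(self) -> GenotypePanel:
        return self.full_panel.subset(variant_ids=self.chip_variant_ids)


def simulate_panel(config: SimConfig) -> SimTruth:
    """Draw a synthetic inbred panel under the mosaic-of-founders model."""
    rng = np.random.default_rng(config.seed)
    m, n, F = config.n_variants, config.n_accessions, config.n_founders

    positions = np.sort(rng.choice(config.chrom_length_bp, size=m, replace=False)) + 1
    a, b = config.founder_af_beta
    founder_afs = rng.beta(a, b, size=m)
    founders = (rng.random((F, m)) < founder_afs[None, :]).astype(np.int8)

    # mosaic copying: switch between consecutive variants with prob 1-exp(-rate*d)
    d = np.diff(positions)
    p_switch = 1.0 - np.exp(-config.switch_rate_per_bp * d)
    assignments = np.empty((n, m), dtype=np.int32)
    assignments[:, 0] = rng.integers(0, F, size=n)
    switches = rng.random((n, m - 1)) < p_switch[None, :]
    new_founders = rng.integers(0, F, size=(n, m - 1))
    for s in range(1, m):
        assignments[:, s] = np.where(switches[:, s - 1], new_founders[:, s - 1],
                                     assignments[:, s - 1])

    alleles = founders[assignments, np.arange(m)[None, :]]
    flips = rng.random((n, m)) < config.mutation_rate
    alleles = np.where(flips, 1 - alleles, alleles).astype(np.int8)

    variants = pd.DataFrame({
        "chrom": config.chrom,
        "pos": positions,
        "ref": "A",
        "alt": "T",
        "vid": [f"{config.chrom}_{p}" for p in positions],
    })
    panel = GenotypePanel(variants, [f"acc{i:04d}" for i in range(n)],
                          alleles * 2, inbred_mode=True)
    n_chip = max(1, int(round(config.chip_fraction * m)))
    chip_cols = np.sort(rng.choice(m, size=n_chip, replace=False))
    chip_ids = [variants["vid"].iloc[j] for j in chip_cols]
    return SimTruth(panel, chip_ids, assignments, founder_afs)


# ---------------------------------------------------------------------------
# Mock imputers


def mock_imputer(truth: GenotypePanel, variant_error=None, accession_error=None,
                 seed: int = 0, honest_posteriors: bool = False):
    """Imputer that returns the truth with controlled, seeded errors.

    ``variant_error`` maps vid -> flip probability (scalar allowed);
    ``accession_error`` maps accession id -> flip probability.  When both are
    given the per-cell rate is ``1 - (1-pv)(1-pa)``.  At each masked cell the
    returned call is the true dosage flipped (0 <-> 2) with the cell's rate.

    Posteriors are point masses on the returned call, or, with
    ``honest_posteriors``, assign probability ``1 - rate`` to the returned
    call and ``rate`` to the alternative, so that the stated confidence
    matches the realized correctness in expectation (a perfectly calibrated
    imputer).
    """
    v_rate = np.zeros(truth.n_variants)
    if variant_error is not None:
        if np.isscalar(variant_error):
            v_rate[:] = float(variant_error)
        else:
            for vid, r in variant_error.items():
                v_rate[truth.variant_index([vid])[0]] = r
    a_rate_full = np.zeros(truth.n_accessions)
    if accession_error is not None:
        if np.isscalar(accession_error):
            a_rate_full[:] = float(accession_error)
        else:
            for acc, r in accession_error.items():
                a_rate_full[truth.accession_index([acc])[0]] = r
    if ((v_rate < 0) | (v_rate > 1)).any() or ((a_rate_full < 0) | (a_rate_full > 1)).any():
        raise PanelError("error rates must be in [0, 1]")
    a_rate_by_id = dict(zip(truth.accessions, a_rate_full))
    rng = np.random.default_rng(seed)

    def imputer(reference: GenotypePanel, target: GenotypePanel) -> ImputationResult:
        cols = truth.variant_index(target.vids)
        rows = truth.accession_index(target.accessions)
        true_d = truth.dosages[np.ix_(rows, cols)]
        rate = 1.0 - (1.0 - v_rate[cols][None, :]) * (
            1.0 - np.array([a_rate_by_id[a] for a in target.accessions])[:, None])
        masked = target.dosages == MISSING
        flip = (rng.random(true_d.shape) < rate) & masked
        call = np.where(flip, 2 - true_d, true_d).astype(np.int8)
        call[~masked] = target.dosages[~masked]

        probs = np.zeros(call.shape + (3,))
        conf = 1.0 - rate if honest_posteriors else np.ones_like(rate)
        conf = np.where(masked, conf, 1.0)
        idx0 = call == 0
        probs[:, :, 0] = np.where(idx0, conf, 1.0 - conf)
        probs[:, :, 2] = np.where(idx0, 1.0 - conf, conf)
        panel = GenotypePanel(target.variants, target.accessions, call, inbred_mode=True)
        post = PosteriorGenotypes(target.variants, target.accessions, probs)
        return ImputationResult(panel, post)

    return imputer


def oracle_imputer(truth: GenotypePanel):
    """Imputer that always returns the truth with point-mass posteriors."""
    return mock_imputer(truth)
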