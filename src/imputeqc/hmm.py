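"""Haploid Li-Stephens haplotype-copying imputation for inbred panels.

Each target accession is modelled as an imperfect mosaic copy of the
reference haplotypes (one haplotype per inbred reference accession, allele =
dosage / 2).  The hidden state at a site is the index of the copied
haplotype; switches between adjacent sites occur with probability

    rho(d) = 1 - exp(-4 * Ne * r * d / H)

for physical distance ``d`` bp, effective population size ``Ne``,
recombination rate ``r`` per bp and ``H`` reference haplotypes, the switch
destination being uniform over haplotypes (the self state receives the
complement).  A typed site emits the observed allele with probability
``1 - eps`` if the copied haplotype matches and ``eps`` otherwise; untyped
sites are uninformative.  Forward-backward posteriors over the copied
haplotype give the posterior alt-allele probability ``q`` at every site, and
the reported genotype posterior is ``(1 - q, 0, q)`` -- the heterozygote has
no mass under the haploid model, though :func:`decode_genotype` still handles
external posteriors where it does.

Chromosomes are processed in overlapping windows; in overlaps the window
whose centre is nearest to the variant provides the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    GenotypePanel,
    ImputationResult,
    PanelError,
    PosteriorGenotypes,
)

logger = logging.getLogger(__name__)


@dataclass
class ImputerConfig:
    """Tuning parameters for the haplotype-copying imputer.

    ``ne``, ``window_bp`` and ``overlap_bp`` default to the values commonly
    used for *A. thaliana* panels (Ne = 250 000, 200 kb windows with 12 kb
    overlap).  ``error_rate`` is the per-site copy-error probability and
    ``recomb_rate_per_bp`` scales the switch probability (default 1e-8 per bp
    per generation, the standard Li-Stephens parameterization).
    """

    error_rate: float = 1e-3
    ne: float = 250_000.0
    window_bp: int = 200_000
    overlap_bp: int = 12_000
    recomb_rate_per_bp: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.error_rate < 0.5:
            raise PanelError("error_rate must be in (0, 0.5)")
        if self.ne <= 0:
            raise PanelError("ne must be positive")
        if self.overlap_bp >= self.window_bp:
            raise PanelError("overlap_bp must be smaller than window_bp")


def switch_probability(d_bp: float, n_haplotypes: int, config: ImputerConfig) -> float:
    """Probability of at least one copying switch across ``d_bp`` base pairs."""
    rate = 4.0 * config.ne * config.recomb_rate_per_bp * d_bp / n_haplotypes
    return 1.0 - np.exp(-rate)


def decode_genotype(triple) -> int:
    """Decode a posterior triple (p0, p1, p2) to a homozygous dosage {0, 2}.

    The argmax genotype wins; if the heterozygote has the highest posterior
    (impossible under the haploid model but possible for external imputers),
    the larger of the two homozygous posteriors wins.  An exact tie
    p0 == p2 is broken toward the reference allele (dosage 0) and logged.
    """
    p0, p1, p2 = triple
    if p1 > p0 and p1 > p2:
        # heterozygous argmax: fall back to the larger homozygous class
        return 0 if p0 >= p2 else 2
    if p0 == p2:
        logger.debug("posterior tie p0 == p2 == %s broken toward reference", p0)
        return 0
    return 0 if p0 > p2 else 2


def estimate_ar2(posteriors: PosteriorGenotypes, best_guess: GenotypePanel,
                 variant_index: int, accession_rows=None) -> float:
    """Allelic R-squared at one variant, estimated from posteriors alone.

    With expected dosage ``e_i = p1 + 2*p2``, expected squared dosage
    ``z_i = p1 + 4*p2`` and best-guess dosage ``b_i``, the estimator is the
    squared correlation between best-guess and (unobserved) true dosage:

        AR2 = [sum(b*e) - sum(b)*sum(e)/n]^2 /
              ( [sum(b^2) - sum(b)^2/n] * [sum(z) - sum(e)^2/n] )

    Returns NaN when fewer than 2 accessions are available or either
    variance term is <= 1e-12.
    """
    if accession_rows is None:
        accession_rows = np.arange(best_guess.n_accessions)
    accession_rows = np.asarray(accession_rows, dtype=int)
    n = accession_rows.size
    if n < 2:
        return np.nan
    p = posteriors.probs[accession_rows, variant_index]
    b = best_guess.dosages[accession_rows, variant_index].astype(float)
    e = p[:, 1] + 2.0 * p[:, 2]
    z = p[:, 1] + 4.0 * p[:, 2]
    num = (b * e).sum() - b.sum() * e.sum() / n
    var_b = (b * b).sum() - b.sum() ** 2 / n
    var_t = z.sum() - e.sum() ** 2 / n
    if var_b <= 1e-12 or var_t <= 1e-12:
        return np.nan
    return float(num * num / (var_b * var_t))


# ---------------------------------------------------------------------------
# Forward-backward core


def _forward_backward(ref_alleles: np.ndarray, obs_alleles: np.ndarray,
                      positions: np.ndarray, config: ImputerConfig) -> np.ndarray:
    """Posterior alt-allele probability for a block of sites.

    Parameters
    ----------
    ref_alleles
        ``(H, S)`` reference haplotype alleles in {0, 1}, -1 for missing.
    obs_alleles
        ``(n_targets, S)`` observed target alleles in {0, 1}, -1 where the
        site is untyped (to be imputed).
    positions
        ``(S,)`` physical positions, ascending.

    Returns ``(n_targets, S)`` posterior probabilities of the alt allele.
    Scaled linear-space forward-backward, vectorized over target accessions.
    """
    H, S = ref_alleles.shape
    n_t = obs_alleles.shape[0]
    eps = config.error_rate

    # emission[i, s, k]: P(obs_i,s | state k); computed lazily per site
    def emission(s: int) -> np.ndarray:
        out = np.ones((n_t, H))
        obs = obs_alleles[:, s]
        typed = obs != -1
        if not typed.any():
            return out
        ref = ref_alleles[:, s]
        match = ref[None, :] == obs[:, None]          # (n_t, H)
        e = np.where(match, 1.0 - eps, eps)
        e[:, ref == -1] = 0.5                         # missing reference call
        out[typed] = e[typed]
        return out

    d = np.diff(positions.astype(float))
    rho = 1.0 - np.exp(-4.0 * config.ne * config.recomb_rate_per_bp * d / H)

    alpha = np.full((n_t, H), 1.0 / H) * emission(0)
    alpha /= alpha.sum(axis=1, keepdims=True)
    alphas = np.empty((S, n_t, H))
    alphas[0] = alpha
    for s in range(1, S):
        r = rho[s - 1]
        alpha = ((1.0 - r) * alpha + r / H) * emission(s)
        alpha /= alpha.sum(axis=1, keepdims=True)
        alphas[s] = alpha

    post = np.empty((n_t, S))
    beta = np.ones((n_t, H))
    gamma = alphas[S - 1] * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    post[:, S - 1] = _allele_expectation(gamma, ref_alleles[:, S - 1])
    for s in range(S - 2, -1, -1):
        r = rho[s]
        eb = emission(s + 1) * beta
        beta = (1.0 - r) * eb + (r / H) * eb.sum(axis=1, keepdims=True)
        beta /= beta.sum(axis=1, keepdims=True)
        gamma = alphas[s] * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        post[:, s] = _allele_expectation(gamma, ref_alleles[:, s])
    return post


def _allele_expectation(gamma: np.ndarray, ref_col: np.ndarray) -> np.ndarray:
    """E[alt allele] under the state posterior; missing ref alleles count 1/2."""
    w = np.where(ref_col == -1, 0.5, ref_col.astype(float))
    return np.clip(gamma @ w, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Window layout


def _windows(positions: np.ndarray, config: ImputerConfig) -> list[tuple[int, int]]:
    """Half-open index ranges of overlapping windows covering all positions."""
    lo, hi = int(positions[0]), int(positions[-1])
    if hi - lo + 1 <= config.window_bp:
        return [(0, len(positions))]
    step = config.window_bp - config.overlap_bp
    out = []
    start = lo
    while start <= hi:
        end = start + config.window_bp
        i = int(np.searchsorted(positions, start, side="left"))
        j = int(np.searchsorted(positions, end, side="left"))
        if j > i:
            out.append((i, j))
        start += step
    return out


def _assign_windows(positions: np.ndarray, windows: list[tuple[int, int]]) -> np.ndarray:
    """Index of the window whose centre is nearest each position (ties: earlier)."""
    centers = np.array([(positions[i] + positions[j - 1]) / 2.0 for i, j in windows])
    n = len(positions)
    assign = np.full(n, -1, dtype=int)
    best = np.full(n, np.inf)
    for w, (i, j) in enumerate(windows):
        dist = np.abs(positions[i:j] - centers[w])
        sel = dist < best[i:j]
        idx = np.arange(i, j)[sel]
        assign[idx] = w
        best[idx] = dist[sel]
    return assign


# ---------------------------------------------------------------------------
# Public imputer


class HaplotypeCopyingImputer:
    """Imputer satisfying the pluggable contract: callable
    ``(reference, target) -> ImputationResult``."""

    def __init__(self, config: ImputerConfig | None = None):
        self.config = config or ImputerConfig()

    def __call__(self, reference: GenotypePanel, target: GenotypePanel) -> ImputationResult:
        return impute(reference, target, self.config)


def impute(reference: GenotypePanel, target: GenotypePanel,
           config: ImputerConfig | None = None) -> ImputationResult:
    """Impute all reference variants into the target accessions.

    The target's typed (non-missing) sites are passed through unchanged with
    point-mass posteriors; every other reference variant receives a posterior
    from the haplotype-copying model and an argmax best guess.  Per-variant
    AR2 is estimated over the accessions that were imputed at that variant.
    """
    config = config or ImputerConfig()
    if reference.n_accessions == 0:
        raise PanelError("reference panel has zero haplotypes")
    if (reference.dosages == 1).any() or (target.dosages == 1).any():
        raise PanelError("haplotype-copying imputation requires inbred panels")

    ref_keys = {k: j for j, k in enumerate(
        zip(reference.variants["chrom"], reference.variants["pos"],
            reference.variants["ref"], reference.variants["alt"]))}
    tgt_keys = list(zip(target.variants["chrom"], target.variants["pos"],
                        target.variants["ref"], target.variants["alt"]))
    try:
        col_of = np.array([ref_keys[k] for k in tgt_keys], dtype=int)
    except KeyError as exc:
        raise PanelError(f"target variant {exc} not in reference") from exc

    n_t = target.n_accessions
    m = reference.n_variants
    # observed alleles on the reference variant grid: -1 = untyped/missing
    obs = np.full((n_t, m), -1, dtype=np.int8)
    obs[:, col_of] = np.where(target.dosages == MISSING, -1, target.dosages // 2)

    ref_alleles = np.where(reference.dosages == MISSING, -1,
                           reference.dosages // 2).astype(np.int8)

    q = np.empty((n_t, m))
    for chrom in pd.unique(reference.variants["chrom"]):
        cols = np.flatnonzero((reference.variants["chrom"] == chrom).to_numpy())
        pos = reference.variants["pos"].to_numpy()[cols]
        wins = _windows(pos, config)
        assign = _assign_windows(pos, wins)
        for w, (i, j) in enumerate(wins):
            mine = np.flatnonzero(assign[i:j] == w)
            if mine.size == 0:
                continue
            post = _forward_backward(ref_alleles[:, cols[i:j]], obs[:, cols[i:j]],
                                     pos[i:j], config)
            q[:, cols[i:j][mine]] = post[:, mine]

    probs = np.zeros((n_t, m, 3))
    probs[:, :, 0] = 1.0 - q
    probs[:, :, 2] = q
    best = np.where(q > 0.5, 2, 0).astype(np.int8)  # tie q == 0.5 -> reference
    # typed sites pass through unchanged
    typed = obs != -1
    best[typed] = (obs[typed] * 2).astype(np.int8)
    probs[typed] = 0.0
    probs[typed, obs[typed] * 2] = 1.0

    best_panel = GenotypePanel(reference.variants, target.accessions, best, inbred_mode=True)
    posteriors = PosteriorGenotypes(reference.variants, target.accessions, probs)
    ar2 = np.full(m, np.nan)
    for j in range(m):
        rows = np.flatnonzero(~typed[:, j])
        if rows.size >= 2:
            ar2[j] = estimate_ar2(posteriors, best_panel, j, rows)
    return ImputationResult(best_panel, posteriors, ar2)
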