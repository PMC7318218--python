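"""Genotype panel containers and VCF input/output.

Panels are bi-allelic SNP matrices over inbred (fully homozygous) diploid
accessions, so genotype dosages live on the diploid scale {0, 2} with 1
reserved for unexpected heterozygous calls and -1 for missing data.  Keeping
the diploid scale (rather than recoding to haploid {0, 1}) keeps VCF GT
fields and downstream effect sizes conventional.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: Sentinel for a missing dosage in integer genotype matrices.
MISSING = -1

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "vid"]


class PanelError(ValueError):
    """Contract violation in a genotype panel or its inputs."""


def _as_variant_frame(variants: pd.DataFrame) -> pd.DataFrame:
    df = variants.reset_index(drop=True).copy()
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns and c != "vid"]
    if missing:
        raise PanelError(f"variant table lacks columns: {missing}")
    if "vid" not in df.columns:
        df["vid"] = df["chrom"].astype(str) + "_" + df["pos"].astype(str)
    return df[VARIANT_COLUMNS]


@dataclass
class GenotypePanel:
    """Accession x variant matrix of allele dosages with variant metadata.

    Parameters
    ----------
    variants
        Data frame with columns chrom, pos (1-based), ref, alt and vid,
        sorted by (chrom, pos) and unique on (chrom, pos).
    accessions
        Unique accession identifiers, one per matrix row.
    dosages
        ``(n_accessions, n_variants)`` integer matrix with values in
        {0, 1, 2, MISSING}.
    inbred_mode
        If set, the panel may not contain dosage 1 anywhere.
    """

    variants: pd.DataFrame
    accessions: list[str]
    dosages: np.ndarray
    inbred_mode: bool = False

    def __post_init__(self) -> None:
        self.variants = _as_variant_frame(self.variants)
        self.accessions = list(self.accessions)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n, m = self.dosages.shape
        if n != len(self.accessions) or m != len(self.variants):
            raise PanelError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.variants)} variants"
            )
        if len(set(self.accessions)) != n:
            raise PanelError("accession ids are not unique")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise PanelError("dosages outside {0,1,2,MISSING}")
        if self.inbred_mode and (self.dosages == 1).any():
            raise PanelError("heterozygous dosage present in inbred panel")
        if (self.variants["pos"] < 1).any():
            raise PanelError("positions must be >= 1")
        key = list(zip(self.variants["chrom"], self.variants["pos"]))
        if len(set(key)) != m:
            raise PanelError("duplicate (chrom, pos)")
        if sorted(key) != key:
            raise PanelError("variants not sorted by (chrom, pos)")

    # -- convenience ------------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def vids(self) -> np.ndarray:
        return self.variants["vid"].to_numpy()

    def accession_index(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accessions)}
        try:
            return np.array([lookup[a] for a in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - contract error path
            raise PanelError(f"unknown accession id {exc}") from exc

    def variant_index(self, vids) -> np.ndarray:
        lookup = {v: j for j, v in enumerate(self.variants["vid"])}
        try:
            return np.array([lookup[v] for v in vids], dtype=int)
        except KeyError as exc:
            raise PanelError(f"unknown variant id {exc}") from exc

    def subset(self, accessions=None, variant_ids=None) -> "GenotypePanel":
        """Restrict the panel to the given accessions and/or variant ids."""
        rows = (
            np.arange(self.n_accessions)
            if accessions is None
            else self.accession_index(accessions)
        )
        cols = (
            np.arange(self.n_variants)
            if variant_ids is None
            else self.variant_index(variant_ids)
        )
        cols = np.sort(cols)
        return GenotypePanel(
            variants=self.variants.iloc[cols],
            accessions=[self.accessions[i] for i in rows],
            dosages=self.dosages[np.ix_(rows, cols)],
            inbred_mode=self.inbred_mode,
        )

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(
            variants=self.variants.copy(),
            accessions=list(self.accessions),
            dosages=self.dosages.copy(),
            inbred_mode=self.inbred_mode,
        )


@dataclass
class PosteriorGenotypes:
    """Posterior probabilities over dosage {0, 1, 2} per accession x variant.

    ``probs`` has shape ``(n_accessions, n_variants, 3)``; every triple is
    non-negative and sums to 1 within 1e-6.
    """

    variants: pd.DataFrame
    accessions: list[str]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.variants = _as_variant_frame(self.variants)
        self.accessions = list(self.accessions)
        self.probs = np.asarray(self.probs, dtype=float)
        n, m, k = self.probs.shape
        if k != 3 or n != len(self.accessions) or m != len(self.variants):
            raise PanelError("posterior array shape mismatch")
        if (self.probs < -1e-12).any():
            raise PanelError("negative posterior probability")
        if not np.allclose(self.probs.sum(axis=2), 1.0, atol=1e-6):
            raise PanelError("posterior triples do not sum to 1")


@dataclass
class ImputationResult:
    """Decoded best-guess panel, its posteriors, and per-variant AR2."""

    best_guess: GenotypePanel
    posteriors: PosteriorGenotypes
    ar2: np.ndarray = field(default=None)  # per-variant, NaN where undefined

    def __post_init__(self) -> None:
        if self.ar2 is None:
            self.ar2 = np.full(self.best_guess.n_variants, np.nan)
        self.ar2 = np.asarray(self.ar2, dtype=float)
        if self.ar2.shape != (self.best_guess.n_variants,):
            raise PanelError("ar2 length mismatch")


# ---------------------------------------------------------------------------
# Allele frequencies


def allele_frequencies(panel: GenotypePanel) -> pd.DataFrame:
    """Per-variant minor allele frequency from called dosages.

    Returns a data frame indexed like ``panel.variants`` with columns
    ``alt_freq``, ``maf``, ``minor_is_alt`` and ``n_called``.  Missing cells
    are excluded from denominators; a variant with zero called accessions
    gets NaN frequencies.  When the alt-allele frequency is exactly 0.5 the
    alt allele is declared minor (documented tie rule).
    """
    if panel.n_variants == 0:
        raise PanelError("empty panel")
    d = panel.dosages
    called = d != MISSING
    n_called = called.sum(axis=0)
    alt_count = np.where(called, d, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(n_called > 0, alt_count / (2.0 * n_called), np.nan)
    minor_is_alt = alt_freq <= 0.5  # tie at 0.5 -> alt is minor
    maf = np.where(minor_is_alt, alt_freq, 1.0 - alt_freq)
    minor_is_alt = np.where(np.isnan(alt_freq), False, minor_is_alt)
    return pd.DataFrame(
        {
            "vid": panel.vids,
            "alt_freq": alt_freq,
            "maf": maf,
            "minor_is_alt": minor_is_alt,
            "n_called": n_called,
        }
    )


# ---------------------------------------------------------------------------
# VCF reading


def _open_maybe_gzip(path):
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, "rt")
    return open(p, "rt")


def read_vcf(path, inbred_mode: bool = False, het_policy: str = "missing") -> GenotypePanel:
    """Read a VCF into a :class:`GenotypePanel`.

    Only bi-allelic SNP records are used; multi-allelic records and indels
    are skipped (and counted in the log).  Dosages are alt-allele counts per
    GT; missing GTs become MISSING.  In ``inbred_mode``, heterozygous calls
    are handled by ``het_policy``:

    - ``"missing"`` (default): recode to MISSING,
    - ``"drop_variant"``: remove the whole variant,
    - ``"keep"``: keep dosage 1 and unset inbred_mode on the result.
    """
    if het_policy not in ("missing", "drop_variant", "keep"):
        raise PanelError(f"unknown het_policy {het_policy!r}")
    try:
        vcf = VCF(str(path), gts012=True)
    except OSError as exc:
        raise IOError(f"cannot read VCF {path}: {exc}") from exc
    accessions = list(vcf.samples)
    rows = []
    dosage_cols = []
    n_skipped = 0
    n_het = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        # gts012: 0=hom ref, 1=het, 2=hom alt, 3=unknown
        d = rec.gt_types.astype(np.int8)
        d[d == 3] = MISSING
        if inbred_mode:
            het = d == 1
            if het.any():
                n_het += int(het.sum())
                if het_policy == "missing":
                    d[het] = MISSING
                elif het_policy == "drop_variant":
                    n_skipped += 1
                    continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0], vid))
        dosage_cols.append(d)
    vcf.close()
    if n_skipped:
        logger.info("read_vcf(%s): skipped %d non bi-allelic-SNP records", path, n_skipped)
    if n_het:
        logger.info("read_vcf(%s): %d heterozygous calls handled by policy %r", path, n_het, het_policy)
    if not rows:
        raise PanelError(f"no bi-allelic SNP records in {path}")
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = np.stack(dosage_cols, axis=1)
    effective_inbred = inbred_mode and not (inbred_mode and het_policy == "keep" and (dosages == 1).any())
    return GenotypePanel(variants, accessions, dosages, inbred_mode=effective_inbred)


def read_imputed_vcf(path, gp_field: str = "GP", ar2_key: str = "AR2") -> ImputationResult:
    """Read an imputed VCF (e.g. Beagle-style output) into an ImputationResult.

    Genotype-probability FORMAT fields and the allelic-correlation INFO key
    are optional: absent probabilities fall back to point masses on the GT
    call, absent AR2 becomes NaN.
    """
    try:
        vcf = VCF(str(path), gts012=True)
    except OSError as exc:
        raise IOError(f"cannot read VCF {path}: {exc}") from exc
    accessions = list(vcf.samples)
    n = len(accessions)
    rows, dos_cols, prob_cols, ar2_vals = [], [], [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        d = rec.gt_types.astype(np.int8)
        d[d == 3] = MISSING
        gp = None
        try:
            gp = rec.format(gp_field)
        except KeyError:
            gp = None
        if gp is not None and gp.shape == (n, 3):
            probs = np.asarray(gp, dtype=float)
            s = probs.sum(axis=1, keepdims=True)
            s[s <= 0] = 1.0
            probs = probs / s
        else:
            probs = np.zeros((n, 3))
            idx = np.where(d == MISSING, 0, d)
            probs[np.arange(n), idx] = 1.0
        ar2 = rec.INFO.get(ar2_key)
        ar2_vals.append(float(ar2) if ar2 is not None else np.nan)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0], vid))
        dos_cols.append(d)
        prob_cols.append(probs)
    vcf.close()
    if not rows:
        raise PanelError(f"no bi-allelic SNP records in {path}")
    if n_skipped:
        logger.info("read_imputed_vcf(%s): skipped %d records", path, n_skipped)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = np.stack(dos_cols, axis=1)
    probs = np.stack(prob_cols, axis=1)
    panel = GenotypePanel(variants, accessions, dosages, inbred_mode=not (dosages == 1).any())
    post = PosteriorGenotypes(variants, accessions, probs)
    return ImputationResult(panel, post, np.array(ar2_vals))


# ---------------------------------------------------------------------------
# VCF writing

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(panel: GenotypePanel, path, posteriors: PosteriorGenotypes | None = None,
              ar2: np.ndarray | None = None) -> None:
    """Write a panel (optionally with posteriors and AR2) as VCF 4.2 text.

    Posteriors are emitted as a GP FORMAT field (probabilities of 0/1/2 alt
    copies) and AR2 as an INFO key.
    """
    if posteriors is not None:
        if posteriors.probs.shape[:2] != panel.dosages.shape:
            raise PanelError("posteriors axes do not match panel")
    if ar2 is not None:
        ar2 = np.asarray(ar2, dtype=float)
        if ar2.shape != (panel.n_variants,):
            raise PanelError("ar2 length does not match panel")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AR2,Number=1,Type=Float,Description="Allelic R-squared estimated from posterior genotype probabilities">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if posteriors is not None:
            fh.write('##FORMAT=<ID=GP,Number=G,Type=Float,Description="Posterior genotype probabilities (0,1,2 alt copies)">\n')
        for chrom in pd.unique(panel.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.accessions) + "\n")
        fmt = "GT:GP" if posteriors is not None else "GT"
        for j in range(panel.n_variants):
            v = panel.variants.iloc[j]
            info = "."
            if ar2 is not None and np.isfinite(ar2[j]):
                info = f"AR2={ar2[j]:.4f}"
            cells = []
            for i in range(panel.n_accessions):
                gt = _GT[int(panel.dosages[i, j])]
                if posteriors is not None:
                    p = posteriors.probs[i, j]
                    gt += ":" + ",".join(f"{x:.6f}" for x in p)
                cells.append(gt)
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\t{fmt}\t"
                + "\t".join(cells) + "\n"
            )
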