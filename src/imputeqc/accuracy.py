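"""Observed imputation-accuracy measures and their summaries.

For a variant, SNP accuracy is the proportion of correctly imputed
accessions; minor- and major-allele accuracy are the same proportion
restricted to accessions whose TRUE genotype carries the minor or major
allele.  With MAF = n_total(minor) / n_total the three are linked by the
exact identity

    snp_accuracy = minor_accuracy * MAF + major_accuracy * (1 - MAF),

so SNP accuracy always lies between the two stratified accuracies.
Accession accuracy is the per-accession proportion of correctly imputed
variants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypePanel, PanelError, allele_frequencies

ACCURACY_COLUMNS = [
    "vid", "maf", "n_total", "n_correct",
    "n_total_minor", "n_correct_minor", "n_total_major", "n_correct_major",
    "snp_accuracy", "minor_allele_accuracy", "major_allele_accuracy",
]


def _mask_matrix(truth: GenotypePanel, mask) -> np.ndarray:
    """Normalize a mask (boolean matrix or iterable of (accession, vid) cells)."""
    if mask is None:
        return truth.dosages != MISSING
    m = np.asarray(mask) if not isinstance(mask, (list, set, tuple)) else None
    if m is not None and m.dtype == bool and m.shape == truth.dosages.shape:
        return m
    out = np.zeros(truth.dosages.shape, dtype=bool)
    rows = truth.accession_index([a for a, _ in mask])
    cols = truth.variant_index([v for _, v in mask])
    out[rows, cols] = True
    return out


def score_variants(truth: GenotypePanel, imputed: GenotypePanel, mask=None,
                   minor_allele_source: GenotypePanel | None = None) -> pd.DataFrame:
    """Per-variant accuracy records over the evaluated (masked) cells.

    ``mask`` selects the evaluated cells, either as a boolean accession x
    variant matrix or as an iterable of (accession_id, vid) pairs; ``None``
    evaluates every cell with non-missing truth.  A cell is correct iff the
    dosages are equal.  Minor-allele identity is taken from
    ``minor_allele_source`` (default: the truth panel restricted to evaluated
    accessions), and a cell belongs to the minor class iff its TRUE genotype
    carries the minor allele.  Zero-denominator accuracies are NaN.
    """
    if truth.dosages.shape != imputed.dosages.shape:
        raise PanelError("truth and imputed panels do not share axes")
    cells = _mask_matrix(truth, mask)
    if not cells.any():
        raise PanelError("empty evaluation mask")
    cells = cells & (truth.dosages != MISSING)

    if minor_allele_source is None:
        # minor allele from the truth over accessions contributing any cell
        rows = cells.any(axis=1)
        src = GenotypePanel(truth.variants, [a for a, r in zip(truth.accessions, rows) if r],
                            truth.dosages[rows], inbred_mode=truth.inbred_mode)
    else:
        src = minor_allele_source
    freq = allele_frequencies(src)
    minor_is_alt = freq["minor_is_alt"].to_numpy()
    maf_src = freq["maf"].to_numpy()

    t = truth.dosages
    correct = cells & (t == imputed.dosages)
    # true genotype carries the minor allele: dosage>0 if minor is alt, dosage<2 if minor is ref
    carries_minor = np.where(minor_is_alt[None, :], t > 0, t < 2)
    minor_cells = cells & carries_minor
    major_cells = cells & ~carries_minor

    n_total = cells.sum(axis=0)
    n_correct = correct.sum(axis=0)
    n_tot_min = minor_cells.sum(axis=0)
    n_cor_min = (correct & minor_cells).sum(axis=0)
    n_tot_maj = major_cells.sum(axis=0)
    n_cor_maj = (correct & major_cells).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        snp = np.where(n_total > 0, n_correct / np.maximum(n_total, 1), np.nan)
        mn = np.where(n_tot_min > 0, n_cor_min / np.maximum(n_tot_min, 1), np.nan)
        mj = np.where(n_tot_maj > 0, n_cor_maj / np.maximum(n_tot_maj, 1), np.nan)
    snp[n_total == 0] = np.nan
    maf = np.where(n_total > 0, n_tot_min / np.maximum(n_total, 1), np.nan)
    # report the source MAF where no cell was evaluated
    maf = np.where(np.isnan(maf), maf_src, maf)
    return pd.DataFrame({
        "vid": truth.vids, "maf": maf,
        "n_total": n_total, "n_correct": n_correct,
        "n_total_minor": n_tot_min, "n_correct_minor": n_cor_min,
        "n_total_major": n_tot_maj, "n_correct_major": n_cor_maj,
        "snp_accuracy": snp, "minor_allele_accuracy": mn,
        "major_allele_accuracy": mj,
    })


def score_accessions(truth: GenotypePanel, imputed: GenotypePanel, mask=None) -> pd.DataFrame:
    """Per-accession accuracy over the evaluated cells (NaN if none)."""
    if truth.dosages.shape != imputed.dosages.shape:
        raise PanelError("truth and imputed panels do not share axes")
    cells = _mask_matrix(truth, mask)
    if not cells.any():
        raise PanelError("empty evaluation mask")
    cells = cells & (truth.dosages != MISSING)
    correct = cells & (truth.dosages == imputed.dosages)
    n_total = cells.sum(axis=1)
    n_correct = correct.sum(axis=1)
    with np.errstate(invalid="ignore"):
        acc = np.where(n_total > 0, n_correct / np.maximum(n_total, 1), np.nan)
    return pd.DataFrame({
        "accession": truth.accessions,
        "nSNP_total": n_total,
        "nSNP_correct": n_correct,
        "accession_accuracy": acc,
    })


DEFAULT_MAF_EDGES = [0.01, 0.05, 0.1, 0.25, 0.5]


def maf_class_labels(edges=DEFAULT_MAF_EDGES) -> list[str]:
    return [f"[{lo},{hi})" for lo, hi in zip(edges[:-1], edges[1:])]


def assign_maf_class(maf: np.ndarray, edges=DEFAULT_MAF_EDGES) -> np.ndarray:
    """Half-open class index per variant; the last class is closed. -1 = out/NaN."""
    maf = np.asarray(maf, dtype=float)
    idx = np.searchsorted(edges, maf, side="right") - 1
    idx[maf == edges[-1]] = len(edges) - 2
    idx[(maf < edges[0]) | (maf > edges[-1]) | np.isnan(maf)] = -1
    return idx


def summarize_by_maf_class(records: pd.DataFrame, class_edges=DEFAULT_MAF_EDGES,
                           quantiles=(0.05, 0.10, 0.5)) -> pd.DataFrame:
    """Distribution summaries of each accuracy metric per MAF class.

    Classes are half-open [lo, hi) except the last, which is closed.  NaN
    accuracies are excluded per statistic; the counts of usable records per
    metric are reported.  Quantiles use the median-unbiased estimator.
    """
    edges = list(class_edges)
    if sorted(edges) != edges or len(set(edges)) != len(edges):
        raise PanelError("class edges must be strictly increasing")
    idx = assign_maf_class(records["maf"].to_numpy(), edges)
    rows = []
    for c, label in enumerate(maf_class_labels(edges)):
        sel = records[idx == c]
        row = {"maf_class": label, "n_variants": len(sel)}
        for metric in ("snp_accuracy", "minor_allele_accuracy", "major_allele_accuracy"):
            vals = sel[metric].dropna().to_numpy()
            row[f"{metric}_n"] = len(vals)
            row[f"{metric}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{metric}_sd"] = vals.std(ddof=1) if len(vals) > 1 else (0.0 if len(vals) == 1 else np.nan)
            for q in quantiles:
                row[f"{metric}_q{int(q * 100):02d}"] = (
                    np.quantile(vals, q, method="median_unbiased") if len(vals) else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows)


def genomic_bins(records: pd.DataFrame, variants: pd.DataFrame, bin_bp: int = 100_000,
                 flag_threshold: float = 0.95) -> pd.DataFrame:
    """Mean SNP accuracy in fixed-width genomic bins, with low-accuracy flags.

    Bins tile each chromosome from position 1 in half-open windows of
    ``bin_bp``.  A bin is flagged iff its mean SNP accuracy is strictly below
    ``flag_threshold``.  Empty bins are emitted with 0 variants and NaN mean.
    """
    if bin_bp <= 0:
        raise PanelError("bin_bp must be positive")
    acc = records.set_index("vid")["snp_accuracy"]
    rows = []
    for chrom in pd.unique(variants["chrom"]):
        sub = variants[variants["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        last = pos.max()
        n_bins = int((last - 1) // bin_bp) + 1
        which = (pos - 1) // bin_bp
        for b in range(n_bins):
            vids = sub["vid"].to_numpy()[which == b]
            vals = acc.reindex(vids).dropna().to_numpy()
            mean = vals.mean() if len(vals) else np.nan
            rows.append({
                "chrom": chrom,
                "start": b * bin_bp + 1,
                "end": (b + 1) * bin_bp,
                "n_variants": len(vids),
                "mean_snp_accuracy": mean,
                "flagged": bool(len(vals)) and mean < flag_threshold,
            })
    return pd.DataFrame(rows)


def bins_to_bed(bins: pd.DataFrame, path) -> None:
    """Write genomic bins as BED (0-based half-open; score = mean accuracy)."""
    with open(path, "w") as fh:
        for _, r in bins.iterrows():
            score = "." if not np.isfinite(r.mean_snp_accuracy) else f"{r.mean_snp_accuracy:.4f}"
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tbin\t{score}\n")
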