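"""Single-marker linear mixed-model association scan with significance thresholds.

The model per marker is

    y = alpha + X beta + u + e,   u ~ N(0, sigma2_A K),  e ~ N(0, sigma2_E I),

with y the quantitative trait, X the marker dosage, K a relatedness matrix
(centered cross-product of the dosage matrix) and u/e random polygenic and
residual effects.  Variance components are estimated once on the null model
by maximum likelihood in the eigenbasis of K and reused across markers;
each marker is then tested by generalized least squares with the residual
scale re-estimated per marker (two-sided t test on n-2 df).  With the
kinship path disabled this reduces exactly to per-marker ordinary least
squares.

Genome-wide significance uses a Bonferroni threshold, -log10(0.05 / m), and
a permutation threshold: the empirical 95th percentile (by default) of the
genome-wide maximum -log10 p over random permutations of the phenotype
against fixed genotypes and kinship.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_io import MISSING, GenotypePanel, PanelError, allele_frequencies

logger = logging.getLogger(__name__)

DEFAULT_N_PERMUTATIONS = 200
DEFAULT_PERM_QUANTILE = 0.95
DEFAULT_MAF_FLOOR = 0.05


def read_phenotype(path) -> pd.Series:
    """Read a two-column TSV (accession_id, value) into a Series."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise PanelError("phenotype table needs accession id and value columns")
    s = pd.Series(df.iloc[:, 1].to_numpy(float), index=df.iloc[:, 0].astype(str))
    if not np.isfinite(s.to_numpy()).all():
        raise PanelError("non-finite phenotype values")
    return s


def _mean_imputed_dosages(panel: GenotypePanel) -> np.ndarray:
    d = panel.dosages.astype(float)
    d[panel.dosages == MISSING] = np.nan
    col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    ind = np.where(np.isnan(d))
    d[ind] = col_mean[ind[1]]
    return d


def kinship(panel: GenotypePanel) -> np.ndarray:
    """Relatedness matrix: centered cross-product of dosages over marker count.

    Missing dosages are mean-imputed per marker.  The result is symmetric
    positive semi-definite.
    """
    d = _mean_imputed_dosages(panel)
    d = d - d.mean(axis=0, keepdims=True)
    if not (d.std(axis=0) > 0).any():
        raise PanelError("zero-variance panel: kinship undefined")
    k = d @ d.T / panel.n_variants
    return (k + k.T) / 2.0


@dataclass
class GwasModelFit:
    """Null-model variance components and the eigendecomposition of K."""

    sigma2_A: float
    sigma2_E: float
    K: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


@dataclass
class GwasResult:
    """Per-marker effects and genome-wide significance thresholds."""

    table: pd.DataFrame                     # chrom, pos, vid, maf, beta, se, neg_log10_p
    bonferroni_threshold: float = np.nan
    permutation_threshold: float = np.nan
    fit: GwasModelFit | None = None

    @property
    def m_tested(self) -> int:
        return int(self.table["neg_log10_p"].notna().sum())


def _null_ml_variance_components(y_rot: np.ndarray, one_rot: np.ndarray,
                                 lam: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood (sigma2_A, sigma2_E) for y = alpha + u + e in the
    eigenbasis of K; optimizes over the ratio delta = sigma2_E / sigma2_A."""
    n = y_rot.size

    def neg_loglik(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = 1.0 / (lam + delta)              # proportional precision
        alpha = (w * one_rot * y_rot).sum() / (w * one_rot ** 2).sum()
        r = y_rot - alpha * one_rot
        s2a = (w * r ** 2).sum() / n         # profiled sigma2_A
        return 0.5 * (n * np.log(s2a) + np.log(lam + delta).sum())

    res = optimize.minimize_scalar(neg_loglik, bounds=(-12.0, 12.0), method="bounded")
    delta = np.exp(res.x)
    w = 1.0 / (lam + delta)
    alpha = (w * one_rot * y_rot).sum() / (w * one_rot ** 2).sum()
    r = y_rot - alpha * one_rot
    s2a = (w * r ** 2).sum() / n
    # boundary handling: essentially no genetic variance
    if res.x >= 11.9:
        s2e = s2a * delta
        return 0.0, float(s2e)
    return float(s2a), float(s2a * delta)


def fit_null_model(y: np.ndarray, K: np.ndarray) -> GwasModelFit:
    lam, U = np.linalg.eigh(K)
    lam = np.clip(lam, 0.0, None)
    y_rot = U.T @ y
    one_rot = U.T @ np.ones_like(y)
    s2a, s2e = _null_ml_variance_components(y_rot, one_rot, lam)
    return GwasModelFit(s2a, s2e, K, lam, U)


def lmm_scan(y: pd.Series, panel: GenotypePanel, K: np.ndarray | None = None,
             maf_floor: float = DEFAULT_MAF_FLOOR,
             fit: GwasModelFit | None = None) -> GwasResult:
    """Single-marker mixed-model scan over all panel variants.

    ``y`` is aligned to the panel by accession id.  Markers with MAF below
    ``maf_floor`` or zero variance are skipped (NaN rows).  Passing ``K=None``
    disables the kinship path (sigma2_A = 0), reducing each test to ordinary
    least squares.
    """
    ids = [a for a in panel.accessions if a in set(y.index)]
    if len(ids) < 4:
        raise PanelError("need at least 4 phenotyped accessions")
    sub = panel.subset(accessions=ids)
    yv = y.loc[ids].to_numpy(float)
    n = len(ids)
    X = _mean_imputed_dosages(sub)

    if K is None:
        lam = np.zeros(n)
        U = np.eye(n)
        fit = GwasModelFit(0.0, float(yv.var()), np.zeros((n, n)), lam, U)
    elif fit is None:
        fit = fit_null_model(yv, K)
    lam, U = fit.eigenvalues, fit.eigenvectors
    # GLS weights from the fixed null-model covariance V = s2a*K + s2e*I
    if fit.sigma2_A <= 0:
        w = np.ones(n)
    else:
        w = 1.0 / (fit.sigma2_A * lam + fit.sigma2_E)

    y_rot = U.T @ yv
    one_rot = U.T @ np.ones(n)
    X_rot = U.T @ X

    maf = allele_frequencies(sub)["maf"].to_numpy()
    beta = np.full(sub.n_variants, np.nan)
    se = np.full(sub.n_variants, np.nan)
    nlp = np.full(sub.n_variants, np.nan)

    # per-marker weighted least squares on the 2-column design [1, x]
    a11 = (w * one_rot ** 2).sum()
    a1y = (w * one_rot * y_rot).sum()
    yy = (w * y_rot ** 2).sum()
    for j in range(sub.n_variants):
        if not np.isfinite(maf[j]) or maf[j] < maf_floor:
            continue
        x = X_rot[:, j]
        a12 = (w * one_rot * x).sum()
        a22 = (w * x ** 2).sum()
        a2y = (w * x * y_rot).sum()
        det = a11 * a22 - a12 ** 2
        if det <= 1e-12 * max(a11 * a22, 1e-300):
            continue  # constant marker: singular design
        b1 = (a22 * a1y - a12 * a2y) / det
        b2 = (a11 * a2y - a12 * a1y) / det
        rss = yy - 2 * (b1 * a1y + b2 * a2y) + (
            a11 * b1 ** 2 + 2 * a12 * b1 * b2 + a22 * b2 ** 2)
        dof = n - 2
        s2 = max(rss, 0.0) / dof
        var_b = s2 * a11 / det
        beta[j] = b2
        se[j] = np.sqrt(var_b)
        if se[j] > 0:
            t = b2 / se[j]
            p = 2.0 * stats.t.sf(abs(t), dof)
            nlp[j] = -np.log10(max(p, np.finfo(float).tiny))
    table = pd.DataFrame({
        "chrom": sub.variants["chrom"], "pos": sub.variants["pos"],
        "vid": sub.vids, "maf": maf, "beta": beta, "se": se, "neg_log10_p": nlp,
    })
    return GwasResult(table, fit=fit)


def thresholds(y: pd.Series, panel: GenotypePanel, K: np.ndarray | None = None,
               n_perm: int = DEFAULT_N_PERMUTATIONS,
               quantile: float = DEFAULT_PERM_QUANTILE, seed: int = 0,
               maf_floor: float = DEFAULT_MAF_FLOOR):
    """Bonferroni and permutation genome-wide thresholds on the -log10 scale.

    The permutation threshold is the empirical ``quantile`` of the
    genome-wide maximum -log10 p over ``n_perm`` random permutations of the
    phenotype, with genotypes and K fixed.  Returns
    ``(bonferroni, permutation, per-permutation maxima)``.
    """
    if n_perm < 1:
        raise PanelError("n_perm must be >= 1")
    base = lmm_scan(y, panel, K, maf_floor=maf_floor)
    m = base.m_tested
    bonferroni = -np.log10(0.05 / m)
    rng = np.random.default_rng(seed)
    ids = [a for a in panel.accessions if a in set(y.index)]
    maxima = np.empty(n_perm)
    for p in range(n_perm):
        perm_y = pd.Series(rng.permutation(y.loc[ids].to_numpy(float)), index=ids)
        scan = lmm_scan(perm_y, panel, K, maf_floor=maf_floor)
        maxima[p] = np.nanmax(scan.table["neg_log10_p"].to_numpy())
    permutation = float(np.quantile(maxima, quantile))
    return float(bonferroni), permutation, maxima
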