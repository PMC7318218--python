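"""Observed accuracy metrics: counting oracles and the convexity identity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from imputeqc import MISSING, PanelError, score_accessions, score_variants
from imputeqc.accuracy import genomic_bins, summarize_by_maf_class

from conftest import make_panel


def random_pair(rng, n, m, p_err=0.1, p_missing=0.0):
    truth = rng.choice([0, 2], size=(n, m)).astype(np.int8)
    if p_missing:
        truth[rng.random((n, m)) < p_missing] = MISSING
    err = rng.random((n, m)) < p_err
    imputed = np.where((truth != MISSING) & err, 2 - truth, truth).astype(np.int8)
    return make_panel(truth), make_panel(imputed)


class TestScoreVariants:
    def test_forced_example(self):
        truth = np.array([[2], [2], [0], [0], [2], [2], [2], [2], [2], [2]], dtype=np.int8)
        imputed = truth.copy()
        imputed[2, 0] = 2  # wrong on one minor (ref-carrying) accession
        rec = score_variants(make_panel(truth), make_panel(imputed))
        r = rec.iloc[0]
        assert r.maf == pytest.approx(0.2)
        assert r.snp_accuracy == pytest.approx(0.9)
        assert r.minor_allele_accuracy == pytest.approx(0.5)
        assert r.major_allele_accuracy == pytest.approx(1.0)
        assert r.snp_accuracy == pytest.approx(
            r.minor_allele_accuracy * r.maf + r.major_allele_accuracy * (1 - r.maf))

    def test_all_correct(self):
        rng = np.random.default_rng(0)
        truth, _ = random_pair(rng, 8, 5, p_err=0)
        rec = score_variants(truth, truth)
        poly = rec["n_total_minor"] > 0
        assert (rec.snp_accuracy == 1).all()
        assert (rec.major_allele_accuracy.dropna() == 1).all()
        assert (rec.loc[poly, "minor_allele_accuracy"] == 1).all()

    def test_counting_oracle_random(self):
        rng = np.random.default_rng(21)
        truth, imputed = random_pair(rng, 30, 100, p_err=0.15, p_missing=0.05)
        rec = score_variants(truth, imputed)
        t, im = truth.dosages, imputed.dosages
        for j in range(100):
            called = t[:, j] != MISSING
            col_t, col_i = t[called, j], im[called, j]
            n = called.sum()
            correct = (col_t == col_i).sum()
            alt = col_t.sum() / (2 * n)
            minor_is_alt = alt <= 0.5
            carries_minor = col_t > 0 if minor_is_alt else col_t < 2
            r = rec.iloc[j]
            assert r.n_total == n and r.n_correct == correct
            assert r.n_total_minor == carries_minor.sum()
            assert r.n_correct_minor == ((col_t == col_i) & carries_minor).sum()
            assert r.n_total == r.n_total_minor + r.n_total_major
            assert r.n_correct == r.n_correct_minor + r.n_correct_major

    def test_empty_mask_is_error(self):
        truth, imputed = random_pair(np.random.default_rng(1), 4, 4)
        with pytest.raises(PanelError):
            score_variants(truth, imputed, mask=np.zeros((4, 4), dtype=bool))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 25), st.integers(1, 30))
    def test_eqn_identity_and_convexity_property(self, seed, n, m):
        rng = np.random.default_rng(seed)
        truth, imputed = random_pair(rng, n, m, p_err=float(rng.random() * 0.6),
                                     p_missing=0.1)
        try:
            rec = score_variants(truth, imputed)
        except PanelError:
            return  # fully missing truth: nothing to evaluate
        full = rec.dropna(subset=["snp_accuracy", "minor_allele_accuracy",
                                  "major_allele_accuracy"])
        lhs = full.snp_accuracy
        rhs = full.minor_allele_accuracy * full.maf + full.major_allele_accuracy * (1 - full.maf)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)
        lo = np.minimum(full.minor_allele_accuracy, full.major_allele_accuracy)
        hi = np.maximum(full.minor_allele_accuracy, full.major_allele_accuracy)
        assert ((lhs >= lo - 1e-12) & (lhs <= hi + 1e-12)).all()


class TestScoreAccessions:
    def test_simple_fraction(self):
        truth = make_panel([[0, 0, 0, 0, 0], [2, 2, 2, 2, 2]])
        imp = make_panel([[0, 0, 0, 0, 2], [2, 2, 2, 2, 2]])
        rec = score_accessions(truth, imp)
        assert rec.accession_accuracy.tolist() == [0.8, 1.0]

    def test_marginal_counts_reconcile(self):
        rng = np.random.default_rng(33)
        truth, imputed = random_pair(rng, 20, 50, p_err=0.2, p_missing=0.05)
        v = score_variants(truth, imputed)
        a = score_accessions(truth, imputed)
        assert v.n_correct.sum() == a.nSNP_correct.sum()
        assert v.n_total.sum() == a.nSNP_total.sum()


class TestMafClassSummary:
    def test_class_assignment(self):
        rec = pd.DataFrame({
            "vid": ["a", "b"], "maf": [0.03, 0.2],
            "snp_accuracy": [0.9, 1.0],
            "minor_allele_accuracy": [0.5, 1.0],
            "major_allele_accuracy": [1.0, 1.0],
        })
        s = summarize_by_maf_class(rec, [0.01, 0.05, 0.1, 0.25, 0.5])
        assert s.loc[s.maf_class == "[0.01,0.05)", "n_variants"].iloc[0] == 1
        assert s.loc[s.maf_class == "[0.1,0.25)", "n_variants"].iloc[0] == 1
        assert s.loc[s.maf_class == "[0.05,0.1)", "n_variants"].iloc[0] == 0

    def test_constant_accuracy(self):
        rec = pd.DataFrame({
            "vid": list("abcd"), "maf": [0.02, 0.07, 0.2, 0.4],
            "snp_accuracy": 0.8, "minor_allele_accuracy": 0.8,
            "major_allele_accuracy": 0.8,
        })
        s = summarize_by_maf_class(rec)
        filled = s[s.n_variants > 0]
        np.testing.assert_allclose(filled.snp_accuracy_mean, 0.8, atol=1e-12)
        np.testing.assert_allclose(filled.snp_accuracy_sd.fillna(0), 0.0, atol=1e-12)

    def test_grouping_oracle(self):
        rng = np.random.default_rng(4)
        rec = pd.DataFrame({
            "vid": [f"v{i}" for i in range(200)],
            "maf": rng.uniform(0.0, 0.5, 200),
            "snp_accuracy": rng.random(200),
            "minor_allele_accuracy": rng.random(200),
            "major_allele_accuracy": rng.random(200),
        })
        edges = [0.01, 0.05, 0.1, 0.25, 0.5]
        s = summarize_by_maf_class(rec, edges).set_index("maf_class")
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (rec.maf >= lo) & ((rec.maf < hi) | ((hi == 0.5) & (rec.maf == 0.5)))
            label = f"[{lo},{hi})"
            assert s.loc[label, "n_variants"] == sel.sum()
            if sel.any():
                assert s.loc[label, "snp_accuracy_mean"] == pytest.approx(
                    rec.loc[sel, "snp_accuracy"].mean())


class TestGenomicBins:
    def test_two_bins(self):
        rec = pd.DataFrame({"vid": ["1_50000", "1_150000"], "snp_accuracy": [1.0, 0.8]})
        var = pd.DataFrame({"chrom": "1", "pos": [50_000, 150_000],
                            "vid": ["1_50000", "1_150000"]})
        bins = genomic_bins(rec, var, bin_bp=100_000, flag_threshold=0.95)
        assert len(bins) == 2
        assert bins.n_variants.tolist() == [1, 1]
        assert bins.flagged.tolist() == [False, True]

    def test_boundary_not_flagged_at_threshold(self):
        rec = pd.DataFrame({"vid": ["1_10", "1_20"], "snp_accuracy": [0.9, 1.0]})
        var = pd.DataFrame({"chrom": "1", "pos": [10, 20], "vid": ["1_10", "1_20"]})
        bins = genomic_bins(rec, var, bin_bp=100, flag_threshold=0.95)
        assert bins.mean_snp_accuracy.iloc[0] == pytest.approx(0.95)
        assert not bins.flagged.iloc[0]

    def test_interval_oracle_random_layout(self):
        rng = np.random.default_rng(12)
        pos = np.sort(rng.choice(500_000, size=80, replace=False)) + 1
        var = pd.DataFrame({"chrom": "1", "pos": pos, "vid": [f"1_{p}" for p in pos]})
        rec = pd.DataFrame({"vid": var.vid, "snp_accuracy": rng.random(80)})
        bins = genomic_bins(rec, var, bin_bp=50_000)
        for _, b in bins.iterrows():
            inside = (pos >= b.start) & (pos <= b.end)
            assert b.n_variants == inside.sum()
        assert bins.n_variants.sum() == 80
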