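"""Haplotype-copying imputer: path-enumeration oracle, decoding, AR2."""

import itertools
import math

import numpy as np
import pytest

from imputeqc import (
    MISSING,
    GenotypePanel,
    ImputerConfig,
    PanelError,
    PosteriorGenotypes,
    decode_genotype,
    estimate_ar2,
    impute,
)
from imputeqc.hmm import _forward_backward, switch_probability

from conftest import make_panel


def enumerate_posterior_q(ref, obs, pos, cfg):
    """Posterior alt-allele probabilities by exhaustive hidden-path enumeration."""
    H, S = ref.shape
    d = np.diff(pos)
    rho = 1 - np.exp(-4 * cfg.ne * cfg.recomb_rate_per_bp * d / H)

    def emis(s, k):
        o = obs[s]
        if o == -1:
            return 1.0
        return 1 - cfg.error_rate if ref[k, s] == o else cfg.error_rate

    tot, z = np.zeros(S), 0.0
    for path in itertools.product(range(H), repeat=S):
        p = emis(0, path[0]) / H
        for s in range(1, S):
            r = rho[s - 1]
            p *= ((1 - r) + r / H if path[s] == path[s - 1] else r / H) * emis(s, path[s])
        z += p
        for s in range(S):
            tot[s] += p * ref[path[s], s]
    return tot / z


class TestForwardBackwardOracle:
    def test_matches_path_enumeration(self):
        rng = np.random.default_rng(123)
        cfg = ImputerConfig(error_rate=0.02)
        for _ in range(40):
            H = int(rng.integers(2, 5))
            S = int(rng.integers(2, 6))
            ref = rng.integers(0, 2, size=(H, S)).astype(np.int8)
            obs = rng.integers(-1, 2, size=S).astype(np.int8)
            pos = np.sort(rng.choice(150_000, size=S, replace=False)).astype(float) + 1
            q = _forward_backward(ref, obs[None, :], pos, cfg)[0]
            qq = enumerate_posterior_q(ref, obs, pos, cfg)
            np.testing.assert_allclose(q, qq, atol=1e-10)

    def test_posterior_in_unit_interval(self):
        rng = np.random.default_rng(5)
        cfg = ImputerConfig()
        ref = rng.integers(0, 2, size=(10, 50)).astype(np.int8)
        obs = rng.integers(-1, 2, size=(3, 50)).astype(np.int8)
        pos = np.sort(rng.choice(10**6, size=50, replace=False)).astype(float)
        q = _forward_backward(ref, obs, pos, cfg)
        assert (q >= 0).all() and (q <= 1).all()


class TestImpute:
    def test_identical_reference_haplotypes(self):
        hap = np.array([0, 2, 2, 0, 2], dtype=np.int8)
        ref = make_panel(np.tile(hap, (4, 1)))
        target = make_panel([[0, MISSING, MISSING, 0, MISSING]], accessions=["t"])
        res = impute(ref, target, ImputerConfig(error_rate=1e-3))
        np.testing.assert_array_equal(res.best_guess.dosages[0], hap)
        masked = [1, 2, 4]
        for j in masked:
            assert res.posteriors.probs[0, j].max() >= 1 - 1e-3

    def test_pass_through_of_typed_sites(self, small_sim):
        panel = small_sim.full_panel
        ref = panel.subset(accessions=panel.accessions[:40])
        tgt = panel.subset(accessions=panel.accessions[40:])
        res = impute(ref, tgt)  # no MISSING sites at all
        np.testing.assert_array_equal(res.best_guess.dosages, tgt.dosages)

    def test_windowed_equals_single_window_when_window_covers_chrom(self, small_sim):
        panel = small_sim.full_panel
        ref = panel.subset(accessions=panel.accessions[:40])
        truth = panel.subset(accessions=panel.accessions[40:45])
        chip = set(small_sim.chip_variant_ids)
        masked = [v for v in panel.vids if v not in chip]
        tgt = truth.copy()
        tgt.dosages[:, tgt.variant_index(masked)] = MISSING
        big = ImputerConfig(window_bp=10**9, overlap_bp=1000)
        also_big = ImputerConfig(window_bp=250_000, overlap_bp=1000)  # > 200 kb chrom
        r1 = impute(ref, tgt, big)
        r2 = impute(ref, tgt, also_big)
        np.testing.assert_allclose(r1.posteriors.probs, r2.posteriors.probs, atol=1e-12)

    def test_multiwindow_covers_every_variant(self, small_sim):
        panel = small_sim.full_panel
        ref = panel.subset(accessions=panel.accessions[:40])
        truth = panel.subset(accessions=panel.accessions[40:44])
        chip = set(small_sim.chip_variant_ids)
        masked = [v for v in panel.vids if v not in chip]
        tgt = truth.copy()
        tgt.dosages[:, tgt.variant_index(masked)] = MISSING
        res = impute(ref, tgt, ImputerConfig(window_bp=60_000, overlap_bp=12_000))
        assert np.isfinite(res.posteriors.probs).all()
        np.testing.assert_allclose(res.posteriors.probs.sum(axis=2), 1.0, atol=1e-9)
        assert not (res.best_guess.dosages == MISSING).any()
        typed = tgt.dosages != MISSING
        np.testing.assert_array_equal(res.best_guess.dosages[typed], tgt.dosages[typed])

    def test_low_error_recovers_reference_haplotype(self):
        rng = np.random.default_rng(8)
        haps = rng.integers(0, 2, size=(3, 60)).astype(np.int8) * 2
        ref = make_panel(haps, positions=np.arange(1, 61) * 50)
        truth = haps[1]
        tgt_d = truth.copy()[None, :]
        tgt_d[0, ::2] = MISSING  # mask half the sites
        tgt = make_panel(tgt_d, positions=np.arange(1, 61) * 50, accessions=["t"])
        res = impute(ref, tgt, ImputerConfig(error_rate=1e-6))
        np.testing.assert_array_equal(res.best_guess.dosages[0], truth)

    def test_errors_on_degenerate_inputs(self, small_sim):
        panel = small_sim.full_panel
        het = make_panel([[0, 1], [2, 0]], inbred=False)
        with pytest.raises(PanelError):
            impute(panel, het)

    def test_switch_probability_monotone_in_distance(self):
        cfg = ImputerConfig()
        assert switch_probability(100, 50, cfg) < switch_probability(10_000, 50, cfg)


class TestDecodeGenotype:
    @pytest.mark.parametrize("triple,expected", [
        ((0.1, 0.0, 0.9), 2),
        ((0.9, 0.0, 0.1), 0),
        ((0.2, 0.5, 0.3), 2),   # heterozygous argmax falls back to larger of p0/p2
        ((0.3, 0.5, 0.2), 0),
        ((0.5, 0.0, 0.5), 0),   # exact tie -> reference allele
    ])
    def test_decode_rules(self, triple, expected):
        assert decode_genotype(triple) == expected


class TestEstimateAr2:
    def oracle(self, probs, b):
        """Direct formula evaluation with exact float summation."""
        n = len(b)
        e = [p[1] + 2 * p[2] for p in probs]
        z = [p[1] + 4 * p[2] for p in probs]
        num = math.fsum(bi * ei for bi, ei in zip(b, e)) - math.fsum(b) * math.fsum(e) / n
        vb = math.fsum(bi * bi for bi in b) - math.fsum(b) ** 2 / n
        vt = math.fsum(z) - math.fsum(e) ** 2 / n
        if vb <= 1e-12 or vt <= 1e-12:
            return np.nan
        return num * num / (vb * vt)

    def _build(self, probs, best):
        best = np.asarray(best, dtype=np.int8)[:, None]
        panel = make_panel(best)
        post = PosteriorGenotypes(panel.variants, panel.accessions,
                                  np.asarray(probs, dtype=float)[:, None, :])
        return post, panel

    def test_point_mass_agreement_gives_one(self):
        probs = [(1, 0, 0), (0, 0, 1), (1, 0, 0), (0, 0, 1)]
        post, panel = self._build(probs, [0, 2, 0, 2])
        assert estimate_ar2(post, panel, 0) == pytest.approx(1.0, abs=1e-12)

    def test_constant_best_guess_is_missing(self):
        probs = [(0.9, 0, 0.1), (0.8, 0, 0.2), (0.7, 0, 0.3)]
        post, panel = self._build(probs, [0, 0, 0])
        assert np.isnan(estimate_ar2(post, panel, 0))

    def test_formula_oracle_random(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n = int(rng.integers(2, 12))
            raw = rng.random((n, 3))
            probs = raw / raw.sum(axis=1, keepdims=True)
            best = rng.choice([0, 2], size=n)
            post, panel = self._build(probs, best)
            got = estimate_ar2(post, panel, 0)
            want = self.oracle(probs, best)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_fewer_than_two_accessions_missing(self):
        post, panel = self._build([(0.5, 0, 0.5)], [0])
        assert np.isnan(estimate_ar2(post, panel, 0))
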