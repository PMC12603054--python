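"""Adaptive de-noising, binomial scoring, doublets, recalibration and the
two-pass search, each against an independent brute-force oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import SIMPLE_LINKER, random_spectrum
from xlmsbench.denoise_search import (
    DenoiseConfig,
    Spectrum,
    adaptive_denoise_score,
    detect_doublets,
    pick_peaks,
    recalibrate,
    score_csm,
)


def brute_pick(spec, m, w):
    """Per-window sort oracle for peak picking."""
    keep = []
    windows = {}
    for i in range(spec.peak_count()):
        windows.setdefault(int(spec.mz[i] // w), []).append(i)
    for _, idxs in windows.items():
        ranked = sorted(idxs, key=lambda i: (-spec.intensity[i], spec.mz[i]))
        keep.extend(ranked[:m])
    return sorted(keep)


class TestPickPeaks:
    def test_three_peaks_keep_two(self):
        s = Spectrum(1, 500.0, 2, 1.0, -48.0,
                     np.array([110.0, 120.0, 130.0]),
                     np.array([5.0, 9.0, 7.0]))
        out = pick_peaks(s, 2, 100.0)
        assert list(out.mz) == [120.0, 130.0]

    def test_identity_when_m_large(self):
        rng = np.random.default_rng(0)
        s = random_spectrum(rng, 40)
        out = pick_peaks(s, 40, 100.0)
        assert np.array_equal(out.mz, s.mz)

    def test_matches_brute_force_oracle_on_random_spectra(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            s = random_spectrum(rng, int(rng.integers(5, 120)))
            m = int(rng.integers(1, 10))
            out = pick_peaks(s, m, 100.0)
            assert list(out.mz) == list(s.mz[brute_pick(s, m, 100.0)])

    @given(m=st.integers(1, 10), seed=st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_bounded_and_idempotent(self, m, seed):
        rng = np.random.default_rng(seed)
        s = random_spectrum(rng, 60)
        out = pick_peaks(s, m, 100.0)
        win = np.floor(out.mz / 100.0).astype(int)
        assert all(np.sum(win == k) <= m for k in np.unique(win))
        again = pick_peaks(out, m, 100.0)
        assert np.array_equal(again.mz, out.mz)


def exact_binom_tail(k, n, p):
    """Independent oracle: exact summation of the binomial pmf."""
    total = 0.0
    for i in range(k, n + 1):
        total += math.comb(n, i) * p ** i * (1 - p) ** (n - i)
    return total


class TestScore:
    def test_zero_matches_scores_zero(self):
        s = Spectrum(1, 0, 2, 0, 0, np.array([100.0]), np.array([1.0]))
        assert score_csm(s, np.array([900.0]), 10.0) == 0.0

    def test_score_monotone_in_matched_count(self):
        rng = np.random.default_rng(2)
        theo = np.sort(rng.uniform(200, 1500, 40))
        scores = []
        for k in (5, 10, 20, 40):
            mz = np.sort(np.concatenate(
                [theo[:k], rng.uniform(1600, 1900, 60 - k)]))
            s = Spectrum(1, 0, 2, 0, 0, mz, np.ones(60))
            scores.append(score_csm(s, theo, 5.0))
        assert scores == sorted(scores)
        assert scores[0] < scores[-1]

    def test_matches_exact_summation_oracle(self):
        # n=10 theoretical ions, k=7 matched, known peak density
        theo = np.arange(200.0, 1200.0, 100.0)  # 10 ions
        mz = np.sort(np.concatenate([theo[:7], [1500.0, 1600.0, 1700.0]]))
        s = Spectrum(1, 0, 2, 0, 0, mz, np.ones(10))
        tol_ppm = 10.0
        span = mz[-1] - mz[0]
        p = min(0.5, 2 * np.mean(theo) * tol_ppm * 1e-6 * 10 / span)
        expected = -10 * math.log10(exact_binom_tail(7, 10, p))
        assert score_csm(s, theo, tol_ppm) == pytest.approx(expected,
                                                            rel=1e-9)


class TestAdaptiveDenoise:
    def test_equals_by_definition_loop_over_m(self):
        rng = np.random.default_rng(3)
        cfg = DenoiseConfig()
        for _ in range(100):
            s = random_spectrum(rng, int(rng.integers(10, 150)))
            theo = np.sort(rng.uniform(150, 1800, 50))
            fast = adaptive_denoise_score(s, theo, cfg)
            best = (0.0, 1)
            for m in range(1, 11):
                sc = score_csm(pick_peaks(s, m, cfg.window_width), theo,
                               cfg.fragment_tol_ppm)
                if sc > best[0]:
                    best = (sc, m)
            assert fast[0] == pytest.approx(best[0], rel=1e-9)
            assert fast[1] == best[1]

    def test_noise_free_spectrum_picks_small_m(self):
        # two true peaks per window, no noise -> m=2 retains everything
        mz = np.array([110.0, 150.0, 210.0, 250.0, 310.0, 350.0])
        s = Spectrum(1, 0, 2, 0, 0, mz, np.full(6, 100.0))
        cfg = DenoiseConfig()
        score, m = adaptive_denoise_score(s, mz.copy(), cfg)
        assert m == 2 and score > 0

    def test_adding_pure_noise_never_raises_score(self):
        rng = np.random.default_rng(4)
        cfg = DenoiseConfig()
        worse = 0
        for _ in range(50):
            theo = np.sort(rng.uniform(200, 1700, 40))
            sig = Spectrum(1, 0, 2, 0, 0, theo.copy(),
                           rng.uniform(500, 1000, 40))
            noise_mz = rng.uniform(200, 1700, 60)
            allmz = np.concatenate([theo, noise_mz])
            allint = np.concatenate([sig.intensity,
                                     rng.uniform(1.0, 100.0, 60)])
            noisy = Spectrum(1, 0, 2, 0, 0, allmz, allint)
            s0 = adaptive_denoise_score(sig, theo, cfg)[0]
            s1 = adaptive_denoise_score(noisy, theo, cfg)[0]
            if s1 > s0 + 1e-9:
                worse += 1
        assert worse == 0


class TestDoublets:
    def test_exact_pair_found(self):
        s = Spectrum(1, 0, 2, 0, 0, np.array([300.0, 340.0]),
                     np.array([1.0, 1.0]))
        assert detect_doublets(s, 40.0, (1,), 5.0) == [(0, 1, 1)]

    def test_empty_spectrum(self):
        s = Spectrum(1, 0, 2, 0, 0, np.array([]), np.array([]))
        assert detect_doublets(s, 40.0, (1, 2), 5.0) == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(5, 80))
            s = random_spectrum(rng, n)
            delta = float(rng.uniform(10, 60))
            tol_ppm = 20.0
            got = set(detect_doublets(s, delta, (1, 2), tol_ppm))
            oracle = set()
            for z in (1, 2):
                for i in range(n):
                    for j in range(n):
                        if j == i:
                            continue
                        target = s.mz[i] + delta / z
                        if abs(s.mz[j] - target) <= target * tol_ppm * 1e-6:
                            if not any(o[:2] == (i, j) for o in oracle):
                                oracle.add((i, j, z))
            assert got == oracle


class TestRecalibrate:
    def test_uniform_shift_corrected(self):
        rng = np.random.default_rng(6)
        s = random_spectrum(rng, 30)
        shifted = Spectrum(1, s.precursor_mz * (1 + 5e-6), 2, 1.0, -48.0,
                           s.mz * (1 + 5e-6), s.intensity)
        out, applied = recalibrate([shifted], [5.0] * 10)
        assert applied == pytest.approx(5.0)
        assert np.allclose(out[0].mz, s.mz, rtol=1e-12)

    def test_too_few_calibrants_is_identity(self):
        rng = np.random.default_rng(7)
        s = random_spectrum(rng, 10)
        out, applied = recalibrate([s], [3.0, 3.0])
        assert applied == 0.0 and out[0] is s

    def test_residual_errors_match_median_subtraction_oracle(self):
        errors = [2.0, 4.0, 8.0, -1.0, 3.0, 5.0]
        med = np.median(errors)
        base = 1000.0
        spectra = [Spectrum(i, base * (1 + e * 1e-6), 2, 1.0, -48.0,
                            np.array([500.0 * (1 + e * 1e-6)]),
                            np.array([1.0]))
                   for i, e in enumerate(errors)]
        out, applied = recalibrate(spectra, errors)
        assert applied == med
        resid = [(s.precursor_mz / base - 1) * 1e6 for s in out]
        oracle = [(1 + e * 1e-6) / (1 + med * 1e-6) * 1e6 - 1e6
                  for e in errors]
        assert np.allclose(resid, oracle)
        assert np.median(resid) == pytest.approx(0.0, abs=1e-9)


class TestSearchEndToEnd:
    def test_single_known_pair_recovered(self, mass_cfg):
        import dataclasses

        from xlmsbench.denoise_search import search_crosslinks
        from xlmsbench.synthetic_data import SimConfig, simulate_spectrum
        from xlmsbench.xl_core import (CrosslinkCandidate, Peptide,
                                       fragment_ions, peptide_mass,
                                       PROTON_MASS)
        a = Peptide("ACKDLR", "P", 10)
        b = Peptide("GGKFVR", "P", 40)
        pm = (peptide_mass(a, mass_cfg) + peptide_mass(b, mass_cfg)
              + SIMPLE_LINKER.spacer_mass)
        cand = CrosslinkCandidate(a, b, 3, 3, pm)
        theo = np.sort([f.mz for f in fragment_ions(cand, SIMPLE_LINKER,
                                                    (1, 2), mass_cfg)])
        rng = np.random.default_rng(8)
        cfg = SimConfig(mass_error_ppm=(0.0, 0.0))
        z = 3
        spec = simulate_spectrum("t", z, -48.0, 5.0, 1e6, theo, cfg, rng, 1,
                                 precursor_mz=(pm + z * PROTON_MASS) / z)
        decoys = [Peptide("KLPWR", "D", 1, is_decoy=True),
                  Peptide("TTKGY", "D", 9, is_decoy=True)]
        csms = search_crosslinks([spec], [a, b] + decoys, SIMPLE_LINKER,
                                 DenoiseConfig())
        assert len(csms) == 1
        got = csms[0].candidate
        assert {got.peptide_a.sequence, got.peptide_b.sequence} == \
            {"ACKDLR", "GGKFVR"}
        assert csms[0].td_class == "TT"

    def test_shuffled_intensity_spectrum_scores_low(self, default_bundle):
        """A spectrum with randomized peak positions finds no convincing
        candidate relative to genuine CSM scores."""
        from xlmsbench.denoise_search import search_crosslinks
        ds = default_bundle.dataset
        real = ds.spectra[0]
        rng = np.random.default_rng(0)
        fake = Spectrum(99, real.precursor_mz, real.precursor_charge,
                        real.rt, real.cv,
                        np.sort(rng.uniform(150, 1900, real.peak_count())),
                        real.intensity.copy())
        peptides_db = default_bundle.csms  # genuine table for comparison
        from xlmsbench.pipeline import build_search_database
        db = build_search_database(ds.protein_id, ds.protein_sequence, 2)
        csms = search_crosslinks([fake], db, ds.linker, DenoiseConfig())
        genuine_median = peptides_db["score"].median()
        assert not csms or csms[0].score < 0.2 * genuine_median
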