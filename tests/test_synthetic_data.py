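"""Generator contracts: structure geometry, link statistics, FAIMS
transmission, feature/spectrum simulation and the DDA loop."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from conftest import CLEAVABLE_LINKER, SIMPLE_LINKER
from xlmsbench.synthetic_data import (
    AcquisitionMethod,
    SimConfig,
    cv_transmission,
    generate_protein_sequence,
    generate_structure,
    sample_true_links,
    simulate_acquisition,
    simulate_dataset,
    simulate_features,
    simulate_spectrum,
)


class TestStructure:
    def test_bond_lengths_and_determinism(self):
        st = generate_structure(150, seed=5)
        xyz = st.as_array()
        bonds = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        assert np.all(np.abs(bonds - 3.8) <= 0.1)
        st2 = generate_structure(150, seed=5)
        assert np.array_equal(xyz, st2.as_array())

    def test_exposure_proxy_matches_centroid_distance_oracle(self):
        st = generate_structure(80, seed=2)
        expo = st.exposure()
        xyz = st.as_array()
        d = np.linalg.norm(xyz - xyz.mean(axis=0), axis=1)
        oracle = (d - d.min()) / (d.max() - d.min())
        got = np.array([expo[i + 1] for i in range(80)])
        assert np.allclose(got, oracle)
        assert got.min() == 0.0 and got.max() == 1.0

    def test_too_few_residues_rejected(self):
        with pytest.raises(ValueError):
            generate_structure(2, seed=0)


class TestLinks:
    def _setup(self, **over):
        cfg = SimConfig(seed=4, n_residues=400, n_links=120, **over)
        rng = np.random.default_rng(cfg.seed)
        protein = generate_protein_sequence(cfg.n_residues, rng)
        st = generate_structure(cfg.n_residues, 99)
        return cfg, protein, st

    def test_overlength_zero_respects_cutoff(self):
        cfg, protein, st = self._setup(overlength_fraction=0.0)
        links = sample_true_links(st, protein, SIMPLE_LINKER, cfg)
        assert all(l.ca_distance <= SIMPLE_LINKER.max_distance
                   for l in links)

    def test_overlength_fraction_realized(self):
        cfg, protein, st = self._setup(overlength_fraction=0.25)
        links = sample_true_links(st, protein, SIMPLE_LINKER, cfg)
        frac = np.mean([l.ca_distance > SIMPLE_LINKER.max_distance
                        for l in links])
        assert frac == pytest.approx(0.25, abs=0.01)

    def test_zero_rho_decouples_abundance_from_exposure(self):
        cfg, protein, st = self._setup(exposure_abundance_rho=0.0)
        links = sample_true_links(st, protein, SIMPLE_LINKER, cfg)
        r = spearmanr([l.exposure for l in links],
                      [l.abundance for l in links]).statistic
        assert abs(r) < 0.2

    def test_rho_recovered_across_seeds(self):
        """Monte-Carlo: the abundance-exposure Spearman correlation
        averages close to the configured coupling of 0.6."""
        rs = []
        for seed in range(20):
            cfg = SimConfig(seed=seed, n_residues=450, n_links=80)
            rng = np.random.default_rng(seed)
            protein = generate_protein_sequence(cfg.n_residues, rng)
            st = generate_structure(cfg.n_residues, seed + 1000)
            links = sample_true_links(st, protein, SIMPLE_LINKER, cfg)
            rs.append(spearmanr([l.exposure for l in links],
                                [l.abundance for l in links]).statistic)
        assert abs(float(np.mean(rs)) - 0.6) <= 0.1

    def test_charge_profiles_normalized(self):
        cfg, protein, st = self._setup()
        for l in sample_true_links(st, protein, SIMPLE_LINKER, cfg):
            assert sum(l.charge_profile.values()) == pytest.approx(1.0)
            assert all(z >= 3 for z in l.charge_profile)


class TestCvTransmission:
    def test_high_charge_peaks_near_minus_49(self):
        cfg = SimConfig()
        grid = np.arange(-90.0, -29.0, 1.0)
        best = grid[np.argmax([cv_transmission(4, cv, cfg) for cv in grid])]
        assert best == -49.0

    def test_low_charge_peaks_near_minus_30_and_unimodal(self):
        cfg = SimConfig()
        assert cv_transmission(1, -90.0, cfg) < cv_transmission(1, -30.0, cfg)
        c, w = cfg.cv_profiles[2]
        assert cv_transmission(2, c - 7.0, cfg) == pytest.approx(
            cv_transmission(2, c + 7.0, cfg))


class TestFeatures:
    def _links(self, n=40):
        cfg = SimConfig(seed=8, n_residues=400, n_links=n)
        rng = np.random.default_rng(8)
        protein = generate_protein_sequence(400, rng)
        st = generate_structure(400, 21)
        return cfg, sample_true_links(st, protein, SIMPLE_LINKER, cfg)

    def test_count_matches_above_floor_enumeration_and_zero_error_mz(self):
        cfg, links = self._links()
        cfg0 = dataclasses.replace(cfg, mass_error_ppm=(0.0, 0.0))
        method = AcquisitionMethod()
        feats = simulate_features(links, method, cfg0)
        # brute-force oracle over (link, charge, CV)
        expected = 0
        for l in links:
            for z, frac in l.charge_profile.items():
                for cv in method.cv_program:
                    if l.abundance * frac * cv_transmission(z, cv, cfg0) \
                            >= cfg0.detection_floor:
                        expected += 1
        assert len(feats) == expected
        from xlmsbench.xl_core import PROTON_MASS
        by_link = {l.link_id: l for l in links}
        for _, row in feats.iterrows():
            theo = (by_link[row["link_id"]].candidate.precursor_mass
                    + row["charge"] * PROTON_MASS) / row["charge"]
            assert row["mz"] == pytest.approx(theo, abs=1e-9)
        assert (feats["intensitySum"] >= feats["intensityApex"]).all()

    def test_linear_response_to_abundance(self):
        cfg, links = self._links()
        cfg = dataclasses.replace(cfg, detection_floor=0.0)
        method = AcquisitionMethod()
        doubled = [dataclasses.replace(l, abundance=2 * l.abundance)
                   for l in links]
        f1 = simulate_features(links, method, cfg)
        f2 = simulate_features(doubled, method, cfg)
        assert np.allclose(f2["intensityApex"], 2 * f1["intensityApex"])


class TestSpectra:
    def test_zero_noise_peaks_all_theoretical(self):
        rng = np.random.default_rng(0)
        cfg = SimConfig(noise_peaks_per_100Da=0.0, mass_error_ppm=(0, 0))
        theo = np.sort(rng.uniform(200, 1500, 50))
        s = simulate_spectrum("XL0000", 3, -48.0, 10.0, 1e6, theo, cfg,
                              rng, scan_id=1)
        assert np.all(np.isin(np.round(s.mz, 6), np.round(theo, 6)))

    def test_doublet_partners_present_for_cleavable_linker(self, mass_cfg):
        from xlmsbench.denoise_search import detect_doublets
        from xlmsbench.xl_core import CrosslinkCandidate, Peptide, \
            fragment_ions, peptide_mass
        a, b = Peptide("GKAR", "P", 5), Peptide("KFR", "P", 30)
        pm = (peptide_mass(a, mass_cfg) + peptide_mass(b, mass_cfg)
              + CLEAVABLE_LINKER.spacer_mass)
        cand = CrosslinkCandidate(a, b, 2, 1, pm)
        theo = np.sort([f.mz for f in fragment_ions(
            cand, CLEAVABLE_LINKER, (1,), mass_cfg)])
        rng = np.random.default_rng(5)
        cfg = SimConfig(noise_peaks_per_100Da=0.0, mass_error_ppm=(0, 0))
        s = simulate_spectrum("XL0000", 3, -48.0, 10.0, 1e6, theo, cfg,
                              rng, scan_id=1)
        found = detect_doublets(s, CLEAVABLE_LINKER.doublet_delta, (1,), 5.0)
        assert len(found) >= 4  # every spanning fragment forms a doublet

    def test_mean_noise_rate(self):
        rng = np.random.default_rng(1)
        cfg = SimConfig(noise_peaks_per_100Da=3.0)
        counts = []
        for i in range(100):
            s = simulate_spectrum("n", 2, -48.0, 5.0, 1e6,
                                  np.array([500.0]), cfg, rng, i)
            counts.append(s.peak_count() - 1)
        span_windows = (2000.0 - 150.0) / 100.0
        assert np.mean(counts) / span_windows == pytest.approx(3.0, rel=0.1)


class TestAcquisition:
    @pytest.fixture(scope="class")
    def small_run(self):
        cfg = SimConfig(seed=3, n_residues=300, n_links=50,
                        n_linear_peptides=30)
        method = AcquisitionMethod(gradient_minutes=6.0)
        ds = simulate_dataset(cfg, method, SIMPLE_LINKER)
        return ds

    def test_ms2_bounded_by_topn_times_ms1(self, small_run):
        log = small_run.acquisition_log
        n_ms1 = (log["type"] == "MS1").sum()
        n_ms2 = (log["type"] == "MS2").sum()
        assert n_ms2 <= small_run.method.top_n * n_ms1

    def test_dynamic_exclusion_honored(self, small_run):
        ms2 = small_run.acquisition_log.query("type == 'MS2'")
        for (mz, cv), grp in ms2.groupby(
                [ms2["precursor_mz"].round(2), "cv"]):
            times = np.sort(grp["time"].to_numpy())
            if len(times) > 1:
                assert np.all(np.diff(times) >=
                              small_run.method.dynamic_exclusion)

    def test_low_charges_never_fragmented(self, small_run):
        ms2 = small_run.acquisition_log.query("type == 'MS2'")
        assert (ms2["charge"] >= 3).all()

    def test_charge_filter_blocks_low_charge_only_features(self):
        cfg = SimConfig(seed=1)
        feats = pd.DataFrame([dict(
            feature_id="F0", mz=600.0, charge=2, cv=-48.0, rt_apex=2.0,
            rt_start=1.0, rt_end=3.0, intensityApex=1e6, intensitySum=3e6,
            n_scans=5, source="linear", link_id="LIN:X@1")])
        method = AcquisitionMethod(gradient_minutes=4.0)
        log, _, ms2 = simulate_acquisition(feats, method, cfg,
                                           SIMPLE_LINKER, [], [])
        assert len(ms2) == 0
        assert (log["type"] == "MS1").sum() > 0

    def test_longer_gradient_non_decreasing_ms2(self):
        counts = []
        for minutes in (4.0, 8.0):
            cfg = SimConfig(seed=9, n_residues=300, n_links=40,
                            n_linear_peptides=10)
            method = AcquisitionMethod(gradient_minutes=minutes)
            ds = simulate_dataset(cfg, method, SIMPLE_LINKER)
            counts.append((ds.acquisition_log["type"] == "MS2").sum())
        assert counts[1] >= counts[0]

    def test_byte_identical_under_same_seed(self):
        cfg = SimConfig(seed=12, n_residues=300, n_links=40)
        method = AcquisitionMethod(gradient_minutes=4.0)
        d1 = simulate_dataset(cfg, method, SIMPLE_LINKER)
        d2 = simulate_dataset(cfg, method, SIMPLE_LINKER)
        pd.testing.assert_frame_equal(d1.features, d2.features)
        pd.testing.assert_frame_equal(d1.acquisition_log, d2.acquisition_log)
        assert all(np.array_equal(a.mz, b.mz) and
                   np.array_equal(a.intensity, b.intensity)
                   for a, b in zip(d1.spectra, d2.spectra))
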