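"""Synthetic study generation: libraries, designs, runs, ground truth."""

import numpy as np
import pandas as pd
import pytest

from tandemgc import gc2d
from tandemgc.stats import rsd
from tandemgc.synth import (SynthConfig, build_spectral_library,
                            make_study_design, simulate_alkane_run,
                            simulate_run, simulate_study, reference_class_effects)


class TestSpectralLibrary:
    def test_entry_count_and_empty_case(self):
        assert len(build_spectral_library(0, seed=0)) == 0
        assert len(build_spectral_library(25, seed=0)) == 25

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            build_spectral_library(-1, seed=0)

    def test_same_seed_reproduces_identical_library(self):
        a = build_spectral_library(12, seed=9)
        b = build_spectral_library(12, seed=9)
        assert a.names == b.names
        for ea, eb in zip(a, b):
            np.testing.assert_array_equal(ea.spectrum_70, eb.spectrum_70)
            np.testing.assert_array_equal(ea.spectrum_12, eb.spectrum_12)
            assert ea.response_70 == eb.response_70

    def test_dual_energy_character_of_named_entry(self):
        lib = build_spectral_library(15, seed=0)
        entry = lib["N-acetyl-D-glucosamine"]
        mz70 = set(entry.spectrum_70[:, 0].astype(int))
        assert {73, 129, 147} <= mz70
        # soft ionization re-weights toward the large diagnostic fragments
        s12 = entry.spectrum_12
        top3 = set(s12[np.argsort(-s12[:, 1])][:3, 0].astype(int))
        assert top3 <= {202, 319, 333}
        # and those fragments are minor at 70 eV
        s70 = dict(zip(entry.spectrum_70[:, 0].astype(int), entry.spectrum_70[:, 1]))
        s12d = dict(zip(s12[:, 0].astype(int), s12[:, 1]))
        assert all(s12d[m] > s70[m] for m in (202, 319, 333))

    def test_entry_invariants(self):
        lib = build_spectral_library(20, seed=3)
        cfg = SynthConfig()
        for e in lib:
            assert e.spectrum_70[:, 1].max() == pytest.approx(999.0)
            assert e.spectrum_12[:, 1].max() == pytest.approx(999.0)
            assert 0 < e.response_12 < e.response_70
            assert 0 <= e.two_d_time < cfg.modulation_period

    def test_named_subset_retention_indices(self):
        lib = build_spectral_library(15, seed=1)
        assert lib["urea"].ri == 1192
        assert lib["N-acetyl-D-glucosamine"].ri == 2052
        assert lib["sucrose"].ri == 2678

    def test_table_effect_ratio_convention(self):
        # +325.2% difference (MUO vs MHO) is the ratio 4.252
        effects = reference_class_effects()
        assert effects["D-(+)-glucuronic acid gamma-lactone"] == pytest.approx(4.252)
        assert effects["D-lactose"] == pytest.approx(0.125)


class TestStudyDesign:
    @pytest.mark.parametrize("args,expected", [
        ((4, 3, 5, 2, 2), 48),   # full study layout
        ((4, 0, 0, 2, 2), 16),   # QC repeatability subset
        ((1, 0, 0, 1, 1), 1),
    ])
    def test_run_counts(self, args, expected):
        assert make_study_design(*args).n_runs == expected

    def test_zero_reps_rejected(self):
        with pytest.raises(ValueError):
            make_study_design(4, 3, 5, 0, 2)

    def test_groups_and_unique_ids(self):
        d = make_study_design(4, 3, 5, 2, 2)
        assert set(d.groups()) == {"QC", "MHO", "MUO"}
        ids = [r.run_id for r in d.runs]
        assert len(set(ids)) == len(ids)
        assert sum(g == "MUO" for g in d.groups()) == 20


class TestSimulateRun:
    def test_empty_library_gives_baseline_only(self, quiet_config, single_run_design):
        lib = build_spectral_library(0, seed=0)
        sim = simulate_run(single_run_design.runs[0], lib, [], quiet_config, seed=0)
        image = gc2d.tic(sim.chromatogram("70eV")).image
        # monotone baseline ramp only: constant along the 2D axis
        assert np.ptp(image, axis=1).max() == pytest.approx(0.0, abs=1e-3)
        assert (np.diff(image[:, 0]) >= -1e-6).all()

    def test_abundance_length_mismatch(self, quiet_config, small_library,
                                       single_run_design):
        with pytest.raises(ValueError, match="length"):
            simulate_run(single_run_design.runs[0], small_library, [1.0],
                         quiet_config, seed=0)

    def test_noiseless_runs_identical_across_seeds(self, quiet_config,
                                                   small_library, single_run_design):
        entry = single_run_design.runs[0]
        a = simulate_run(entry, small_library, np.ones(8), quiet_config, seed=1)
        b = simulate_run(entry, small_library, np.ones(8), quiet_config, seed=2)
        np.testing.assert_array_equal(a.stream_70, b.stream_70)
        np.testing.assert_array_equal(a.stream_12, b.stream_12)

    def test_class_effect_scales_muo_volumes_exactly(self, quiet_config,
                                                     small_library):
        quiet_config.class_effects = {small_library.names[0]: 4.252}
        design = make_study_design(0, 1, 1, 1, 1)
        mho = next(r for r in design.runs if r.group == "MHO")
        muo = next(r for r in design.runs if r.group == "MUO")
        a = simulate_run(mho, small_library, np.ones(8), quiet_config, seed=0)
        b = simulate_run(muo, small_library, np.ones(8), quiet_config, seed=0)
        name = small_library.names[0]
        v_mho = a.truth.set_index("name").loc[name, "volume_70eV"]
        v_muo = b.truth.set_index("name").loc[name, "volume_70eV"]
        assert v_muo / v_mho == pytest.approx(4.252, rel=1e-9)
        other = small_library.names[1]
        assert (b.truth.set_index("name").loc[other, "volume_70eV"]
                == pytest.approx(a.truth.set_index("name").loc[other, "volume_70eV"]))

    def test_ground_truth_conservation(self, tiny_config, small_library,
                                       single_run_design):
        sim = simulate_run(single_run_design.runs[0], small_library,
                           np.ones(8), tiny_config, seed=4)
        total = gc2d.tic(sim.chromatogram("70eV")).image.sum()
        assert sim.truth["realized_70eV"].sum() <= total

    def test_channel_asymmetry(self, tiny_config, small_library, single_run_design):
        sim = simulate_run(single_run_design.runs[0], small_library,
                           np.ones(8), tiny_config, seed=4)
        assert sim.truth["realized_12eV"].sum() < sim.truth["realized_70eV"].sum()

    def test_same_seed_byte_identical(self, tiny_config, small_library,
                                      single_run_design):
        entry = single_run_design.runs[0]
        a = simulate_run(entry, small_library, np.ones(8), tiny_config, seed=7)
        b = simulate_run(entry, small_library, np.ones(8), tiny_config, seed=7)
        assert a.stream_70.tobytes() == b.stream_70.tobytes()
        assert a.stream_12.tobytes() == b.stream_12.tobytes()


class TestAlkaneRun:
    def test_emits_24_monotone_blobs(self, tiny_config):
        sim = simulate_alkane_run(tiny_config, seed=0)
        assert len(sim.truth) == 24
        assert sim.truth.carbon_number.tolist() == list(range(7, 31))
        assert (np.diff(sim.truth.rt1_min) > 0).all()

    def test_self_calibration_identity(self, tiny_config):
        from tandemgc.identification import RICalibration, retention_index

        sim = simulate_alkane_run(tiny_config, seed=0)
        calib = RICalibration(sim.truth.carbon_number.to_numpy(),
                              sim.truth.rt1_min.to_numpy())
        rt_c12 = float(sim.truth.set_index("carbon_number").loc[12, "rt1_min"])
        assert retention_index(rt_c12, calib) == pytest.approx(1200.0)


class TestJitterCalibration:
    def test_empirical_1d_rsd_matches_configuration(self, small_library):
        """Across 60 runs, the ¹D apex-time RSD ≈ the configured 0.20%."""
        cfg = SynthConfig(modulation_period=2.5, acquisition_rate=50.0,
                          n_modulations=120, mz_range=(45, 194),
                          noise_sigma_70=0.0, noise_sigma_12=0.0,
                          shot_noise=False)
        name = small_library.names[0]
        rts = []
        for k in range(60):
            sim = simulate_run(make_study_design(1, 0, 0, 1, 1).runs[0],
                               small_library, np.ones(8), cfg, seed=k)
            rts.append(sim.truth.set_index("name").loc[name, "rt1_min"])
        assert rsd(rts) == pytest.approx(0.20, rel=0.30)


class TestSimulateStudy:
    def test_yields_one_run_per_design_entry_deterministically(self, tiny_config,
                                                               small_library):
        design = make_study_design(1, 1, 1, 1, 1)
        runs_a = list(simulate_study(design, small_library, tiny_config, seed=3))
        runs_b = list(simulate_study(design, small_library, tiny_config, seed=3))
        assert [r.run.run_id for r in runs_a] == [r.run_id for r in design.runs]
        for a, b in zip(runs_a, runs_b):
            assert a.stream_70.tobytes() == b.stream_70.tobytes()
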