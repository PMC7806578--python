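"""Template matching, reliable-peak selection, alignment and quantification."""

import numpy as np
import pytest

from tandemgc.fingerprint import (FeatureMatrix, Match, TemplateEntry,
                                  Transform, build_composite,
                                  delineate_regions, fit_transform,
                                  match_template, quantify_features,
                                  reliable_threshold, select_reliable,
                                  template_from_peaks)
from tandemgc.peaks import Peak2D
from tandemgc.preprocess import NoiseEstimate
from tandemgc.specmatch import normalize_spectrum


def make_peak(rt1, rt2, spectrum, volume=1e6):
    return Peak2D(rt1=rt1, rt2=rt2, apex_pixel=(0, 0), volume=volume,
                  snr=500.0, spectrum=spectrum)


def spectrum_bank(rng, n):
    out = []
    for _ in range(n):
        mz = rng.choice(np.arange(50, 400), size=8, replace=False)
        out.append(normalize_spectrum(
            np.column_stack([mz, rng.uniform(50, 999, size=8)])))
    return out


class TestMatchTemplate:
    def make_set(self, rng, n=6):
        specs = spectrum_bank(rng, n)
        peaks = [make_peak(5.0 + k, 1.0 + 0.3 * k, s) for k, s in enumerate(specs)]
        template = template_from_peaks(peaks)
        return template, peaks

    def test_identity_matches_everything(self, rng):
        template, peaks = self.make_set(rng)
        matches = match_template(template, peaks, 0.125, 0.15)
        assert len(matches) == len(template)
        assert all(m.dmf == 999 for m in matches)

    def test_shift_within_window_matched_beyond_unmatched(self, rng):
        template, peaks = self.make_set(rng)
        for p in peaks:
            p.rt1 += 0.08
        assert len(match_template(template, peaks, 0.125, 0.15)) == len(peaks)
        for p in peaks:
            p.rt1 += 0.2
        assert match_template(template, peaks, 0.125, 0.15) == []

    def test_spectrally_scrambled_peak_unmatched(self, rng):
        template, peaks = self.make_set(rng, n=3)
        other = spectrum_bank(rng, 3)
        for p, s in zip(peaks, other):
            p.spectrum = s
        matches = match_template(template, peaks, 0.125, 0.15,
                                 min_dmf=750, min_rmf=750)
        assert matches == []

    def test_one_to_one_assignment(self, rng):
        template, peaks = self.make_set(rng)
        doubled = peaks + [make_peak(p.rt1 + 0.01, p.rt2, p.spectrum)
                           for p in peaks]
        matches = match_template(template, doubled, 0.125, 0.15)
        assert len(matches) == len(template)
        assert len({id(m.peak) for m in matches}) == len(matches)

    def test_gate_bounds_validated(self, rng):
        template, peaks = self.make_set(rng, 2)
        with pytest.raises(ValueError):
            match_template(template, peaks, 0.125, 0.15, min_dmf=1000)
        with pytest.raises(ValueError):
            match_template(template, peaks, -0.1, 0.15)


class TestSelectReliable:
    @pytest.mark.parametrize("n_runs,threshold", [(48, 25), (2, 2), (3, 2)])
    def test_more_than_half_rule(self, n_runs, threshold):
        assert reliable_threshold(n_runs) == threshold

    def test_selection_respects_threshold(self):
        counts = {"a": 25, "b": 24, "c": 48}
        assert set(select_reliable(counts, 48)) == {"a", "c"}
        assert select_reliable({"x": 1, "y": 2}, 2) == ["y"]


class TestFitTransform:
    def test_known_affine_recovered(self, rng):
        t = rng.uniform([5, 0.5], [30, 4.5], size=(12, 2))
        r1 = 1.01 * t[:, 0] + 0.05
        r2 = 0.97 * t[:, 1] - 0.02
        tr = fit_transform(list(zip(map(tuple, t), zip(r1, r2))))
        assert tr.a1 == pytest.approx(1.01, abs=1e-9)
        assert tr.b1 == pytest.approx(0.05, abs=1e-9)
        assert tr.a2 == pytest.approx(0.97, abs=1e-9)
        assert tr.b2 == pytest.approx(-0.02, abs=1e-9)
        assert tr.rms_residual == pytest.approx(0.0, abs=1e-6)

    def test_identity_pairs(self, rng):
        t = rng.uniform([5, 0.5], [30, 4.5], size=(5, 2))
        tr = fit_transform(list(zip(map(tuple, t), map(tuple, t))))
        assert (tr.a1, tr.b1, tr.a2, tr.b2) == pytest.approx((1, 0, 1, 0), abs=1e-9)

    def test_noisy_pairs_residual_bounded(self, rng):
        sigma = 0.01
        t = rng.uniform([5, 0.5], [30, 4.5], size=(100, 2))
        r = t + rng.normal(0, sigma, size=t.shape)
        tr = fit_transform(list(zip(map(tuple, t), map(tuple, r))))
        # rms combines both dimensions (1D converted to seconds)
        assert tr.rms_residual <= 2 * sigma * np.sqrt(60**2 + 1)

    def test_too_few_or_degenerate_pairs(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_transform([((1, 1), (1, 1)), ((2, 2), (2, 2))])
        with pytest.raises(ValueError, match="span"):
            fit_transform([((1, 1), (1, 1)), ((1, 2), (1, 2)), ((1, 3), (1, 3))])

    def test_inversion_round_trip(self):
        tr = Transform(1.02, 0.3, 0.95, -0.1)
        rt1, rt2 = tr.invert().apply(*tr.apply(10.0, 2.0))
        assert (float(rt1), float(rt2)) == pytest.approx((10.0, 2.0))


class TestComposite:
    def test_single_run_identity_transform(self, image_factory, blob_factory):
        img = image_factory(blob_factory((120, 125), (60, 60), (2, 2.5), 1e6))
        comp = build_composite([img], [Transform()])
        np.testing.assert_allclose(comp.image, img.image, atol=1e-9)

    def test_n_copies_scale(self, image_factory, blob_factory):
        img = image_factory(blob_factory((120, 125), (60, 60), (2, 2.5), 1e6))
        comp = build_composite([img] * 4, [Transform()] * 4)
        np.testing.assert_allclose(comp.image, 4 * img.image, atol=1e-9)
        mean = build_composite([img] * 4, [Transform()] * 4, mode="mean")
        np.testing.assert_allclose(mean.image, img.image, atol=1e-9)

    def test_shifted_runs_realigned(self, image_factory, blob_factory):
        """A run whose retention times are globally scaled is pulled back onto
        the template blob position by its fitted transform."""
        base = image_factory(blob_factory((120, 125), (60, 70), (2, 2.5), 1e6))
        shifted = image_factory(blob_factory((120, 125), (66, 70), (2, 2.5), 1e6))
        # template rt -> run rt: row 60 maps to row 66
        tr = Transform(a1=1.1, b1=0.0)
        comp = build_composite([base, shifted], [Transform(), tr])
        apex = np.unravel_index(np.argmax(comp.image), comp.image.shape)
        assert abs(apex[0] - 60) <= 1 and abs(apex[1] - 70) <= 1
        assert comp.image.max() == pytest.approx(2 * base.image.max(), rel=0.05)


class TestRegionsAndQuantify:
    def test_regions_found_and_disjoint(self, image_factory, blob_factory):
        img = np.zeros((120, 125))
        centers = [(20, 30), (60, 60), (100, 90)]
        for c in centers:
            img += blob_factory((120, 125), c, (2, 2.5), 1e6)
        comp = image_factory(img)
        regions = delineate_regions(comp, min_counts=1e5, min_snr=0.0,
                                    noise=NoiseEstimate(10.0))
        assert len(regions) == 3
        seen = set()
        for r in regions:
            px = set(map(tuple, r.region_pixels))
            assert not (px & seen)
            seen |= px

    def test_blob_below_gate_yields_no_region(self, image_factory, blob_factory):
        comp = image_factory(blob_factory((120, 125), (60, 60), (2, 2.5), 1e4))
        assert delineate_regions(comp, min_counts=1e5, min_snr=0.0,
                                 noise=NoiseEstimate(10.0)) == []

    def test_quantify_recovers_per_run_volumes(self, image_factory, blob_factory):
        img = image_factory(blob_factory((120, 125), (60, 60), (2, 2.5), 1e6))
        comp = build_composite([img] * 3, [Transform()] * 3)
        regions = delineate_regions(comp, min_counts=1e5, min_snr=0.0,
                                    noise=NoiseEstimate(10.0))
        fm = quantify_features([img] * 3, regions, [Transform()] * 3,
                               ["a", "b", "c"], ["QC", "MHO", "MUO"])
        region_total = comp.image[regions[0].region_pixels[:, 0],
                                  regions[0].region_pixels[:, 1]].sum()
        np.testing.assert_allclose(fm.volumes.iloc[:, 0], region_total / 3,
                                   rtol=1e-9)

    def test_empty_region_set_gives_empty_matrix(self, image_factory):
        img = image_factory(np.zeros((20, 30)))
        fm = quantify_features([img], [], [Transform()], ["a"], ["QC"])
        assert fm.volumes.shape == (1, 0)

    def test_region_outside_run_warns_and_zero(self, image_factory, blob_factory):
        img = image_factory(blob_factory((120, 125), (60, 60), (2, 2.5), 1e6))
        region = TemplateEntry(id="R0", expected_rt1=0, expected_rt2=0,
                               kind="peak_region",
                               region_pixels=np.array([[500, 500]]))
        with pytest.warns(UserWarning, match="outside"):
            fm = quantify_features([img], [region], [Transform()], ["a"], ["QC"])
        assert fm.volumes.iloc[0, 0] == 0.0

    def test_negative_volumes_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            FeatureMatrix(volumes=pd.DataFrame([[-1.0]], index=["a"]),
                          groups=pd.Series(["QC"], index=["a"]))
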