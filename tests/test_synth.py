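"""Generators: zero-noise identities, seed determinism, truth echoes."""

import numpy as np
import pytest

import cellugel as cg
from cellugel import synth


class TestSaxsGenerator:
    def test_zero_noise_equals_forward_model(self, space_upper_params):
        cfg = cg.SynthConfig(kind="saxs", noise=0.0, truth=space_upper_params.to_dict())
        curve = cg.generate_saxs_curve(cfg)
        assert np.array_equal(curve.intensity,
                              cg.unified_intensity(space_upper_params, curve.q))

    def test_fractional_residual_sd_matches_noise_level(self, space_upper_params):
        cfg = cg.SynthConfig(kind="saxs", seed=1, noise=0.02,
                             grid={"n": 200}, truth=space_upper_params.to_dict())
        curve = cg.generate_saxs_curve(cfg)
        model = cg.unified_intensity(space_upper_params, curve.q)
        resid = curve.intensity / model - 1.0
        assert 0.015 <= resid.std(ddof=1) <= 0.025

    def test_seed_determinism(self, space_upper_params):
        cfg = cg.SynthConfig(kind="saxs", seed=9, noise=0.05,
                             truth=space_upper_params.to_dict())
        a = cg.generate_saxs_curve(cfg)
        b = cg.generate_saxs_curve(cfg)
        assert np.array_equal(a.intensity, b.intensity)
        assert np.array_equal(a.q, b.q)

    def test_sigma_reported_as_noise_times_model(self, space_upper_params):
        cfg = cg.SynthConfig(kind="saxs", seed=2, noise=0.03,
                             truth=space_upper_params.to_dict())
        curve = cg.generate_saxs_curve(cfg)
        model = cg.unified_intensity(space_upper_params, curve.q)
        assert np.allclose(curve.sigma, 0.03 * model)

    def test_intensity_stays_positive_and_oversized_noise_rejected(self, space_upper_params):
        # below the 5-sigma positivity bound (noise < 0.2) output is positive
        cfg = cg.SynthConfig(kind="saxs", seed=0, noise=0.15, grid={"n": 500},
                             truth=space_upper_params.to_dict())
        assert np.all(cg.generate_saxs_curve(cfg).intensity > 0)
        # beyond it even +-5-truncated draws cannot guarantee positivity
        cfg = cg.SynthConfig(kind="saxs", seed=0, noise=0.3, grid={"n": 500},
                             truth=space_upper_params.to_dict())
        with pytest.raises(ValueError):
            cg.generate_saxs_curve(cfg)

    def test_truth_echoed(self, space_upper_params):
        cfg = cg.SynthConfig(kind="saxs", noise=0.0, truth=space_upper_params.to_dict())
        curve = cg.generate_saxs_curve(cfg)
        assert curve.meta["truth"] == space_upper_params.to_dict()


class TestWaxsGenerator:
    def test_no_peaks_no_noise_equals_background(self):
        cfg = cg.SynthConfig(kind="waxs", noise=0.0, truth={"peaks": []})
        prof = cg.generate_waxs_profile(cfg)
        bg = synth.waxs_background(prof.q, synth.DEFAULT_WAXS_BACKGROUND)
        assert np.array_equal(prof.intensity, bg)

    def test_single_peak_integrated_area(self):
        cfg = cg.SynthConfig(kind="waxs", noise=0.0,
                             truth={"peaks": [[15.6, 0.35, 200.0]]})
        prof = cg.generate_waxs_profile(cfg)
        bg = synth.waxs_background(prof.q, synth.DEFAULT_WAXS_BACKGROUND)
        area = np.trapezoid(prof.intensity - bg, prof.q)
        assert area == pytest.approx(200.0, rel=0.005)

    def test_cellulose_positions_generated_exactly(self):
        peaks = [[8.69, 0.5, 120.0], [14.1, 0.45, 80.0], [15.6, 0.35, 200.0]]
        cfg = cg.SynthConfig(kind="waxs", noise=0.0, truth={"peaks": peaks})
        prof = cg.generate_waxs_profile(cfg)
        assert prof.meta["truth"]["peaks"] == [list(map(float, p)) for p in peaks]

    def test_overlapping_peaks_flagged_unresolvable(self):
        cfg = cg.SynthConfig(kind="waxs", noise=0.0,
                             truth={"peaks": [[10.0, 1.0, 50.0], [10.1, 1.0, 50.0]]})
        prof = cg.generate_waxs_profile(cfg)
        assert prof.meta.get("unresolvable") is True

    def test_nonmonotone_background_rejected(self):
        cfg = cg.SynthConfig(kind="waxs", noise=0.0,
                             truth={"peaks": [], "background": [0.0, 20.0, -1.0]})
        with pytest.raises(ValueError):
            cg.generate_waxs_profile(cfg)


class TestMaldiGenerator:
    def test_dp_range_yields_eight_peak_positions(self):
        cfg = cg.SynthConfig(kind="maldi", noise=0.0, truth={"mean_dp": 6.9})
        sp = cg.generate_maldi_spectrum(cfg)
        assert len(sp.meta["truth"]["peak_mz"]) == 8

    def test_consecutive_positions_spaced_by_residue_mass(self):
        cfg = cg.SynthConfig(kind="maldi", noise=0.0, truth={"mean_dp": 6.9})
        sp = cg.generate_maldi_spectrum(cfg)
        diffs = np.diff(sp.meta["truth"]["peak_mz"])
        assert np.allclose(diffs, 162.14)

    def test_envelope_weighted_mean_recovers_mean_dp(self):
        cfg = cg.SynthConfig(kind="maldi", noise=0.0, truth={"mean_dp": 6.9})
        sp = cg.generate_maldi_spectrum(cfg)
        n = np.arange(sp.meta["truth"]["dp_min"], sp.meta["truth"]["dp_max"] + 1)
        h = np.array(sp.meta["truth"]["peak_heights"])
        assert np.sum(n * h) / np.sum(h) == pytest.approx(6.9, abs=0.01)

    def test_empty_dp_range_rejected(self):
        cfg = cg.SynthConfig(kind="maldi", truth={"dp_min": 8, "dp_max": 4})
        with pytest.raises(ValueError):
            cg.generate_maldi_spectrum(cfg)

    def test_seed_determinism(self):
        cfg = cg.SynthConfig(kind="maldi", seed=4, noise=0.05, truth={"mean_dp": 6.0})
        a = cg.generate_maldi_spectrum(cfg)
        b = cg.generate_maldi_spectrum(cfg)
        assert np.array_equal(a.intensity, b.intensity)


class TestRibbonGenerator:
    def test_horizontal_ribbon_has_requested_column_thickness(self):
        canvas = np.full((128, 128), 20.0)
        synth.render_ribbon(canvas, (64.0, 64.0), 0.0, 100.0, 11.0)
        cols = (canvas[:, 40:89] > 100).sum(axis=0)
        assert np.all(cols == 11)

    def test_drawn_width_sample_mean_near_configured_mean(self):
        cfg = cg.SynthConfig(kind="ribbon_image", seed=5,
                             grid={"pixel_size_um": 0.05},
                             truth={"n_ribbons": 200, "width_mean_um": 0.254,
                                    "width_sd_um": 0.128})
        img = cg.generate_ribbon_image(cfg)
        widths = np.array(img.meta["truth"]["widths_um"])
        assert widths.size == 200
        assert abs(widths.mean() - 0.254) / 0.254 < 0.05

    def test_seed_determinism(self):
        cfg = cg.SynthConfig(kind="ribbon_image", seed=2, grid={"shape": (256, 256)},
                             truth={"n_ribbons": 20})
        a = cg.generate_ribbon_image(cfg)
        b = cg.generate_ribbon_image(cfg)
        assert np.array_equal(a.pixels, b.pixels)

    def test_subpixel_width_request_rejected(self):
        cfg = cg.SynthConfig(kind="ribbon_image", grid={"pixel_size_um": 0.05},
                             truth={"width_um": 0.10, "n_ribbons": 5})
        with pytest.raises(ValueError):
            cg.generate_ribbon_image(cfg)


class TestTextRoundTrips:
    def test_curve_round_trip_preserves_data_and_truth(self, tmp_path,
                                                       space_upper_params):
        cfg = cg.SynthConfig(kind="saxs", seed=1, noise=0.02,
                             truth=space_upper_params.to_dict())
        curve = cg.generate_saxs_curve(cfg)
        path = tmp_path / "curve.dat"
        cg.write_curve(curve, path)
        back = cg.read_curve(path)
        assert np.allclose(back.q, curve.q)
        assert np.allclose(back.intensity, curve.intensity)
        assert np.allclose(back.sigma, curve.sigma)
        assert back.meta["truth"] == curve.meta["truth"]

    def test_angstrom_unit_conversion_on_read(self, tmp_path):
        path = tmp_path / "curve_aa.dat"
        q_aa = np.linspace(0.01, 0.25, 20)
        np.savetxt(path, np.column_stack([q_aa, np.ones(20)]))
        curve = cg.read_curve(path, q_unit="angstrom")
        assert np.allclose(curve.q, q_aa * 10)

    def test_micrograph_round_trip_with_sidecar(self, tmp_path):
        cfg = cg.SynthConfig(kind="ribbon_image", seed=3, grid={"shape": (128, 128)},
                             truth={"n_ribbons": 5})
        img = cg.generate_ribbon_image(cfg)
        path = tmp_path / "ribbons.png"
        cg.write_micrograph(img, path)
        back = cg.read_micrograph(path)
        assert np.array_equal(back.pixels, img.pixels)
        assert back.pixel_size == img.pixel_size
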