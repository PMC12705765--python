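import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import flarequant as fq
from flarequant.sorting_kymo import (
    LineROI,
    extract_profile,
    kymograph,
    sorting_coefficient,
)
from flarequant.synthgen import truth_profile_lines
from flarequant.types import ImageStack


class TestExtractProfile:
    def test_constant_image_gives_constant_profile(self):
        roi = LineROI(((5.0, 2.0), (5.0, 20.0)), step_px=1.0, half_width_px=1)
        profile = extract_profile(np.full((30, 30), 13.0), roi)
        assert np.allclose(profile, 13.0)
        assert len(profile) == 19

    def test_step_edge_reproduced(self):
        img = np.zeros((20, 40))
        img[:, 20:] = 10.0
        roi = LineROI(((10.0, 5.0), (10.0, 35.0)), step_px=1.0, half_width_px=0)
        profile = extract_profile(img, roi)
        assert np.allclose(profile[:14], 0.0)
        assert np.allclose(profile[-14:], 10.0)

    def test_diagonal_ramp_matches_closed_form(self):
        # f(r, c) = 2r + 3c is reproduced exactly by bilinear interpolation
        rr, cc = np.mgrid[0:40, 0:40]
        img = 2.0 * rr + 3.0 * cc
        roi = LineROI(((5.0, 5.0), (30.0, 35.0)), step_px=0.7, half_width_px=0)
        points, _ = roi.sample_points()
        expected = 2.0 * points[:, 0] + 3.0 * points[:, 1]
        assert np.allclose(extract_profile(img, roi), expected, atol=1e-9)

    def test_roi_outside_image_rejected(self):
        roi = LineROI(((5.0, -3.0), (5.0, 10.0)))
        with pytest.raises(ValueError, match="leaves the image"):
            extract_profile(np.zeros((20, 20)), roi)

    def test_band_averaging_uses_perpendicular_offsets(self):
        img = np.zeros((21, 21))
        img[9, :], img[10, :], img[11, :] = 3.0, 6.0, 3.0
        roi = LineROI(((10.0, 3.0), (10.0, 17.0)), step_px=1.0, half_width_px=1)
        assert np.allclose(extract_profile(img, roi), 4.0)  # (3 + 6 + 3) / 3

    def test_roi_json_roundtrip(self, tmp_path):
        roi = LineROI(((1.0, 2.0), (3.0, 4.0), (7.0, 4.0)), step_px=0.5, half_width_px=2)
        p = tmp_path / "roi.json"
        p.write_text(__import__("json").dumps(roi.to_json()))
        assert LineROI.from_json(p) == roi


class TestSortingCoefficient:
    def test_identical_channels_give_one(self):
        rng = np.random.default_rng(6)
        inv, pm = rng.uniform(10, 50, 20), rng.uniform(10, 50, 25)
        m = sorting_coefficient(inv, inv, pm, pm, background_rule=(0.0, 0.0))
        assert m.sorting_coefficient == pytest.approx(1.0)

    def test_forced_arithmetic_on_densities(self):
        # densities 200 / 100 / 50 / 100 -> (2.0) / (0.5) = 4.0
        m = sorting_coefficient(np.array([200.0]), np.array([100.0]),
                                np.array([50.0]), np.array([100.0]),
                                background_rule=(0.0, 0.0))
        assert m.sorting_coefficient == pytest.approx(4.0)
        assert (m.f_tested_invag, m.f_ref_invag, m.f_tested_pm, m.f_ref_pm) == \
            (200.0, 100.0, 50.0, 100.0)

    def test_background_subtraction_precedes_integration(self):
        # clamping at 0 before summing: sum(clip(p - bg)) != clip(sum(p) - n*bg)
        profile = np.array([10.0, 0.0])
        m = sorting_coefficient(profile, np.array([5.0, 5.0]),
                                np.array([5.0, 5.0]), np.array([5.0, 5.0]),
                                background_rule=(5.0, 0.0))
        assert m.f_tested_invag == pytest.approx(5.0)  # not max(10 - 10, 0) = 0

    def test_nonpositive_denominator_flagged_undefined(self):
        m = sorting_coefficient(np.array([5.0]), np.array([0.0]),
                                np.array([5.0]), np.array([5.0]),
                                background_rule=(0.0, 0.0))
        assert not m.defined and "undefined" in m.flags

    def test_saturation_flagged(self):
        m = sorting_coefficient(np.array([255.0, 10.0]), np.array([5.0]),
                                np.array([5.0]), np.array([5.0]),
                                background_rule="min", saturation_value=255)
        assert "saturated" in m.flags

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale_t=st.floats(0.01, 100), scale_r=st.floats(0.01, 100))
    def test_invariant_under_independent_channel_scaling(self, scale_t, scale_r):
        rng = np.random.default_rng(7)
        inv_t, inv_r = rng.uniform(10, 50, 15), rng.uniform(10, 50, 15)
        pm_t, pm_r = rng.uniform(10, 50, 15), rng.uniform(10, 50, 15)
        base = sorting_coefficient(inv_t, inv_r, pm_t, pm_r, (0.0, 0.0))
        scaled = sorting_coefficient(scale_t * inv_t, scale_r * inv_r,
                                     scale_t * pm_t, scale_r * pm_r, (0.0, 0.0))
        assert scaled.sorting_coefficient == pytest.approx(
            base.sorting_coefficient, rel=1e-9)

    def test_proportional_channels_give_one_regardless_of_geometry(self):
        rng = np.random.default_rng(8)
        inv_r, pm_r = rng.uniform(10, 50, 12), rng.uniform(10, 50, 33)
        m = sorting_coefficient(2.7 * inv_r, inv_r, 2.7 * pm_r, pm_r, (0.0, 0.0))
        assert m.sorting_coefficient == pytest.approx(1.0)

    def test_noise_free_simulated_cell_recovers_sorting_factor(self, noiseless):
        spec = fq.CellSpec(center=(60.0, 60.0), n_invaginations=1, sorting_factor=3.0,
                           n_foci=0)
        stack, mask, gt = fq.generate_field([spec], noiseless, shape=(128, 128))
        lines = truth_profile_lines(gt, 1)
        roi_i = LineROI(tuple(lines["invagination"]), step_px=0.5, half_width_px=0)
        roi_p = LineROI(tuple(lines["pm"]), step_px=0.5, half_width_px=0)
        t, r = stack.channel("tested"), stack.channel("reference")
        m = sorting_coefficient(extract_profile(t, roi_i), extract_profile(r, roi_i),
                                extract_profile(t, roi_p), extract_profile(r, roi_p),
                                background_rule=(0.0, 0.0))
        assert m.sorting_coefficient == pytest.approx(3.0, rel=1e-9)


class TestKymograph:
    def test_static_timelapse_gives_identical_rows(self, noiseless):
        spec = fq.CellSpec(center=(50.0, 50.0))
        kin = fq.KineticsSpec(internalization_rate_per_min=0.0, spike_amplitude=0.0,
                              pm_fraction_end=spec.pm_fraction)
        stack, _, _ = fq.generate_timelapse([spec], kin, noiseless, n_frames=6,
                                            shape=(100, 100))
        roi = LineROI(((50.0, 20.0), (50.0, 80.0)))
        kymo = kymograph(stack, roi, channel="tested")
        assert np.allclose(kymo, kymo[0])

    def test_shape_is_frames_by_samples(self):
        data = np.zeros((30, 2, 20, 50), np.float32)
        stack = ImageStack(data, "TCYX", frame_interval_min=1.0,
                           channel_names=("reference", "tested"))
        roi = LineROI(((10.0, 5.0), (10.0, 44.0)), step_px=1.0)
        assert kymograph(stack, roi).shape == (30, 40)

    def test_moving_spot_traces_unit_slope(self):
        n = 25
        rr, cc = np.mgrid[0:21, 0:60]
        frames = []
        for t in range(n):
            img = 100.0 * np.exp(-(((rr - 10) ** 2 + (cc - (15 + t)) ** 2) / 8.0))
            frames.append(np.stack([img, img]))
        stack = ImageStack(np.stack(frames), "TCYX", frame_interval_min=1.0,
                           channel_names=("reference", "tested"))
        roi = LineROI(((10.0, 5.0), (10.0, 55.0)), step_px=1.0, half_width_px=1)
        kymo = kymograph(stack, roi)
        peaks = kymo.argmax(axis=1)
        assert np.all(np.diff(peaks) >= 0)
        slope = np.polyfit(np.arange(n), peaks, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.5)
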