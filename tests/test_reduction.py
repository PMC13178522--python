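"""Reduction tests: centring/tilt, mirroring, ROI integration, hull baseline."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibrediff.frames import DetectorFrame
from fibrediff.profiles import Band, Profile1D, DEFAULT_ROIS
from fibrediff.reduction import (CentringError, arc_hull_baseline,
                                 find_centre_and_tilt, integrate, mirror,
                                 subtract_background_frame)
from fibrediff.simulate import render_frame, simulate_timecourse_truth, \
    tetanus_config


class TestCentring:
    def test_offset_and_tilt_recovered(self, rest_frame):
        """2.3 px diagonal offset and 0.4° tilt recovered to 0.2 px / 0.05°."""
        corrected = find_centre_and_tilt(rest_frame)
        cz, cr = corrected.beam_centre
        assert abs(cz - 951.7) < 0.2
        assert abs(cr - 377.7) < 0.2
        assert abs(corrected.provenance["centring"]["tilt_removed_deg"]
                   - 0.4) < 0.05

    def test_already_centred_frame_identity(self):
        config = tetanus_config(seed=11, beam_offset=(0.0, 0.0), tilt=0.0)
        truth = simulate_timecourse_truth(config)
        frame = render_frame(truth, 0, noise=False)
        corrected = find_centre_and_tilt(frame)
        assert abs(corrected.beam_centre[0] - 950.0) < 0.05
        assert abs(corrected.beam_centre[1] - 380.0) < 0.05
        assert abs(corrected.provenance["centring"]["tilt_removed_deg"]) < 0.01

    def test_masked_10_reflection_uses_other_pair(self, tetanus_truth):
        frame = render_frame(tetanus_truth, 0, bank="sa").copy()
        # mask a generous region over the +radial 1,0 spot
        q10_px = (1.0 / 39.10) / 2e-4
        c0 = int(377.7 + q10_px)
        frame.tile_mask[:, c0 - 15:c0 + 15] = True
        frame.pixels[:, c0 - 15:c0 + 15] = 0
        corrected = find_centre_and_tilt(frame)
        assert abs(corrected.beam_centre[0] - 951.7) < 0.4
        assert abs(corrected.beam_centre[1] - 377.7) < 0.4

    def test_featureless_frame_reports_failure(self):
        frame = DetectorFrame(pixels=np.full((301, 301), 10.0),
                              beam_centre=(150.0, 150.0))
        with pytest.raises(CentringError, match="not detected"):
            find_centre_and_tilt(frame)


class TestMirror:
    def test_symmetric_noise_free_frame_unchanged_by_both(self):
        config = tetanus_config(seed=0, beam_offset=(0.0, 0.0), tilt=0.0)
        truth = simulate_timecourse_truth(config)
        frame = render_frame(truth, 0, noise=False)
        out = mirror(frame, "both")
        ok = ~out.tile_mask & ~frame.tile_mask
        assert np.allclose(out.pixels[ok], frame.pixels[ok], rtol=1e-4,
                           atol=1e-2)

    def test_mirroring_idempotent(self, rest_frame):
        corrected = find_centre_and_tilt(rest_frame)
        once = mirror(corrected, "both")
        twice = mirror(once, "both")
        ok = ~once.tile_mask & ~twice.tile_mask
        assert np.allclose(once.pixels[ok], twice.pixels[ok], rtol=1e-4,
                           atol=0.5)

    def test_four_quadrant_average_reduces_variance(self, rng):
        """Averaging four independent Poisson quadrants cuts the per-pixel
        variance about fourfold."""
        expected = np.full((201, 201), 100.0)
        draws = []
        for k in range(40):
            frame = DetectorFrame(
                pixels=rng.poisson(expected).astype(float),
                beam_centre=(100.0, 100.0))
            draws.append(mirror(frame, "both").pixels[40:60, 40:60])
        var_mirrored = np.var(np.stack(draws), axis=0).mean()
        assert var_mirrored == pytest.approx(100.0 / 4, rel=0.2)

    def test_quadrant_select_fills_masked_gap(self, tetanus_truth):
        frame = render_frame(tetanus_truth, 0, bank="sa")
        corrected = find_centre_and_tilt(frame)
        # default camera has a tile gap on the +radial side only
        assert corrected.tile_mask.any()
        out = mirror(corrected, "quadrant-select", use=("identity", "h"))
        band = integrate(out, "axial", DEFAULT_ROIS["AL6_radial"],
                         side="positive")
        assert np.all(np.isfinite(band.intensity))

    def test_unknown_mode_rejected(self, rest_frame):
        with pytest.raises(ValueError):
            mirror(rest_frame, "diagonal")


class TestIntegrate:
    def _uniform(self, value=7.0):
        return DetectorFrame(pixels=np.full((101, 101), value),
                             beam_centre=(50.0, 50.0))

    def test_uniform_frame_band_sum(self):
        frame = self._uniform(7.0)
        prof = integrate(frame, "meridional", Band(0.0, 0.0038))
        n_cols = np.sum(np.abs(frame.q_radial()) <= 0.0038)
        assert np.allclose(prof.intensity, 7.0 * n_cols)

    def test_linearity(self, rest_frame_reduced):
        scaled = rest_frame_reduced.copy()
        scaled.pixels = scaled.pixels * 3.0
        p1 = integrate(rest_frame_reduced, "meridional", Band(0.0, 0.0038))
        p3 = integrate(scaled, "meridional", Band(0.0, 0.0038))
        assert np.allclose(p3.intensity, 3.0 * p1.intensity)

    def test_equatorial_peaks_at_hexagonal_positions(self, rest_frame_reduced):
        """Resting equator shows 1,0 and 1,1 peaks at 1/39.10 and √3/39.10."""
        prof = integrate(rest_frame_reduced, "equatorial",
                         DEFAULT_ROIS["equatorial_halfwidth"])
        _, sub = arc_hull_baseline(prof, smoothing=2)
        for expected in (1.0 / 39.10, math.sqrt(3) / 39.10):
            sel = np.abs(sub.q - expected) < 0.003
            peak_q = sub.q[sel][np.argmax(sub.intensity[sel])]
            assert abs(peak_q - expected) < 4e-4

    def test_rendered_meridional_doublet_centroid(self, tetanus_truth,
                                                  rest_frame_reduced):
        """The rendered M6 cluster appears in the meridional profile with its
        centroid at the truth weighted spacing within 0.1 bin."""
        prof = integrate(rest_frame_reduced, "meridional",
                         DEFAULT_ROIS["meridional_halfwidth"])
        _, sub = arc_hull_baseline(prof, smoothing=2)
        win = sub.window(0.135, 0.142)
        centroid = np.sum(win.q * win.intensity) / np.sum(win.intensity)
        expected = 1.0 / tetanus_truth.series("S_M6")[0]
        assert abs(centroid - expected) < 0.1 * 2e-4

    def test_fully_masked_band_rejected(self):
        frame = self._uniform()
        frame.tile_mask[:] = True
        prof = integrate(frame, "meridional", Band(0.0, 0.0038))
        assert np.all(np.isinf(prof.variance))


class TestArcHullBaseline:
    def test_gaussian_on_straight_line_area_recovered(self):
        """Peak area on a linear background is recovered within 2%."""
        q = np.linspace(0.0, 0.1, 400)
        sigma, amp = 0.003, 800.0
        peak = amp * np.exp(-0.5 * ((q - 0.05) / sigma) ** 2)
        prof = Profile1D(q=q, intensity=peak + 200.0 - 1000.0 * q)
        _, sub = arc_hull_baseline(prof, smoothing=0)
        area = np.trapezoid(sub.intensity, q)
        assert area == pytest.approx(amp * sigma * math.sqrt(2 * math.pi),
                                     rel=0.02)

    def test_convex_profile_subtracts_to_noise_level(self):
        q = np.linspace(0, 1, 200)
        prof = Profile1D(q=q, intensity=np.exp(-3 * q) * 100)
        _, sub = arc_hull_baseline(prof, smoothing=0)
        assert np.all(np.abs(sub.intensity) < 0.05)

    def test_all_zero_profile(self):
        prof = Profile1D(q=np.arange(10.0), intensity=np.zeros(10))
        base, sub = arc_hull_baseline(prof)
        assert np.allclose(base.intensity, 0)
        assert np.allclose(sub.intensity, 0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            arc_hull_baseline(Profile1D(q=np.arange(2.0),
                                        intensity=np.ones(2)))

    @given(st.integers(0, 2 ** 31 - 1), st.integers(0, 3))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_baseline_never_exceeds_smoothed_profile(self, seed, smoothing):
        """Hull property: baseline ≤ boxcar-smoothed intensity at every bin."""
        rg = np.random.default_rng(seed)
        q = np.sort(rg.uniform(0, 1, 50))
        q += np.arange(50) * 1e-6  # guarantee strictly increasing
        y = rg.uniform(0, 100, 50)
        prof = Profile1D(q=q, intensity=y)
        base, _ = arc_hull_baseline(prof, smoothing=smoothing)
        win = 2 * smoothing + 1
        ysm = np.convolve(np.pad(y, smoothing, mode="edge"),
                          np.ones(win) / win, mode="valid")
        assert np.all(base.intensity <= ysm + 1e-9)

    def test_subtraction_preserves_peak_centroid(self):
        q = np.linspace(0.0, 0.1, 500)
        peak = 600 * np.exp(-0.5 * ((q - 0.061) / 0.002) ** 2)
        prof = Profile1D(q=q, intensity=peak + 300 * np.exp(-10 * q))
        _, sub = arc_hull_baseline(prof, smoothing=2)
        sel = np.abs(q - 0.061) < 0.006
        c_raw = np.sum(q[sel] * peak[sel]) / np.sum(peak[sel])
        c_sub = np.sum(q[sel] * sub.intensity[sel]) / np.sum(sub.intensity[sel])
        assert abs(c_sub - c_raw) < 0.1 * (q[1] - q[0])

    def test_depth_pushes_baseline_down(self):
        rg = np.random.default_rng(0)
        q = np.linspace(0, 1, 100)
        y = 50 + rg.normal(0, 2, 100)
        prof = Profile1D(q=q, intensity=y)
        b0, _ = arc_hull_baseline(prof, smoothing=0, depth=0.0)
        b2, _ = arc_hull_baseline(prof, smoothing=0, depth=2.0)
        assert np.all(b2.intensity < b0.intensity)


def test_camera_background_subtraction():
    sig = DetectorFrame(pixels=np.full((20, 20), 30.0))
    bg = DetectorFrame(pixels=np.full((20, 20), 12.0))
    out = subtract_background_frame(sig, bg)
    assert np.allclose(out.pixels, 18.0)
    assert out.provenance["camera_background_subtracted"]
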