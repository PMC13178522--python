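"""Peak-fitting tests: constrained equatorials, interference clusters,
widths, band integrals, AL6 deconvolution and centroid spacings."""

import math

import numpy as np
import pytest

from fibrediff.peakfit import (AL6Deconvolution, FitError, PeakComponent,
                               band_intensity, cross_meridional_width,
                               deconvolve_al6, fit_equatorials,
                               fit_interference_cluster,
                               layerline_centroid_spacing)
from fibrediff.profiles import Band, Profile1D

SQRT3 = math.sqrt(3.0)
S2PI = math.sqrt(2 * math.pi)


def gauss(q, c, s, a):
    return a * np.exp(-0.5 * ((q - c) / s) ** 2)


def equatorial_profile(d10, I10, I11, I20, sigma=0.0015, noise=0.0, seed=0):
    q = np.arange(0.015, 0.07, 2e-4)
    y = (gauss(q, 1 / d10, sigma, I10 / (sigma * S2PI))
         + gauss(q, SQRT3 / d10, sigma, I11 / (sigma * S2PI))
         + gauss(q, 2 / d10, sigma, I20 / (sigma * S2PI)))
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, len(q))
    return Profile1D(q=q, intensity=y, baseline_state="subtracted")


class TestEquatorials:
    def test_hexagonal_constraints_hold_exactly(self):
        res = fit_equatorials(equatorial_profile(39.10, 100, 58, 15))
        assert res.d11 * SQRT3 == pytest.approx(res.d10, abs=1e-12)
        assert res.d20 * 2 == pytest.approx(res.d10, abs=1e-12)
        assert res.ratio_I11_I10 == pytest.approx(res.I11 / res.I10, rel=1e-12)

    @pytest.mark.parametrize("d10, ratio", [(39.10, 0.58), (39.70, 1.36)])
    def test_noise_free_recovery(self, d10, ratio):
        """Rest and peak-tetanus lattices recovered to 0.1% spacing and 1%
        intensity ratio on noise-free profiles."""
        res = fit_equatorials(equatorial_profile(d10, 100, 100 * ratio, 20))
        assert res.d10 == pytest.approx(d10, rel=1e-3)
        assert res.ratio_I11_I10 == pytest.approx(ratio, rel=0.01)
        assert res.residual_rms < 1e-6 * res.I10

    def test_rendered_frame_recovery(self, tetanus_truth, rest_frame_reduced):
        """End-to-end on a rendered resting frame: d10 within 0.1%, ratio
        within 3%."""
        from fibrediff.profiles import DEFAULT_ROIS
        from fibrediff.reduction import arc_hull_baseline, integrate
        prof = integrate(rest_frame_reduced, "equatorial",
                         DEFAULT_ROIS["equatorial_halfwidth"])
        _, sub = arc_hull_baseline(prof, smoothing=2)
        res = fit_equatorials(sub)
        assert res.d10 == pytest.approx(tetanus_truth.d10[0], rel=1e-3)
        truth_ratio = tetanus_truth.series("I_1,1/I_1,0")[0]
        assert res.ratio_I11_I10 == pytest.approx(truth_ratio, rel=0.03)

    def test_scaling_profile_scales_areas_not_centres(self):
        prof = equatorial_profile(39.1, 100, 58, 15)
        res1 = fit_equatorials(prof)
        prof7 = Profile1D(q=prof.q, intensity=7 * prof.intensity,
                          baseline_state="subtracted")
        res7 = fit_equatorials(prof7)
        assert res7.I10 == pytest.approx(7 * res1.I10, rel=1e-4)
        assert res7.I11 == pytest.approx(7 * res1.I11, rel=1e-4)
        assert res7.d10 == pytest.approx(res1.d10, abs=1e-6)

    def test_profile_without_10_region_rejected(self):
        prof = equatorial_profile(39.1, 100, 58, 15).window(0.04, 0.065)
        with pytest.raises(FitError, match="1,0 region"):
            fit_equatorials(prof)


def cluster_profile(components, sigma=4e-4, window=(0.058, 0.078)):
    q = np.arange(*window, 2e-4)
    y = np.zeros_like(q)
    for d, area in components:
        y += gauss(q, 1 / d, sigma, area / (sigma * S2PI))
    return Profile1D(q=q, intensity=y, baseline_state="subtracted")


class TestInterferenceCluster:
    def test_m3_triplet_weighted_spacing(self):
        """LA/MA/HA at 14.69/14.46/14.23 nm with rest weights give the
        resting spacing 14.442 nm, recovered within 0.002 nm noise-free."""
        comps = [(14.69, 4.0), (14.46, 93.0), (14.23, 13.0), (15.52, 12.0)]
        truth_s = sum(d * a for d, a in comps[:3]) / sum(a for _, a in comps[:3])
        fit = fit_interference_cluster(cluster_profile(comps), "M3",
                                       include_extras=False)
        assert fit.spacing == pytest.approx(truth_s, abs=0.002)
        assert fit.residual_rms < 1e-3 * max(c.amplitude
                                             for c in fit.components)

    def test_m6_weighted_spacing(self):
        comps = [(7.26, 10.0), (7.23, 56.0), (7.20, 10.0), (7.62, 8.0)]
        truth_s = sum(d * a for d, a in comps[:3]) / sum(a for _, a in comps[:3])
        fit = fit_interference_cluster(
            cluster_profile(comps, window=(0.128, 0.148)), "M6")
        assert fit.spacing == pytest.approx(truth_s, abs=0.001)

    def test_single_component_spacing_is_reciprocal_centre(self):
        fit = fit_interference_cluster(
            cluster_profile([(14.46, 80.0)]), "M3", include_extras=False)
        dominant = max(fit.components, key=lambda c: c.area)
        assert fit.spacing == pytest.approx(1.0 / dominant.centre, rel=1e-6)
        assert fit.spacing == pytest.approx(14.46, abs=0.002)

    def test_sum_rule_exact(self):
        fit = fit_interference_cluster(
            cluster_profile([(14.69, 5.0), (14.46, 90.0), (14.23, 12.0)]),
            "M3", include_extras=False, radial_width=0.004)
        assert fit.total_intensity == pytest.approx(
            sum(c.area for c in fit.components) * 0.004, rel=1e-12)

    def test_weighted_spacing_bounded_by_components(self):
        fit = fit_interference_cluster(
            cluster_profile([(14.69, 30.0), (14.46, 60.0), (14.23, 30.0)]),
            "M3", include_extras=False)
        spacings = [c.spacing for c in fit.components]
        assert min(spacings) <= fit.spacing <= max(spacings)

    def test_labels_ordered_by_descending_spacing(self):
        fit = fit_interference_cluster(
            cluster_profile([(14.69, 40.0), (14.46, 80.0), (14.23, 20.0)]),
            "M3", include_extras=False)
        labs = [c.label for c in fit.components]
        assert labs == ["M3-LA", "M3-MA", "M3-HA"]
        assert fit.components[0].spacing > fit.components[-1].spacing

    def test_scaling_monotone_response(self):
        prof = cluster_profile([(14.69, 5.0), (14.46, 90.0), (14.23, 12.0)])
        f1 = fit_interference_cluster(prof, "M3", include_extras=False)
        prof3 = Profile1D(q=prof.q, intensity=3 * prof.intensity,
                          baseline_state="subtracted")
        f3 = fit_interference_cluster(prof3, "M3", include_extras=False)
        assert f3.total_intensity == pytest.approx(3 * f1.total_intensity,
                                                   rel=1e-3)
        assert f3.spacing == pytest.approx(f1.spacing, abs=1e-4)


class TestCrossMeridionalWidth:
    def _radial(self, s_narrow, s_broad, a_narrow=100.0, a_broad=30.0,
                offset=20.0):
        q = np.arange(-0.06, 0.0601, 2e-4)
        y = (gauss(q, 0, s_narrow, a_narrow) + gauss(q, 0, s_broad, a_broad)
             + offset)
        return Profile1D(q=q, intensity=y)

    def test_narrow_width_of_mixture(self):
        w = cross_meridional_width(self._radial(0.004, 0.020))
        assert w == pytest.approx(0.004, rel=0.05)

    def test_single_gaussian_degenerate_warns(self):
        prof = self._radial(0.004, 0.004, 60.0, 60.0)
        with pytest.warns(UserWarning, match="degenerate"):
            w = cross_meridional_width(prof)
        assert w == pytest.approx(0.004, rel=0.1)

    def test_width_doubling_doubles_corrected_intensity(self):
        """With equal component areas, doubling the cross-meridional width
        doubles the width-corrected total intensity."""
        comps = [(14.46, 90.0)]
        f1 = fit_interference_cluster(cluster_profile(comps), "M3",
                                      include_extras=False, radial_width=0.004)
        f2 = fit_interference_cluster(cluster_profile(comps), "M3",
                                      include_extras=False, radial_width=0.008)
        assert f2.total_intensity == pytest.approx(2 * f1.total_intensity,
                                                   rel=1e-9)


class TestBandIntensity:
    def test_unit_rectangle(self):
        q = np.linspace(0, 1, 1001)
        y = np.where((q >= 0.2) & (q <= 0.5), 1.0, 0.0)
        prof = Profile1D(q=q, intensity=y)
        assert band_intensity(prof, (0.2, 0.5)) == pytest.approx(0.3,
                                                                 abs=2e-3)

    def test_window_outside_support_rejected(self):
        prof = Profile1D(q=np.linspace(0, 1, 10), intensity=np.ones(10))
        with pytest.raises(ValueError, match="outside"):
            band_intensity(prof, (2.0, 3.0))

    def test_halved_band_timecourse(self):
        """A band whose truth amplitude falls to 50% of rest measures a
        0.50 ratio."""
        q = np.linspace(0.01, 0.03, 200)
        rest = Profile1D(q=q, intensity=gauss(q, 0.021, 0.002, 100.0))
        active = Profile1D(q=q, intensity=gauss(q, 0.021, 0.002, 50.0))
        w = (0.017, 0.024)
        ratio = band_intensity(active, w) / band_intensity(rest, w)
        assert ratio == pytest.approx(0.50, abs=0.01)


class TestAL6Deconvolution:
    def _series(self, al6_areas, m7=30.0, m8=30.0):
        q = np.arange(0.150, 0.200, 2e-4)
        profs = []
        for a in al6_areas:
            y = (gauss(q, 1 / 5.90, 1.2e-3, a / (1.2e-3 * S2PI))
                 + gauss(q, 1 / 6.143, 1.5e-3, m7 / (1.5e-3 * S2PI))
                 + gauss(q, 1 / 5.375, 1.5e-3, m8 / (1.5e-3 * S2PI)))
            profs.append(Profile1D(q=q, intensity=y,
                                   baseline_state="subtracted"))
        return profs

    def test_overlapping_212_mixture_recovered(self):
        """AL6:M7:M8 = 2:1:1 overlap: AL6 area recovered within 5%."""
        areas = deconvolve_al6(self._series([60.0, 60.0], m7=30.0, m8=30.0))
        assert np.allclose(areas, 60.0, rtol=0.05)

    def test_pure_al6_equals_band_integral(self):
        profs = self._series([80.0], m7=0.0, m8=0.0)
        dec = deconvolve_al6(profs)[0]
        integral = band_intensity(profs[0], (0.160, 0.180))
        assert dec == pytest.approx(integral, rel=0.02)

    def test_rising_al6_ratio_recovered(self):
        """A 1.59-fold rest→peak AL6 rise is recovered within 10%."""
        areas = deconvolve_al6(self._series([50.0, 79.5]))
        assert areas[1] / areas[0] == pytest.approx(1.59, rel=0.10)

    def test_per_frame_before_global_rejected(self):
        dec = AL6Deconvolution()
        prof = self._series([50.0])[0]
        with pytest.raises(RuntimeError, match="fit_global"):
            dec.amplitudes(prof)


class TestLayerlineCentroid:
    def test_symmetric_peak_at_al1_spacing(self):
        q = np.linspace(0.015, 0.04, 400)
        prof = Profile1D(q=q, intensity=gauss(q, 1 / 37.5, 0.002, 50.0))
        assert layerline_centroid_spacing(prof) == pytest.approx(37.5,
                                                                 abs=0.05)

    def test_single_bin_delta(self):
        q = np.linspace(0.0185, 0.0355, 100)
        y = np.zeros_like(q)
        y[40] = 10.0
        prof = Profile1D(q=q, intensity=y)
        assert layerline_centroid_spacing(prof) == pytest.approx(1 / q[40],
                                                                 rel=1e-12)

    def test_two_equal_peaks_harmonic_mix(self):
        """Equal peaks at 1/43 and 1/37.5 give centroid spacing
        2/(1/43 + 1/37.5) ≈ 40.06 nm."""
        q = np.linspace(0.015, 0.04, 2000)
        y = gauss(q, 1 / 43.0, 5e-4, 50.0) + gauss(q, 1 / 37.5, 5e-4, 50.0)
        prof = Profile1D(q=q, intensity=y)
        expected = 2.0 / (1 / 43.0 + 1 / 37.5)
        assert layerline_centroid_spacing(prof) == pytest.approx(expected,
                                                                 abs=0.05)

    def test_zero_intensity_rejected(self):
        prof = Profile1D(q=np.linspace(0.0185, 0.0355, 50),
                         intensity=np.zeros(50))
        with pytest.raises(ValueError, match="non-positive"):
            layerline_centroid_spacing(prof)


def test_peak_component_invariants():
    with pytest.raises(ValueError):
        PeakComponent("x", 0.07, -1e-4, 10.0)
    with pytest.raises(ValueError):
        PeakComponent("x", 0.07, 1e-3, -5.0)
    c = PeakComponent("x", 0.0692, 4e-4, 10.0)
    assert c.area == pytest.approx(10.0 * 4e-4 * S2PI)
    assert c.spacing == pytest.approx(1 / 0.0692)
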