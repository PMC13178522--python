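"""End-to-end analysis chain: frames → profiles → fits → time courses → kinetics.

Each small-angle frame is centred and de-tilted on the equatorial 1,0 pair,
quadrant-mirrored, integrated into the standard 1D profiles, hull-baseline
subtracted and fitted; the ultra-small-angle frames yield sarcomere length
from the 14th-order (tetanus) or 1st-order (twitch) sarcomere reflection.
Per-frame observables are then assembled into a stimulus-aligned
:class:`~fibrediff.timecourse.TimeCourse`, mass-in-beam corrected,
rest-normalized, and fitted for half-times and relaxation rate constants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinetics as kin
from .frames import DetectorFrame
from .peakfit import (AL6Deconvolution, band_intensity, cross_meridional_width,
                      fit_equatorials, fit_interference_cluster,
                      layerline_centroid_spacing, FitError)
from .profiles import Band, Profile1D, DEFAULT_ROIS
from .reduction import (arc_hull_baseline, find_centre_and_tilt, integrate,
                        mirror)
from .calibration import CalibrationError, fit_sarcomere_order, sl_from_order
from .timecourse import (TimeCourse, amplitude_from_intensity,
                         mass_in_beam_correction, normalize_to_rest,
                         period_averages, smooth_121)

__all__ = ["FrameObservables", "reduce_and_fit_frame", "sl_from_usa_frame",
           "assemble_timecourse", "fit_kinetics_table", "analyse_series",
           "AnalysisResult"]

#: band over which the diffuse background under the first layer line is
#: integrated for the mass-in-beam correction
_BACKGROUND_AXIAL = Band(0.012, 0.050)


@dataclass
class FrameObservables:
    """Per-frame scalar observables extracted from one small-angle frame."""

    frame_time: float
    d10: float = np.nan
    I10: float = np.nan
    I11: float = np.nan
    I20: float = np.nan
    S_M3: float = np.nan
    I_M3: float = np.nan
    S_M6: float = np.nan
    I_M6: float = np.nan
    width_M3: float = np.nan
    width_M6: float = np.nan
    I_ML1: float = np.nan
    I_101: float = np.nan
    I_111_201: float = np.nan
    S_L1: float = np.nan
    background: float = np.nan
    al6_profile: Profile1D | None = None


def reduce_and_fit_frame(frame: DetectorFrame, *, fit_meridionals: bool = True,
                         fit_offaxis: bool = True) -> FrameObservables:
    """Full reduction and fitting of one centred-able small-angle frame."""
    corrected = find_centre_and_tilt(frame)
    mirrored = mirror(corrected, "both")
    obs = FrameObservables(frame_time=frame.frame_time)

    # equator: triple-Gaussian with hexagonal constraints
    eq_raw = integrate(mirrored, "equatorial", DEFAULT_ROIS["equatorial_halfwidth"])
    _, eq_sub = arc_hull_baseline(eq_raw, smoothing=2, depth=0.0)
    eq = fit_equatorials(eq_sub)
    obs.d10, obs.I10, obs.I11, obs.I20 = eq.d10, eq.I10, eq.I11, eq.I20

    # layer-line axial profile: mass-in-beam background + ML1 band
    ll_raw = integrate(mirrored, "axial", DEFAULT_ROIS["layerline_radial"],
                       side="both")
    ll_base, ll_sub = arc_hull_baseline(ll_raw, smoothing=2, depth=0.0)
    obs.background = band_intensity(ll_base, _BACKGROUND_AXIAL)
    obs.I_ML1 = band_intensity(ll_sub, DEFAULT_ROIS["ML1_axial"])
    try:
        obs.S_L1 = layerline_centroid_spacing(ll_sub)
    except ValueError:
        pass

    # AL6 band axial profile, deconvolved globally across the series
    al6_raw = integrate(mirrored, "axial", DEFAULT_ROIS["AL6_radial"],
                        side="both")
    _, obs.al6_profile = arc_hull_baseline(al6_raw, smoothing=2, depth=0.0)

    if fit_meridionals:
        mer_raw = integrate(mirrored, "meridional",
                            DEFAULT_ROIS["meridional_halfwidth"])
        _, mer_sub = arc_hull_baseline(mer_raw, smoothing=2, depth=0.0)
        for family in ("M3", "M6"):
            # the double-Gaussian-plus-offset model absorbs the smooth
            # background, so the radial profile is fitted raw (a hull
            # baseline would swallow the broad component); the radial bands
            # holding the sampled layer-line spots of the same axial window
            # are excised so only meridional-centred intensity is fitted
            rad = integrate(mirrored, "radial", DEFAULT_ROIS[family],
                            signed=True)
            aq = np.abs(rad.q)
            keep = (aq <= 0.060) & ~((aq > 0.019) & (aq < 0.032)) \
                & ~((aq > 0.036) & (aq < 0.052))
            rad_w = Profile1D(q=rad.q[keep], intensity=rad.intensity[keep],
                              variance=rad.variance[keep], roi=rad.roi)
            try:
                width = cross_meridional_width(rad_w)
            except FitError:
                width = np.nan
            try:
                fit = fit_interference_cluster(mer_sub, family,
                                               radial_width=width)
                if family == "M3":
                    obs.S_M3, obs.I_M3, obs.width_M3 = (
                        fit.spacing, fit.total_intensity, width)
                else:
                    obs.S_M6, obs.I_M6, obs.width_M6 = (
                        fit.spacing, fit.total_intensity, width)
            except FitError:
                pass

    if fit_offaxis:
        # radial profile of the first myosin layer line -> off-axis spots
        ml1_rad = integrate(mirrored, "radial", DEFAULT_ROIS["ML1_full_axial"])
        _, ml1_sub = arc_hull_baseline(ml1_rad, smoothing=2, depth=0.0)
        obs.I_101 = band_intensity(ml1_sub, DEFAULT_ROIS["radial_10"])
        obs.I_111_201 = band_intensity(ml1_sub, DEFAULT_ROIS["radial_11_20"])
    return obs


def sl_from_usa_frame(frame: DetectorFrame, order: int = 14,
                      window: Band | None = None,
                      halfwidth: float = 0.00304) -> float:
    """Sarcomere length (µm) from an ultra-small-angle frame.

    Integrates ±``halfwidth`` nm^-1 about the meridian, removes the residual
    background with a plain hull (no smoothing, depth 0), and fits a single
    Gaussian to the chosen sarcomere order; SL follows from the Bragg
    relation.  Raises :class:`CalibrationError` when the order is absent.
    """
    if window is None:
        window = (DEFAULT_ROIS["sarcomere_14th"] if order >= 2
                  else DEFAULT_ROIS["sarcomere_1st"])
    prof = integrate(frame, "meridional", Band(0.0, halfwidth))
    _, sub = arc_hull_baseline(prof, smoothing=0, depth=0.0)
    # q to µm^-1
    sub_um = Profile1D(q=sub.q * 1000.0, intensity=sub.intensity,
                       variance=sub.variance, roi=sub.roi,
                       baseline_state=sub.baseline_state)
    q_n = fit_sarcomere_order(sub_um, window, order)
    return sl_from_order(q_n, order)


def assemble_timecourse(observables: list[FrameObservables], force,
                        stimulus_times, sl=None,
                        al6_mode: str = "global") -> TimeCourse:
    """Build the corrected, rest-normalized TimeCourse from per-frame fits."""
    times = np.array([o.frame_time for o in observables])
    series = {
        "force": np.asarray(force, dtype=float),
        "d10": np.array([o.d10 for o in observables]),
        "I_1,0": np.array([o.I10 for o in observables]),
        "I_1,1": np.array([o.I11 for o in observables]),
        "I_1,1/I_1,0": np.array([o.I11 / o.I10 for o in observables]),
        "S_M3": np.array([o.S_M3 for o in observables]),
        "I_M3": np.array([o.I_M3 for o in observables]),
        "S_M6": np.array([o.S_M6 for o in observables]),
        "I_M6": np.array([o.I_M6 for o in observables]),
        "I_ML1": np.array([o.I_ML1 for o in observables]),
        "I_1,0,1": np.array([o.I_101 for o in observables]),
        "I_1,1,1+2,0,1": np.array([o.I_111_201 for o in observables]),
    }
    if sl is not None:
        series["SL"] = np.asarray(sl, dtype=float)
    al6_profiles = [o.al6_profile for o in observables]
    if all(p is not None for p in al6_profiles):
        from .peakfit import deconvolve_al6
        try:
            series["I_AL6"] = smooth_121(deconvolve_al6(al6_profiles,
                                                        mode=al6_mode))
        except (FitError, ValueError) as exc:
            warnings.warn(f"AL6 deconvolution skipped: {exc}")

    tc = TimeCourse(frame_times=times, series=series,
                    stimulus_times=tuple(stimulus_times))
    bg = np.array([o.background for o in observables])
    if np.all(np.isfinite(bg)) and np.all(bg > 0):
        tc = mass_in_beam_correction(tc, bg)
    tc = normalize_to_rest(tc)
    # amplitude observables from normalized intensities
    for src, dst in (("I_M3", "A_M3"), ("I_ML1", "A_ML1")):
        if src in tc.series and np.all(np.isfinite(tc.series[src])):
            tc.series[dst] = amplitude_from_intensity(
                np.clip(tc.series[src], 0.0, None))
    return tc


#: observables fitted with a double sigmoid during tetanus activation
_BIPHASIC = ("I_M3", "A_M3", "S_M3")


def fit_kinetics_table(tc: TimeCourse, protocol: str = "tetanus"
                       ) -> pd.DataFrame:
    """Half-times and rate constants for every series, mirroring the
    conventions of the kinetics analysis (activation t½ re first stimulus,
    tetanus relaxation re last stimulus, twitch relaxation re 52.25 ms)."""
    win = kin.TETANUS_WINDOWS if protocol == "tetanus" else kin.TWITCH_WINDOWS
    rest = tc.rest_frames()
    rows = []
    for name, y in tc.series.items():
        if not np.all(np.isfinite(y)):
            continue
        row = {"observable": name}
        try:
            if protocol == "tetanus" and name in _BIPHASIC:
                res = kin.fit_double_sigmoid(tc.frame_times, y,
                                             win["activation"],
                                             win["activation_ref"])
                row["t_half_fast_ms"] = res.t_half_fast
                row["t_half_slow_ms"] = res.t_half_slow
                if res.t_half is not None:
                    row["t_half_activation_ms"] = res.t_half
            else:
                res = kin.fit_sigmoid(tc.frame_times, y, win["activation"],
                                      win["activation_ref"])
                row["t_half_activation_ms"] = res.t_half
        except (RuntimeError, ValueError) as exc:
            row["activation_error"] = str(exc)
        try:
            res = kin.fit_sigmoid(tc.frame_times, y, win["relaxation"],
                                  win["relaxation_ref"])
            row["t_half_relaxation_ms"] = res.t_half
        except (RuntimeError, ValueError) as exc:
            row["relaxation_error"] = str(exc)
        if protocol == "tetanus":
            rest_value = float(y[rest].mean())
            try:
                row["slow_K_REL_s"] = kin.slow_krel(tc.frame_times, y,
                                                    rest_value)
                row["fast_K_REL_s"] = kin.fast_krel(tc.frame_times, y,
                                                    rest_value)
            except (RuntimeError, ValueError) as exc:
                row["krel_error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AnalysisResult:
    timecourse: TimeCourse
    kinetics: pd.DataFrame
    periods: list
    provenance: dict = field(default_factory=dict)


def analyse_series(sa_frames, force, stimulus_times, usa_frames=None,
                   protocol: str = "tetanus", sl_order: int | None = None,
                   fit_meridionals: bool = True, fit_offaxis: bool = True
                   ) -> AnalysisResult:
    """Run the whole chain on a list of frames plus the force trace.

    ``sa_frames`` / ``usa_frames`` may be lists or generators of
    :class:`DetectorFrame` (generators keep memory flat for long series).
    """
    observables = [reduce_and_fit_frame(f, fit_meridionals=fit_meridionals,
                                        fit_offaxis=fit_offaxis)
                   for f in sa_frames]
    sl = None
    if usa_frames is not None:
        if sl_order is None:
            sl_order = 14 if protocol == "tetanus" else 1
        sl = []
        for f in usa_frames:
            try:
                sl.append(sl_from_usa_frame(f, order=sl_order))
            except (CalibrationError, ValueError):
                sl.append(np.nan)
        sl = np.asarray(sl)
    tc = assemble_timecourse(observables, force, stimulus_times, sl=sl)
    table = fit_kinetics_table(tc, protocol)
    periods = period_averages(tc)
    return AnalysisResult(timecourse=tc, kinetics=table, periods=periods,
                          provenance={"protocol": protocol,
                                      "n_frames": len(observables)})
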