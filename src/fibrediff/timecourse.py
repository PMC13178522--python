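"""Assembly of per-frame observables into stimulus-aligned time courses.

Applies, in the order used for the reported series: the mass-in-beam
correction (frame-wise division of intensities by the relative diffuse
background under the first layer line), rest-normalization of intensities,
1:2:1 smoothing where requested, record-level quality control, and
period averaging (rest / early / peak force / isometric relaxation /
mechanically relaxed, 3–4 frames each).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TimeCourse", "PeriodSummary", "mass_in_beam_correction",
           "normalize_to_rest", "smooth_121", "qc_exclude", "period_averages",
           "amplitude_from_intensity", "default_periods"]

#: series treated as intensities (corrected and rest-normalized); spacings
#: and lengths stay in absolute units.
INTENSITY_PREFIXES = ("I_", "A_")


def is_intensity(name: str) -> bool:
    # intensity ratios (e.g. "I_1,1/I_1,0") are dimensionless: the mass
    # correction cancels and they are reported absolute, not rest-normalized
    return name.startswith(INTENSITY_PREFIXES) and "/" not in name


@dataclass
class TimeCourse:
    """Named per-frame series aligned to the stimulus train."""

    frame_times: np.ndarray                 # ms, centre of integration window
    series: dict = field(default_factory=dict)
    stimulus_times: tuple = ()
    correction_factors: np.ndarray | None = None
    normalization_reference: np.ndarray | None = None  # rest frame indices
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        for name, s in list(self.series.items()):
            s = np.asarray(s, dtype=float)
            if s.shape != self.frame_times.shape:
                raise ValueError(f"series {name!r} length mismatch")
            self.series[name] = s
        if self.correction_factors is not None:
            if np.any(np.asarray(self.correction_factors) <= 0):
                raise ValueError("correction factors must be positive")

    def rest_frames(self) -> np.ndarray:
        if self.normalization_reference is not None:
            return np.asarray(self.normalization_reference)
        first = min(self.stimulus_times) if self.stimulus_times else np.inf
        idx = np.flatnonzero(self.frame_times < first)
        if len(idx) == 0:
            raise ValueError("no pre-stimulus rest frames")
        return idx

    def copy(self) -> "TimeCourse":
        return TimeCourse(frame_times=self.frame_times.copy(),
                          series={k: v.copy() for k, v in self.series.items()},
                          stimulus_times=tuple(self.stimulus_times),
                          correction_factors=None if self.correction_factors is None
                          else np.asarray(self.correction_factors).copy(),
                          normalization_reference=self.normalization_reference,
                          provenance=dict(self.provenance))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_ms": self.frame_times, **self.series})
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def mass_in_beam_correction(tc: TimeCourse, background_series,
                            threshold: float = 0.01) -> TimeCourse:
    """Divide intensity series by the relative diffuse-background change.

    ``background_series`` is the per-frame background integral under the
    first layer line band; each intensity series is divided frame-wise by
    background/background(rest).  Spacings are untouched.  When the maximum
    relative deviation is below ``threshold`` (1%) no correction is applied
    — the twitch case — and provenance records the skip.
    """
    bg = np.asarray(background_series, dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background series must be positive")
    out = tc.copy()
    rest = tc.rest_frames()
    rel = bg / bg[rest].mean()
    max_dev = float(np.max(np.abs(rel - 1.0)))
    if max_dev < threshold:
        out.provenance["mass_in_beam"] = {
            "applied": False, "max_deviation": max_dev,
            "reason": f"max background change {100 * max_dev:.2f}% < "
                      f"{100 * threshold:.0f}% threshold"}
        out.correction_factors = np.ones_like(rel)
        return out
    for name in out.series:
        if is_intensity(name):
            out.series[name] = out.series[name] / rel
    out.correction_factors = rel
    out.provenance["mass_in_beam"] = {"applied": True, "max_deviation": max_dev}
    return out


def normalize_to_rest(tc: TimeCourse) -> TimeCourse:
    """Divide each intensity series by its mean over the pre-stimulus frames."""
    out = tc.copy()
    rest = tc.rest_frames()
    if len(rest) < 2:
        raise ValueError("need at least 2 pre-stimulus frames")
    for name in out.series:
        if not is_intensity(name):
            continue
        ref = out.series[name][rest].mean()
        if ref == 0:
            raise ValueError(f"zero rest mean for series {name!r}")
        out.series[name] = out.series[name] / ref
    out.normalization_reference = rest
    out.provenance["normalized_to_rest"] = {"frames": rest.tolist()}
    return out


def smooth_121(series) -> np.ndarray:
    """Weighted moving average with kernel (1,2,1)/4; truncated at the ends."""
    s = np.asarray(series, dtype=float)
    if len(s) < 3:
        raise ValueError("need at least 3 points")
    out = np.empty_like(s)
    out[1:-1] = (s[:-2] + 2 * s[1:-1] + s[2:]) / 4.0
    out[0] = (2 * s[0] + s[1]) / 3.0
    out[-1] = (s[-2] + 2 * s[-1]) / 3.0
    return out


def qc_exclude(records: list[dict], force_decline_limit: float = 0.15
               ) -> list[dict]:
    """Flag records failing the exclusion rules; return the retained subset.

    Each record dict carries ``force_peaks`` (per-contraction peak forces)
    and optional boolean quality metrics ``collagen_reflections`` and
    ``pattern_deteriorated``.  A record is excluded when force declined by
    more than 15% from the first contraction, when collagen-based
    reflections indicate tendon in the beam, or when the pattern quality
    deteriorated.  Exclusion reasons are written into each record's
    ``qc_flags``; excluding every record is a hard failure.
    """
    retained = []
    for rec in records:
        flags = []
        peaks = np.asarray(rec.get("force_peaks", [1.0]), dtype=float)
        if len(peaks) and peaks[0] > 0:
            decline = 1.0 - peaks.min() / peaks[0]
            if decline > force_decline_limit:
                flags.append(f"force declined {100 * decline:.0f}% "
                             f"(> {100 * force_decline_limit:.0f}%)")
        if rec.get("collagen_reflections"):
            flags.append("collagen reflections (tendon in beam)")
        if rec.get("pattern_deteriorated"):
            flags.append("diffraction pattern deteriorated")
        rec["qc_flags"] = flags
        if not flags:
            retained.append(rec)
    if not retained:
        raise RuntimeError("all records excluded by quality control")
    return retained


@dataclass
class PeriodSummary:
    label: str
    frames: np.ndarray
    means: dict
    sds: dict

    def to_row(self) -> dict:
        row = {"period": self.label, "n_frames": len(self.frames)}
        for k in self.means:
            row[k] = self.means[k]
            row[f"{k}_sd"] = self.sds[k]
        return row


def default_periods(tc: TimeCourse, n_frames: int = 3) -> dict:
    """Period frame windows from force-trace landmarks.

    rest: last pre-stimulus frames; peak force: frames around maximal force;
    isometric relaxation: first post-stimulus frames before the exponential
    phase; mechanically relaxed: first frames after force returns below 5% of
    peak.  Each window holds ``n_frames`` (3–4) frames.
    """
    force = tc.series["force"]
    t = tc.frame_times
    rest = tc.rest_frames()[-n_frames:]
    i_peak = int(np.argmax(force))
    lo = max(i_peak - n_frames // 2, 0)
    peak = np.arange(lo, min(lo + n_frames, len(t)))
    periods = {"rest": rest, "peak force": peak}
    last_stim = max(tc.stimulus_times) if tc.stimulus_times else 0.0
    post = np.flatnonzero(t > last_stim)
    if len(post):
        iso = post[:n_frames]
        if len(iso) == n_frames:
            periods["isometric relaxation"] = iso
    peak_force = force[i_peak]
    relaxed = np.flatnonzero((t > last_stim) & (force < 0.05 * peak_force))
    if len(relaxed) >= n_frames:
        periods["mechanically relaxed"] = relaxed[:n_frames]
    return periods


def period_averages(tc: TimeCourse, period_definitions: dict | None = None
                    ) -> list[PeriodSummary]:
    """Per-period mean ± SD for every series over 3–4 frames per period."""
    if period_definitions is None:
        period_definitions = default_periods(tc)
    out = []
    for label, frames in period_definitions.items():
        frames = np.asarray(frames, dtype=int)
        if len(frames) == 0:
            raise ValueError(f"period {label!r} window is empty")
        if not 3 <= len(frames) <= 4:
            warnings.warn(f"period {label!r} averages {len(frames)} frames "
                          "(3-4 expected)")
        means = {k: float(v[frames].mean()) for k, v in tc.series.items()}
        sds = {k: float(v[frames].std(ddof=1)) if len(frames) > 1 else 0.0
               for k, v in tc.series.items()}
        out.append(PeriodSummary(label=label, frames=frames, means=means,
                                 sds=sds))
    return out


def amplitude_from_intensity(I_rel) -> np.ndarray | float:
    """Diffraction amplitude from relative intensity: A = √I.

    Reflection intensity scales with the square of the number of coherently
    contributing diffractors, so √I tracks the number fraction.
    """
    arr = np.asarray(I_rel, dtype=float)
    if np.any(arr < 0):
        raise ValueError("relative intensity must be non-negative")
    out = np.sqrt(arr)
    return float(out) if np.isscalar(I_rel) or arr.ndim == 0 else out
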