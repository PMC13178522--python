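"""1D intensity profiles and the standard integration bands.

A :class:`Profile1D` is a background-inclusive or background-subtracted
intensity distribution versus reciprocal spacing q = 1/d (nm^-1), produced by
integrating a detector frame over a transverse band.  The named bands in
:data:`DEFAULT_ROIS` are the integration limits used throughout the analysis:
meridional and equatorial half-widths, the M3/M6 axial windows, the layer-line
radial bands and the sarcomere windows (the last two in µm^-1 on the same
q = 1/d convention).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Profile1D", "Band", "ROISet", "DEFAULT_ROIS"]


@dataclass
class Profile1D:
    """Integrated 1D intensity versus reciprocal spacing.

    ``q`` must be strictly increasing; ``variance`` carries propagated
    Poisson counting variance (may be zero for synthetic noise-free data).
    ``roi`` records how the profile was obtained (axis, band limits,
    mirroring mode); ``baseline_state`` is ``"raw"`` or ``"subtracted"``.
    """

    q: np.ndarray
    intensity: np.ndarray
    variance: np.ndarray | None = None
    roi: dict = field(default_factory=dict)
    baseline_state: str = "raw"

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.variance is None:
            self.variance = np.zeros_like(self.intensity)
        self.variance = np.asarray(self.variance, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be 1D arrays of equal length")
        if len(self.q) > 1 and not np.all(np.diff(self.q) > 0):
            raise ValueError("q must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")

    def window(self, lo: float, hi: float) -> "Profile1D":
        """Sub-profile restricted to lo <= q <= hi."""
        sel = (self.q >= lo) & (self.q <= hi)
        if not np.any(sel):
            raise ValueError(f"window [{lo}, {hi}] outside profile support")
        return replace(self, q=self.q[sel], intensity=self.intensity[sel],
                       variance=self.variance[sel])

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["q", "intensity", "variance"])
            for row in zip(self.q, self.intensity, self.variance):
                w.writerow([f"{v:.10g}" for v in row])
        with open(str(path) + ".json", "w") as fh:
            json.dump({"roi": self.roi, "baseline_state": self.baseline_state},
                      fh, indent=1)

    @classmethod
    def from_csv(cls, path) -> "Profile1D":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        try:
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = {"roi": {}, "baseline_state": "raw"}
        return cls(q=data[:, 0], intensity=data[:, 1], variance=data[:, 2],
                   roi=meta["roi"], baseline_state=meta["baseline_state"])


@dataclass(frozen=True)
class Band:
    """A named integration band [lo, hi] in reciprocal units."""

    lo: float
    hi: float
    units: str = "nm^-1"

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError("band lower limit must be below upper limit")

    @property
    def width(self) -> float:
        return self.hi - self.lo


class ROISet(dict):
    """Named bands; values are :class:`Band`.  Keys follow the observables."""


#: Standard integration limits (nm^-1 unless noted).
DEFAULT_ROIS = ROISet(
    # transverse half-widths for the axial/radial 1D integrations
    meridional_halfwidth=Band(0.0, 0.0038),
    equatorial_halfwidth=Band(0.0, 0.0036),
    # axial windows of the meridional reflection families
    M3=Band(0.066, 0.072),
    M6=Band(0.135, 0.142),
    M3_extras=Band(0.062, 0.067),
    # layer-line radial band used for ML1/AL1 axial profiles and the
    # mass-in-beam background series
    layerline_radial=Band(0.037, 0.064),
    # ML1 axial window excluding the overlapped AL1
    ML1_axial=Band(0.017, 0.024),
    # axial windows of the first three myosin layer lines
    ML1_full_axial=Band(0.016, 0.034),
    ML2_axial=Band(0.041, 0.049),
    ML3_axial=Band(0.066, 0.072),
    # radial windows of the equatorial columns for off-axis intensities
    radial_10=Band(0.020, 0.035),
    radial_11_20=Band(0.037, 0.061),
    # AL6 bands
    AL6_radial=Band(0.035, 0.060),
    AL6_axial=Band(0.166, 0.178),
    AL6_axial_narrow=Band(0.166, 0.170),
    # mixed first layer line centroid window
    L1_centroid=Band(0.0185, 0.0355),
    # equatorial triple-Gaussian fit window
    equatorial_fit=Band(0.02, 0.065),
    # sarcomere reflection windows (µm^-1)
    sarcomere_14th=Band(5.0, 7.0, units="um^-1"),
    sarcomere_1st=Band(0.25, 0.57, units="um^-1"),
)
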