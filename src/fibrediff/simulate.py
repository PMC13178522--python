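"""Forward simulation of fibre-diffraction time series.

The generator has two halves:

* :func:`simulate_timecourse_truth` builds per-frame ground-truth structural
  parameters (force, sarcomere length, lattice spacing, and position /
  amplitude / width of every reflection) from closed-form kinetic
  trajectories — logistic activation, optionally biphasic (sum of two
  logistics of opposite sign), followed by a linear-then-exponential
  relaxation envelope, mimicking a fixed-end twitch or tetanus.
* :func:`render_frame` turns one frame of that truth into a noisy 2D detector
  image: a smooth, isotropically decaying diffuse background plus separable
  2D Gaussians at the four-quadrant-symmetric reflection positions, rotated
  by the detector tilt, masked by the tile gaps and Poisson sampled.

Default parameter values are the resting/active levels and half-times of a
rat soleus fixed-end tetanus (64 × 10 ms frames) or twitch (70 × 5 ms):
peak force 110 kPa, d(1,0) 39.10 → 39.70 nm, sarcomere length 2.43 → 2.15 µm,
S(M3) 14.442 nm at rest with interference sub-peaks at ~14.69/14.46/14.23 nm,
S(M6) 7.230 nm, and the observed intensity changes of the equatorial,
layer-line and meridional reflections.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .frames import DetectorFrame
from .profiles import Profile1D

__all__ = [
    "Relaxation", "Trajectory", "ReflectionSpec", "CameraConfig",
    "BackgroundConfig", "SimulationConfig", "SimulationTruth",
    "simulate_timecourse_truth", "render_frame", "generate_grating_profile",
    "tetanus_config", "twitch_config",
]

SQRT3 = math.sqrt(3.0)
TWO_PI = 2.0 * math.pi


def _logistic(t, t_half, tau):
    return 1.0 / (1.0 + np.exp(-(np.asarray(t, dtype=float) - t_half) / tau))


@dataclass(frozen=True)
class Relaxation:
    """Envelope applied to the deviation from rest after stimulation ends.

    ``linear_exp``: unity until ``start_ms``, then a linear decline at
    ``slow_rate`` (s^-1, normalized to the deviation at ``start_ms``) until
    ``lin_end_ms``, then exponential decay at ``fast_rate`` (s^-1) — the
    isometric-then-exponential relaxation of a tetanus.  ``sigmoid``: a
    falling logistic centred at ``t_half_ms`` (used for the twitch).
    """

    kind: str = "none"            # none | linear_exp | sigmoid
    start_ms: float = 244.0
    lin_end_ms: float = 344.0
    slow_rate: float = 1.7
    fast_rate: float = 23.0
    t_half_ms: float = 80.0
    tau_ms: float = 12.0

    def envelope(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "none":
            return np.ones_like(t)
        if self.kind == "sigmoid":
            return 1.0 - _logistic(t, self.t_half_ms, self.tau_ms)
        if self.kind != "linear_exp":
            raise ValueError(f"unknown relaxation kind {self.kind!r}")
        env = np.ones_like(t)
        lin = (t > self.start_ms) & (t <= self.lin_end_ms)
        env[lin] = 1.0 - self.slow_rate / 1000.0 * (t[lin] - self.start_ms)
        at_end = 1.0 - self.slow_rate / 1000.0 * (self.lin_end_ms - self.start_ms)
        late = t > self.lin_end_ms
        env[late] = at_end * np.exp(-self.fast_rate / 1000.0 * (t[late] - self.lin_end_ms))
        return np.clip(env, 0.0, None)


@dataclass(frozen=True)
class Trajectory:
    """Closed-form time course: rest + sum of logistic phases × relaxation.

    ``phases`` is a tuple of ``(amplitude, t_half_ms, tau_ms)``; a biphasic
    course uses two phases of opposite sign (fast drop then slow rise, or
    vice versa).  The relaxation envelope multiplies the total deviation
    from rest, so every series returns towards its resting level.
    """

    rest: float
    phases: tuple[tuple[float, float, float], ...] = ()
    relax: Relaxation = Relaxation()

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        dev = np.zeros_like(t)
        for amp, t_half, tau in self.phases:
            dev += amp * _logistic(t, t_half, tau)
        return self.rest + dev * self.relax.envelope(t)

    # -- constructors -------------------------------------------------------
    @classmethod
    def constant(cls, value: float) -> "Trajectory":
        return cls(rest=value)

    @classmethod
    def sigmoid(cls, rest: float, active: float, t_half: float, tau: float,
                relax: Relaxation = Relaxation()) -> "Trajectory":
        return cls(rest=rest, phases=((active - rest, t_half, tau),), relax=relax)

    @classmethod
    def biphasic(cls, rest: float, transient: float, active: float,
                 t_half_fast: float, tau_fast: float,
                 t_half_slow: float, tau_slow: float,
                 relax: Relaxation = Relaxation()) -> "Trajectory":
        """Fast phase rest→transient, slow phase transient→active."""
        return cls(rest=rest,
                   phases=((transient - rest, t_half_fast, tau_fast),
                           (active - transient, t_half_slow, tau_slow)),
                   relax=relax)

    def scaled(self, factor: float) -> "Trajectory":
        return replace(self, rest=self.rest * factor,
                       phases=tuple((a * factor, th, tau) for a, th, tau in self.phases))


@dataclass(frozen=True)
class ReflectionSpec:
    """One reflection (or sub-peak) of the simulated pattern.

    Radial position: either fixed ``q_radial`` (nm^-1) or ``radial_mult``
    giving q_r = mult / d10(t) for reflections tied to the hexagonal lattice
    (mult = 1, √3, 2 for the 1,0 / 1,1 / 2,0 columns).  Axial position: rest
    spacing ``d_axial`` (nm, None for equatorials) optionally multiplied by
    the shared spacing-scale trajectory named by ``axial_scale_key`` ("M3",
    "M6" or "SL").  ``family`` groups sub-peaks into a reported reflection.
    """

    label: str
    amplitude: Trajectory
    sigma_ax: float = 0.0015
    sigma_rad: float = 0.004
    d_axial: float | None = None
    axial_scale_key: str | None = None
    q_radial: float = 0.0
    radial_mult: float | None = None
    bank: str = "sa"
    family: str = ""


@dataclass(frozen=True)
class CameraConfig:
    shape: tuple[int, int] = (1901, 761)
    reciprocal_scale: tuple[float, float] = (2e-4, 2e-4)
    beam_centre: tuple[float, float] = (950.0, 380.0)
    tilt: float = 0.0
    pixel_size: float = 75.0
    camera_length: float = 8.26
    exposure: float = 8.0
    # masked tile gaps: list of (axis, start_px, width_px); axis 0 masks rows
    tile_gaps: tuple[tuple[int, int, int], ...] = ()

    def tile_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        for axis, start, width in self.tile_gaps:
            if axis == 0:
                mask[start:start + width, :] = True
            else:
                mask[:, start:start + width] = True
        return mask


@dataclass(frozen=True)
class BackgroundConfig:
    """Diffuse scatter: double exponential in |q| with one anisotropy factor.

    b(q) = b1·exp(−|q|/l1) + b2·exp(−|q|/l2) + floor with
    |q| = hypot(q_r, anisotropy·q_z).  The real diffuse scatter of muscle is
    unspecified; this is a simulator choice (smooth and peak-free, so the
    hull baseline can remove it).
    """

    b1: float = 600.0
    l1: float = 0.010
    b2: float = 150.0
    l2: float = 0.060
    floor: float = 20.0
    anisotropy: float = 1.3

    def evaluate(self, q_r: np.ndarray, q_z: np.ndarray) -> np.ndarray:
        q = np.hypot(q_r, self.anisotropy * q_z)
        return (self.b1 * np.exp(-q / self.l1)
                + self.b2 * np.exp(-q / self.l2) + self.floor)


@dataclass
class SimulationConfig:
    protocol: str = "tetanus"
    n_frames: int = 64
    frame_pitch_ms: float = 10.0
    first_frame_ms: float = -26.0
    stimulus_times: tuple[float, ...] = ()
    seed: int = 0
    force: Trajectory = field(default_factory=lambda: Trajectory.constant(0.65))
    sl: Trajectory = field(default_factory=lambda: Trajectory.constant(2430.0))
    d10: Trajectory = field(default_factory=lambda: Trajectory.constant(39.10))
    background_scale: Trajectory = field(default_factory=lambda: Trajectory.constant(1.0))
    spacing_scales: dict = field(default_factory=dict)  # name -> Trajectory
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    reflections: tuple[ReflectionSpec, ...] = ()
    cameras: dict = field(default_factory=dict)         # bank -> CameraConfig

    def frame_times(self) -> np.ndarray:
        if self.frame_pitch_ms <= 0:
            raise ValueError("frame spacing must be positive")
        return self.first_frame_ms + self.frame_pitch_ms * np.arange(self.n_frames)


@dataclass
class SimulationTruth:
    """Per-frame ground truth used by the renderer and recovered by tests."""

    frame_times: np.ndarray
    stimulus_times: tuple[float, ...]
    force: np.ndarray
    d10: np.ndarray
    sl: np.ndarray
    background_scale: np.ndarray
    reflection_params: dict          # label -> dict of per-frame arrays
    seed: int
    config: SimulationConfig

    def __post_init__(self):
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if np.any(self.force < 0):
            raise ValueError("force must be non-negative")
        if np.any(self.d10 <= 0) or np.any(self.sl <= 0):
            raise ValueError("d10 and SL must be positive")
        if np.any(self.background_scale <= 0):
            raise ValueError("background_scale must be positive")
        for label, p in self.reflection_params.items():
            if p["sigma_ax"] <= 0 or p["sigma_rad"] <= 0:
                raise ValueError(f"widths of {label} must be positive")
            if np.any(p["amplitude"] < 0):
                raise ValueError(f"amplitude of {label} must be non-negative")

    # -- derived truth series ----------------------------------------------
    def area(self, label: str) -> np.ndarray:
        """Integrated counts of one reflection spot (q-space integral)."""
        p = self.reflection_params[label]
        return p["amplitude"] * TWO_PI * p["sigma_ax"] * p["sigma_rad"]

    def family_labels(self, family: str) -> list[str]:
        return [lab for lab, p in self.reflection_params.items()
                if p["family"] == family]

    def meridional_family(self, family: str, halfwidth: float = 0.0038):
        """Truth total intensity and weighted spacing of a sub-peak family.

        Weights are spot areas times the fraction of each spot's radial
        profile captured by the meridional integration band (the capture
        fraction matters only if sub-peaks have different radial widths).
        """
        from scipy.special import erf
        labels = self.family_labels(family)
        if not labels:
            raise KeyError(f"no reflections in family {family!r}")
        total = np.zeros_like(self.frame_times, dtype=float)
        weighted = np.zeros_like(total)
        for lab in labels:
            p = self.reflection_params[lab]
            capture = erf(halfwidth / (math.sqrt(2) * p["sigma_rad"]))
            w = self.area(lab) * capture
            total += w
            weighted += w / p["q_axial"]
        return total, weighted / total

    def series(self, name: str) -> np.ndarray:
        """Named truth series matching the reported observables."""
        if name == "force":
            return self.force
        if name == "SL":
            return self.sl
        if name == "d10":
            return self.d10
        if name == "background_scale":
            return self.background_scale
        if name in ("I_M3", "S_M3", "I_M6", "S_M6"):
            fam = name[-2:]
            total, spacing = self.meridional_family(fam)
            return total if name.startswith("I") else spacing
        if name == "I_1,0":
            return self.area("1,0")
        if name == "I_1,1":
            return self.area("1,1")
        if name == "I_1,1/I_1,0":
            return self.area("1,1") / self.area("1,0")
        if name == "I_ML1":
            return self.area("1,1,1") + self.area("2,0,1")
        if name == "I_1,0,1":
            return self.area("1,0,1")
        if name == "I_1,1,1+2,0,1":
            return self.area("1,1,1") + self.area("2,0,1")
        if name == "I_AL6":
            return self.area("AL6")
        if name == "I_AL1":
            return self.area("AL1-out")
        raise KeyError(f"unknown truth series {name!r}")

    def rest_frames(self) -> np.ndarray:
        """Indices of frames entirely before the first stimulus."""
        first = min(self.stimulus_times) if self.stimulus_times else np.inf
        return np.flatnonzero(self.frame_times < first)

    def to_json(self, path) -> None:
        out = {
            "frame_times": self.frame_times.tolist(),
            "stimulus_times": list(self.stimulus_times),
            "force": self.force.tolist(),
            "d10": self.d10.tolist(),
            "sl": self.sl.tolist(),
            "background_scale": self.background_scale.tolist(),
            "seed": self.seed,
            "reflections": {
                lab: {"bank": p["bank"], "family": p["family"],
                      "sigma_ax": p["sigma_ax"], "sigma_rad": p["sigma_rad"],
                      "q_axial": p["q_axial"].tolist(),
                      "q_radial": p["q_radial"].tolist(),
                      "amplitude": p["amplitude"].tolist()}
                for lab, p in self.reflection_params.items()},
        }
        with open(path, "w") as fh:
            json.dump(out, fh)


def simulate_timecourse_truth(config: SimulationConfig) -> SimulationTruth:
    """Evaluate every configured trajectory on the frame-time grid."""
    t = config.frame_times()
    d10 = config.d10(t)
    sl = config.sl(t)
    scales = {k: traj(t) for k, traj in config.spacing_scales.items()}
    scales["SL"] = sl / config.sl.rest

    params = {}
    for spec in config.reflections:
        if spec.radial_mult is not None:
            q_r = spec.radial_mult / d10
        else:
            q_r = np.full_like(t, spec.q_radial)
        if spec.d_axial is None:
            q_z = np.zeros_like(t)
        else:
            d = spec.d_axial * (scales[spec.axial_scale_key]
                                if spec.axial_scale_key else np.ones_like(t))
            q_z = 1.0 / d
        params[spec.label] = {
            "bank": spec.bank, "family": spec.family,
            "q_radial": np.asarray(q_r, dtype=float),
            "q_axial": np.asarray(q_z, dtype=float),
            "amplitude": spec.amplitude(t),
            "sigma_ax": spec.sigma_ax, "sigma_rad": spec.sigma_rad,
        }

    return SimulationTruth(
        frame_times=t, stimulus_times=tuple(config.stimulus_times),
        force=config.force(t), d10=d10, sl=sl,
        background_scale=config.background_scale(t),
        reflection_params=params, seed=config.seed, config=config)


def render_frame(truth: SimulationTruth, frame_index: int,
                 geometry: CameraConfig | None = None, bank: str = "sa",
                 noise: bool = True) -> DetectorFrame:
    """Render one noisy detector frame from the ground truth.

    Expected counts are the diffuse background (scaled by the per-frame
    mass-in-beam factor) plus every reflection of ``bank`` placed as a
    separable 2D Gaussian at (±q_r, ±q_z), four-quadrant symmetric before the
    detector tilt rotates the pattern.  Tile-gap pixels are zeroed and the
    observed counts are Poisson draws from a per-frame substream of the
    master seed, so rendering is bit-reproducible.
    """
    if not 0 <= frame_index < len(truth.frame_times):
        raise IndexError("frame_index out of range")
    geom = geometry or truth.config.cameras[bank]
    nz, nr = geom.shape
    iz = np.arange(nz, dtype=float)[:, None] - geom.beam_centre[0]
    ir = np.arange(nr, dtype=float)[None, :] - geom.beam_centre[1]
    sz, sr = geom.reciprocal_scale
    # fibre coordinates: rotate detector coordinates back by the tilt
    th = math.radians(geom.tilt)
    cos_t, sin_t = math.cos(th), math.sin(th)
    # q in detector axes
    qz_det = iz * sz
    qr_det = ir * sr

    # background is isotropic up to the anisotropy factor, evaluated in fibre
    # coordinates (rotation matters only through the anisotropy)
    qr_f = cos_t * qr_det + sin_t * qz_det
    qz_f = -sin_t * qr_det + cos_t * qz_det
    expected = truth.background_scale[frame_index] * \
        truth.config.background.evaluate(qr_f, qz_f)

    q_max_r = max(abs(qr_f.min()), abs(qr_f.max()))
    q_max_z = max(abs(qz_f.min()), abs(qz_f.max()))

    # the mass-in-beam factor multiplies every diffracted count, reflections
    # and diffuse scatter alike
    mass_factor = truth.background_scale[frame_index]
    for label, p in truth.reflection_params.items():
        if p["bank"] != bank:
            continue
        amp = p["amplitude"][frame_index] * mass_factor
        if amp <= 0:
            continue
        qr0 = p["q_radial"][frame_index]
        qz0 = p["q_axial"][frame_index]
        if qr0 > q_max_r or qz0 > q_max_z:
            warnings.warn(f"reflection {label} outside detector extent; skipped")
            continue
        s_r, s_z = p["sigma_rad"], p["sigma_ax"]
        r_signs = (1.0,) if qr0 == 0 else (1.0, -1.0)
        z_signs = (1.0,) if qz0 == 0 else (1.0, -1.0)
        for rs in r_signs:
            for zs in z_signs:
                _add_gaussian(expected, qr_f, qz_f, rs * qr0, zs * qz0,
                              amp, s_r, s_z, sz, sr, geom, cos_t, sin_t)

    mask = geom.tile_mask()
    expected[mask] = 0.0
    if noise:
        bank_key = int.from_bytes(bank.encode()[:4].ljust(4, b"\0"), "big")
        rng = np.random.default_rng(
            np.random.SeedSequence([int(truth.seed) & 0x7FFFFFFF,
                                    bank_key, int(frame_index)]))
        pixels = rng.poisson(expected).astype(np.float64)
    else:
        pixels = expected
    return DetectorFrame(
        pixels=pixels, pixel_size=geom.pixel_size, beam_centre=geom.beam_centre,
        camera_length=geom.camera_length, reciprocal_scale=geom.reciprocal_scale,
        tilt=geom.tilt, tile_mask=mask, exposure=geom.exposure,
        frame_time=float(truth.frame_times[frame_index]),
        provenance={"bank": bank, "frame_index": int(frame_index),
                    "seed": int(truth.seed)})


def _add_gaussian(expected, qr_f, qz_f, qr0, qz0, amp, s_r, s_z,
                  scale_z, scale_r, geom, cos_t, sin_t):
    """Add one Gaussian spot, evaluated only inside a ±5σ bounding box."""
    # spot centre in detector pixel coordinates (rotate fibre -> detector)
    qr_det = cos_t * qr0 - sin_t * qz0
    qz_det = sin_t * qr0 + cos_t * qz0
    col = geom.beam_centre[1] + qr_det / scale_r
    row = geom.beam_centre[0] + qz_det / scale_z
    half_r = (5.0 * s_r + abs(sin_t) * 5.0 * s_z) / scale_r + 2
    half_z = (5.0 * s_z + abs(sin_t) * 5.0 * s_r) / scale_z + 2
    r0 = max(int(row - half_z), 0)
    r1 = min(int(row + half_z) + 1, expected.shape[0])
    c0 = max(int(col - half_r), 0)
    c1 = min(int(col + half_r) + 1, expected.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    dr = qr_f[r0:r1, c0:c1] - qr0
    dz = qz_f[r0:r1, c0:c1] - qz0
    expected[r0:r1, c0:c1] += amp * np.exp(
        -0.5 * (dr / s_r) ** 2 - 0.5 * (dz / s_z) ** 2)


def generate_grating_profile(period: float, reciprocal_scale: float,
                             n_orders: int, noise_sd: float = 0.0,
                             n_pixels: int = 2048, sigma_px: float = 2.0,
                             jitter_px: float = 0.0, amp0: float = 1000.0,
                             seed: int = 0) -> Profile1D:
    """1D diffraction profile of a calibration grating, in pixel units.

    Gaussian peaks sit at pixel positions k/(period·scale) for k = 1..n_orders
    with amplitudes decaying as 1/k; ``noise_sd`` adds Gaussian noise as a
    fraction of the local amplitude (plus a small floor), ``jitter_px``
    perturbs peak centres.  The q axis of the returned profile is the PIXEL
    index; spatial calibration turns it into nm^-1.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if n_orders < 2:
        raise ValueError("need at least two orders")
    px_per_order = 1.0 / (period * reciprocal_scale)
    if n_orders * px_per_order > n_pixels - 5 * sigma_px:
        raise ValueError("n_orders exceeds the grid extent")
    x = np.arange(n_pixels, dtype=float)
    rng = np.random.default_rng(seed)
    y = np.zeros_like(x)
    for k in range(1, n_orders + 1):
        centre = k * px_per_order
        if jitter_px:
            centre += rng.normal(0.0, jitter_px)
        y += (amp0 / k) * np.exp(-0.5 * ((x - centre) / sigma_px) ** 2)
    if noise_sd:
        y += rng.normal(0.0, noise_sd * (y + 0.01 * amp0))
        y = np.clip(y, 0.0, None)
    return Profile1D(q=x, intensity=y,
                     roi={"axis": "grating", "units": "pixel",
                          "period_nm": period, "n_orders": n_orders},
                     baseline_state="subtracted")


# ---------------------------------------------------------------------------
# default configurations: the stated experimental conditions
# ---------------------------------------------------------------------------

def _tetanus_relax(slow=1.7, fast=23.0):
    return Relaxation(kind="linear_exp", start_ms=244.0, lin_end_ms=344.0,
                      slow_rate=slow, fast_rate=fast)


def _tetanus_reflections():
    relax = _tetanus_relax()
    T = Trajectory
    specs = [
        # --- equatorials (lattice-tied radial positions) ---
        ReflectionSpec("1,0", T.sigmoid(4000, 2480, 61.0, 16.0, relax),
                       sigma_ax=0.0020, sigma_rad=0.0012, radial_mult=1.0,
                       family="EQ"),
        ReflectionSpec("1,1", T.sigmoid(1989, 2891, 61.0, 16.0, relax),
                       sigma_ax=0.0020, sigma_rad=0.0014, radial_mult=SQRT3,
                       family="EQ"),
        ReflectionSpec("2,0", T.sigmoid(700, 900, 61.0, 16.0, relax),
                       sigma_ax=0.0020, sigma_rad=0.0016, radial_mult=2.0,
                       family="EQ"),
        # inner equatorial of unknown origin (~71 nm), outside the fit window
        ReflectionSpec("IE", T.constant(500), sigma_ax=0.0020,
                       sigma_rad=0.0014, q_radial=1.0 / 71.0),
        # --- M3 interference cluster (shared radial width 0.004) ---
        ReflectionSpec("M3-LA", T.sigmoid(100, 600, 112.8, 25.0, relax),
                       sigma_ax=0.00035, sigma_rad=0.004, d_axial=14.69,
                       axial_scale_key="M3", family="M3"),
        ReflectionSpec("M3-MA", T.sigmoid(2000, 1300, 23.0, 7.0, relax),
                       sigma_ax=0.00035, sigma_rad=0.004, d_axial=14.46,
                       axial_scale_key="M3", family="M3"),
        ReflectionSpec("M3-HA", T.sigmoid(332, 200, 23.0, 7.0, relax),
                       sigma_ax=0.00035, sigma_rad=0.004, d_axial=14.23,
                       axial_scale_key="M3", family="M3"),
        # broad radial component under M3 (lateral misalignment tail)
        ReflectionSpec("M3-diffuse", T.sigmoid(500, 325, 23.0, 7.0, relax),
                       sigma_ax=0.00035, sigma_rad=0.020, d_axial=14.46,
                       axial_scale_key="M3", family="M3"),
        ReflectionSpec("M3L", T.constant(300), sigma_ax=0.00035,
                       sigma_rad=0.004, d_axial=15.52),
        # four extra peaks at 0.062-0.067 nm^-1, not part of M3
        ReflectionSpec("X1", T.constant(150), sigma_ax=0.00035,
                       sigma_rad=0.004, d_axial=16.00),
        ReflectionSpec("X2", T.constant(120), sigma_ax=0.00035,
                       sigma_rad=0.004, d_axial=15.67),
        ReflectionSpec("X3", T.constant(100), sigma_ax=0.00035,
                       sigma_rad=0.004, d_axial=15.34),
        ReflectionSpec("X4", T.constant(80), sigma_ax=0.00035,
                       sigma_rad=0.004, d_axial=15.04),
        # --- M6 cluster ---
        ReflectionSpec("M6-LA", T.sigmoid(250, 190, 30.0, 8.0, relax),
                       sigma_ax=0.0004, sigma_rad=0.004, d_axial=7.26,
                       axial_scale_key="M6", family="M6"),
        ReflectionSpec("M6-MA", T.sigmoid(1400, 1080, 30.0, 8.0, relax),
                       sigma_ax=0.0004, sigma_rad=0.004, d_axial=7.23,
                       axial_scale_key="M6", family="M6"),
        ReflectionSpec("M6-HA", T.sigmoid(250, 195, 30.0, 8.0, relax),
                       sigma_ax=0.0004, sigma_rad=0.004, d_axial=7.20,
                       axial_scale_key="M6", family="M6"),
        ReflectionSpec("M6-diffuse", T.sigmoid(350, 270, 30.0, 8.0, relax),
                       sigma_ax=0.0004, sigma_rad=0.020, d_axial=7.23,
                       axial_scale_key="M6", family="M6"),
        ReflectionSpec("M6L", T.constant(200), sigma_ax=0.0004,
                       sigma_rad=0.004, d_axial=7.62),
        # --- low-order meridionals and M7/M8 ---
        ReflectionSpec("M1", T.sigmoid(800, 500, 72.0, 18.0, relax),
                       sigma_ax=0.0008, sigma_rad=0.004, d_axial=42.9),
        ReflectionSpec("M2", T.constant(300), sigma_ax=0.0008,
                       sigma_rad=0.004, d_axial=21.45),
        ReflectionSpec("M7", T.constant(400), sigma_ax=0.0008,
                       sigma_rad=0.004, d_axial=6.143),
        ReflectionSpec("M7w", T.constant(250), sigma_ax=0.0008,
                       sigma_rad=0.035, d_axial=6.143),
        ReflectionSpec("M8", T.constant(350), sigma_ax=0.0008,
                       sigma_rad=0.004, d_axial=5.375),
        ReflectionSpec("M8w", T.constant(250), sigma_ax=0.0008,
                       sigma_rad=0.035, d_axial=5.375),
        # --- sampled myosin layer lines (x,y,z off-axis reflections) ---
        # rest pattern: 1,1,1 > 1,0,1 ; 1,1,2 > 1,0,2 ; 1,0,3 > 1,1,3
        ReflectionSpec("1,0,1", T.sigmoid(900, 540, 40.0, 12.0, relax),
                       sigma_ax=0.0015, sigma_rad=0.0035, d_axial=42.9,
                       radial_mult=1.0),
        ReflectionSpec("1,1,1", T.sigmoid(1100, 430, 47.9, 12.0, relax),
                       sigma_ax=0.0015, sigma_rad=0.0035, d_axial=42.9,
                       radial_mult=SQRT3),
        ReflectionSpec("2,0,1", T.sigmoid(500, 194, 47.9, 12.0, relax),
                       sigma_ax=0.0015, sigma_rad=0.0035, d_axial=42.9,
                       radial_mult=2.0),
        ReflectionSpec("1,0,2", T.sigmoid(150, 0, 30.0, 9.0, relax),
                       sigma_ax=0.0015, sigma_rad=0.0035, d_axial=21.45,
                       radial_mult=1.0),
        ReflectionSpec("1,1,2", T.sigmoid(600, 250, 47.9, 12.0, relax),
                       sigma_ax=0.0015, sigma_rad=0.0035, d_axial=21.45,
                       radial_mult=SQRT3),
        ReflectionSpec("2,0,2", T.sigmoid(250, 100, 47.9, 12.0, relax),
                       sigma_ax=0.0015, sigma_rad=0.0035, d_axial=21.45,
                       radial_mult=2.0),
        ReflectionSpec("1,0,3", T.sigmoid(700, 120, 23.0, 7.0, relax),
                       sigma_ax=0.0015, sigma_rad=0.0035, d_axial=14.3,
                       radial_mult=1.0),
        ReflectionSpec("1,1,3", T.sigmoid(350, 80, 23.0, 7.0, relax),
                       sigma_ax=0.0015, sigma_rad=0.0035, d_axial=14.3,
                       radial_mult=SQRT3),
        # --- actin layer lines ---
        ReflectionSpec("AL1-in", T.sigmoid(500, 690, 25.0, 8.0, relax),
                       sigma_ax=0.0020, sigma_rad=0.015, d_axial=37.2,
                       q_radial=0.055),
        ReflectionSpec("AL1-out", T.sigmoid(350, 480, 25.0, 8.0, relax),
                       sigma_ax=0.0020, sigma_rad=0.030, d_axial=37.5,
                       q_radial=0.072),
        ReflectionSpec("AL6", T.sigmoid(400, 636, 72.0, 18.0, relax),
                       sigma_ax=0.0015, sigma_rad=0.012, d_axial=5.90,
                       q_radial=0.0475),
    ]
    # sarcomere reflections, even orders 14-24, ultra-small-angle bank
    sl_rest = 2430.0
    for k in range(14, 25, 2):
        amp = 3000.0 * math.exp(-(k - 14) / 4.0)
        specs.append(ReflectionSpec(
            f"SL{k}", T.constant(amp), sigma_ax=8e-5, sigma_rad=2e-4,
            d_axial=sl_rest / k, axial_scale_key="SL", bank="usa",
            family="SL"))
    return tuple(specs)


def tetanus_config(seed: int = 0, n_frames: int = 64,
                   beam_offset: tuple[float, float] = (0.0, 0.0),
                   tilt: float = 0.0) -> SimulationConfig:
    """Fixed-end tetanus: 237 ms train at 80 Hz, 64 frames at 10 ms pitch.

    Frame times are the centres of the 8 ms integration windows and run from
    −26 ms (three rest frames) to +604 ms; stimuli at 0, 12.5, ... 237.5 ms.
    """
    stimuli = tuple(12.5 * k for k in range(20))
    relax = _tetanus_relax()
    cam_sa = CameraConfig(
        shape=(1901, 761), reciprocal_scale=(2e-4, 2e-4),
        beam_centre=(950.0 + beam_offset[0], 380.0 + beam_offset[1]),
        tilt=tilt, camera_length=8.26, exposure=8.0,
        tile_gaps=((1, 380 + 330, 22),))   # one gap at q_r ~ 0.066-0.070
    cam_usa = CameraConfig(
        shape=(1201, 121), reciprocal_scale=(2e-5, 2e-5),
        beam_centre=(600.0, 60.0), tilt=0.0, camera_length=8.26, exposure=8.0)
    return SimulationConfig(
        protocol="tetanus", n_frames=n_frames, frame_pitch_ms=10.0,
        first_frame_ms=-26.0, stimulus_times=stimuli, seed=seed,
        force=Trajectory.sigmoid(0.65, 110.0, 72.3, 18.0, relax),
        sl=Trajectory.sigmoid(2430.0, 2150.0, 29.1, 8.0,
                              _tetanus_relax(slow=0.0, fast=15.0)),
        d10=Trajectory.sigmoid(39.10, 39.70, 60.0, 15.0),
        background_scale=Trajectory.sigmoid(1.0, 1.10, 72.3, 18.0, relax),
        spacing_scales={
            "M3": Trajectory.biphasic(1.0, 0.9990, 14.558 / 14.442,
                                      17.1, 5.0, 78.3, 18.0,
                                      _tetanus_relax(slow=4.3, fast=53.4)),
            "M6": Trajectory.sigmoid(1.0, 7.292 / 7.230, 44.2, 12.0,
                                     _tetanus_relax(slow=2.5, fast=12.3)),
        },
        reflections=_tetanus_reflections(),
        cameras={"sa": cam_sa, "usa": cam_usa})


def twitch_config(seed: int = 0, n_frames: int = 70) -> SimulationConfig:
    """Fixed-end twitch: single stimulus, 70 frames at 5 ms pitch.

    Frame times run from −17.75 ms; peak force ~19 kPa at ~50 ms.  The
    relaxation of every series is a falling logistic (no isometric phase in
    the twitch).  The ultra-small-angle camera emulates the 31 m geometry
    where sarcomere orders 1-9 are visible.
    """
    T = Trajectory
    rel_force = Relaxation(kind="sigmoid", t_half_ms=52.25 + 28.2, tau_ms=12.0)
    rel_slow = Relaxation(kind="sigmoid", t_half_ms=52.25 + 89.4, tau_ms=30.0)
    base = _tetanus_reflections()
    # twitch amplitudes: smaller structural changes, same resting pattern
    overrides = {
        "1,0": T.sigmoid(4000, 3560, 15.7, 5.0, rel_force),
        "1,1": T.sigmoid(1646, 1892, 15.7, 5.0, rel_force),   # ratio 0.48->0.62
        "2,0": T.sigmoid(700, 760, 15.7, 5.0, rel_force),
        "M3-MA": T.sigmoid(2000, 1000, 9.9, 4.0, rel_slow),   # I_M3 -> ~0.52
        "M3-LA": T.constant(100),
        "M3-HA": T.sigmoid(332, 185, 9.9, 4.0, rel_slow),
        "M3-diffuse": T.sigmoid(500, 260, 9.9, 4.0, rel_slow),
        "M6-LA": T.sigmoid(250, 200, 16.5, 6.0, rel_force),
        "M6-MA": T.sigmoid(1400, 1120, 16.5, 6.0, rel_force),
        "M6-HA": T.sigmoid(250, 200, 16.5, 6.0, rel_force),
        "M6-diffuse": T.sigmoid(350, 280, 16.5, 6.0, rel_force),
        "1,0,1": T.sigmoid(900, 585, 15.0, 5.0, rel_slow),
        "1,1,1": T.sigmoid(1100, 913, 24.1, 7.0, rel_slow),
        "2,0,1": T.sigmoid(500, 415, 24.1, 7.0, rel_slow),
        "AL6": T.sigmoid(400, 512, 20.0, 7.0, rel_force),
    }
    specs = []
    for spec in base:
        if spec.family == "SL":
            continue
        if spec.label in overrides:
            spec = replace(spec, amplitude=overrides[spec.label])
        specs.append(spec)
    sl_rest = 2460.0
    for k in range(1, 10):
        amp = 4000.0 / k
        specs.append(ReflectionSpec(
            f"SL{k}", T.constant(amp), sigma_ax=1.2e-5, sigma_rad=2e-4,
            d_axial=sl_rest / k, axial_scale_key="SL", bank="usa",
            family="SL"))

    cam_sa = CameraConfig(shape=(1901, 761), reciprocal_scale=(2e-4, 2e-4),
                          beam_centre=(950.0, 380.0), camera_length=3.2,
                          exposure=4.5)
    cam_usa = CameraConfig(shape=(4001, 81), reciprocal_scale=(2e-6, 2e-5),
                           beam_centre=(2000.0, 40.0), camera_length=31.0,
                           exposure=5.0)
    return SimulationConfig(
        protocol="twitch", n_frames=n_frames, frame_pitch_ms=5.0,
        first_frame_ms=-17.75, stimulus_times=(0.0,), seed=seed,
        force=T.sigmoid(0.65, 18.76, 18.0, 5.0, rel_force),
        sl=T.sigmoid(2460.0, 2420.0, 14.0, 5.0, rel_force),
        d10=T.sigmoid(37.86, 37.66, 18.0, 6.0, rel_force),
        background_scale=T.constant(1.0),
        spacing_scales={
            "M3": T.sigmoid(1.0, 14.446 / 14.452, 9.9, 4.0, rel_slow),
            "M6": T.sigmoid(1.0, 7.242 / 7.226, 16.5, 6.0, rel_force),
        },
        reflections=tuple(specs),
        cameras={"sa": cam_sa, "usa": cam_usa})
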