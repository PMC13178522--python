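"""Activation and relaxation kinetics of force and structural signals.

Half-times come from logistic ("sigmoidal") fits over fixed windows:
activation between −26 and 234 ms (tetanus) or −17.75 and 52.25 ms (twitch),
with t½ referenced to the first stimulus; tetanus relaxation between 234 and
604 ms referenced to the last stimulus; twitch relaxation referenced to
t = 52.25 ms.  Signals with an early fall followed by a slow rise (I_M3,
A_M3, S_M3 in the tetanus) use a double-sigmoid with opposite-sign
amplitudes, reporting fast and slow branch half-times.  The isometric
("slow") relaxation rate is the normalized linear slope between 244 and
324 ms, and the exponential ("fast") rate comes from an exponential fit
between 344 and 604 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = ["KineticsResult", "fit_sigmoid", "fit_double_sigmoid",
           "slow_krel", "fast_krel", "TETANUS_WINDOWS", "TWITCH_WINDOWS"]

#: standard fit windows (ms) and half-time reference times
TETANUS_WINDOWS = {
    "activation": (-26.0, 234.0), "activation_ref": 0.0,
    "relaxation": (234.0, 604.0), "relaxation_ref": 237.5,
    "slow_krel": (244.0, 324.0), "fast_krel": (344.0, 604.0),
}
TWITCH_WINDOWS = {
    "activation": (-17.75, 52.25), "activation_ref": 0.0,
    "relaxation": (52.25, 327.75), "relaxation_ref": 52.25,
}


@dataclass
class KineticsResult:
    t_half: float | None = None            # ms, relative to `reference`
    t_half_fast: float | None = None       # ms, double-sigmoid fast branch
    t_half_slow: float | None = None       # ms, double-sigmoid slow branch
    reference: float = 0.0                 # ms, the t½ convention origin
    window: tuple[float, float] = (0.0, 0.0)
    model: str = "logistic"
    params: dict = field(default_factory=dict)
    stderr: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def __post_init__(self):
        if (self.t_half_fast is not None and self.t_half_slow is not None
                and not self.t_half_fast < self.t_half_slow):
            raise ValueError("fast branch t_half must precede slow branch")


def _logistic(t, y0, a, t_half, tau):
    return y0 + a / (1.0 + np.exp(-(t - t_half) / tau))


def _in_window(times, series, window):
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    sel = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    if sel.sum() < 6:
        raise ValueError(f"need >= 6 points in window {window}")
    return times[sel], series[sel]


def fit_sigmoid(times, series, window: tuple[float, float],
                reference: float = 0.0) -> KineticsResult:
    """Logistic fit y = y0 + a/(1 + exp(−(t − t½)/τ)); bounded least squares.

    Works for rising or falling transitions (the sign of ``a`` is free).
    ``reference`` is subtracted from the fitted t½ so activation half-times
    are reported relative to the first stimulus and relaxation half-times
    relative to the protocol's convention.
    """
    t, y = _in_window(times, series, window)
    span = float(y[-3:].mean() - y[:3].mean())
    scale = float(np.ptp(y))
    if scale <= 0 or abs(span) < 1e-12 * max(abs(y).max(), 1.0):
        raise ValueError("amplitude indistinguishable from zero")
    pitch = float(np.median(np.diff(t)))
    p0 = [float(y[:3].mean()), span, float(t[np.argmin(np.abs(
        y - (y[:3].mean() + span / 2)))]), 3 * pitch]
    lo = [-np.inf, -np.inf, window[0] - 5 * pitch, pitch / 10]
    hi = [np.inf, np.inf, window[1] + 5 * pitch, window[1] - window[0]]
    try:
        popt, pcov = optimize.curve_fit(_logistic, t, y, p0=p0,
                                        bounds=(lo, hi), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"sigmoid fit did not converge: {exc}") from exc
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return KineticsResult(
        t_half=float(popt[2] - reference), reference=reference, window=window,
        model="logistic",
        params=dict(zip(("y0", "a", "t_half_abs", "tau"), map(float, popt))),
        stderr=dict(zip(("y0", "a", "t_half_abs", "tau"), map(float, perr))))


def _double_logistic(t, y0, a1, th1, tau1, a2, th2, tau2):
    return (y0 + a1 / (1.0 + np.exp(-(t - th1) / tau1))
            + a2 / (1.0 + np.exp(-(t - th2) / tau2)))


def fit_double_sigmoid(times, series, window: tuple[float, float],
                       reference: float = 0.0,
                       min_branch_separation: float = 20.0) -> KineticsResult:
    """Sum of two logistics with opposite-sign amplitudes.

    For biphasic signals (fast descending then slow ascending phase, or the
    reverse).  Branch half-times are reported with the fast branch first;
    initialization keeps the branches at least ``min_branch_separation`` ms
    apart for identifiability.  If the second branch amplitude collapses the
    fit falls back to a single sigmoid with a notice.
    """
    t, y = _in_window(times, series, window)
    pitch = float(np.median(np.diff(t)))
    y0 = float(y[:3].mean())
    y_end = float(y[-3:].mean())
    # the fast transient runs opposite to the net change: seed it at the
    # extremum on the far side of the baseline from the end level
    i_ext = int(np.argmin(y)) if y_end >= y0 else int(np.argmax(y))
    a1 = float(y[i_ext] - y0)
    a2 = y_end - float(y[i_ext])
    th1 = max(float(t[i_ext]) / 2.0, pitch)
    th2 = max(th1 + min_branch_separation, float(t[i_ext]) + pitch)
    p0 = [y0, a1, th1, 2 * pitch, a2, th2, 4 * pitch]
    lo = [-np.inf, -np.inf, window[0], pitch / 10, -np.inf,
          window[0], pitch / 10]
    hi = [np.inf, np.inf, window[1], window[1] - window[0], np.inf,
          window[1] + 10 * pitch, window[1] - window[0]]
    try:
        popt, pcov = optimize.curve_fit(_double_logistic, t, y, p0=p0,
                                        bounds=(lo, hi), maxfev=40000)
    except RuntimeError:
        popt = None
    fallback = popt is None
    if popt is not None:
        a1_f, a2_f = popt[1], popt[4]
        if (abs(a2_f) < 0.02 * abs(a1_f) or abs(a1_f) < 0.02 * abs(a2_f)
                or np.sign(a1_f) == np.sign(a2_f)):
            fallback = True
    if fallback:
        res = fit_sigmoid(times, series, window, reference)
        res.notes.append("double-sigmoid collapsed; single-sigmoid fallback")
        return res
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    names = ("y0", "a_fast", "t_half_fast_abs", "tau_fast",
             "a_slow", "t_half_slow_abs", "tau_slow")
    th_a, th_b = float(popt[2]), float(popt[5])
    th_fast, th_slow = (th_a, th_b) if th_a <= th_b else (th_b, th_a)
    return KineticsResult(
        t_half_fast=th_fast - reference, t_half_slow=th_slow - reference,
        reference=reference, window=window, model="double-logistic",
        params=dict(zip(names, map(float, popt))),
        stderr=dict(zip(names, map(float, perr))))


def slow_krel(times, series, rest_value: float,
              window: tuple[float, float] = TETANUS_WINDOWS["slow_krel"]
              ) -> float:
    """Isometric relaxation rate (s^-1): normalized linear slope.

    The slope of the linear fit over ``window`` is normalized by the
    difference between the value at the first frame of the window (the first
    frame after the last stimulus) and the resting value.
    """
    t, y = np.asarray(times, float), np.asarray(series, float)
    sel = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
    if sel.sum() < 3:
        raise ValueError(f"need >= 3 points in window {window}")
    slope, _ = np.polyfit(t[sel], y[sel], 1)      # per ms
    start_value = float(y[sel][0])
    denom = start_value - rest_value
    if abs(denom) < 1e-12 * max(abs(start_value), 1.0):
        raise ValueError("relaxation amplitude indistinguishable from zero")
    return float(-slope / denom * 1000.0)


def fast_krel(times, series, rest_value: float | None = None,
              window: tuple[float, float] = TETANUS_WINDOWS["fast_krel"]
              ) -> float:
    """Exponential relaxation rate (s^-1) toward the resting value."""
    t, y = np.asarray(times, float), np.asarray(series, float)
    sel = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
    if sel.sum() < 4:
        raise ValueError(f"need >= 4 points in window {window}")
    t, y = t[sel], y[sel]
    if rest_value is None:
        rest_value = float(y[-3:].mean())

    def model(t, b, k):
        return rest_value + b * np.exp(-k / 1000.0 * (t - t[0]))

    b0 = float(y[0] - rest_value)
    try:
        popt, _ = optimize.curve_fit(model, t, y, p0=[b0, 20.0],
                                     bounds=([-np.inf, 0.0], [np.inf, 1000.0]),
                                     maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"exponential fit did not converge: {exc}") from exc
    return float(popt[1])
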