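"""Frame reduction: centring, tilt correction, mirroring, ROI integration
and hull-baseline subtraction.

The reduction chain turns a raw 2D frame into the 1D profiles the peak
fitting consumes: the frame is centred and de-tilted on the equatorial 1,0
reflection pair, optionally quadrant-mirrored (masked pixels excluded with
weight renormalization), integrated over a named transverse band, and the
residual diffuse background is removed with a lower-convex-hull ("arc hull")
baseline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import replace

import numpy as np
from scipy import ndimage, optimize

from .frames import DetectorFrame
from .profiles import Band, Profile1D, DEFAULT_ROIS

__all__ = ["CentringError", "find_centre_and_tilt", "mirror", "integrate",
           "arc_hull_baseline", "subtract_background_frame"]


class CentringError(RuntimeError):
    """Raised when the equatorial reflection pair cannot be located."""


def _gauss_offset(x, a, mu, sig, c):
    return a * np.exp(-0.5 * ((x - mu) / sig) ** 2) + c


def _locate_spot(pixels, mask, rows, cols, min_snr=5.0):
    """Sub-pixel (row, col) of a single diffraction spot in a window.

    Marginal sums of the background-subtracted window are fitted with a
    1D Gaussian + offset; falls back to the intensity centroid.  Returns
    None if the window is mostly masked or the peak is below ``min_snr``.
    """
    win = pixels[rows[0]:rows[1], cols[0]:cols[1]].astype(float).copy()
    m = mask[rows[0]:rows[1], cols[0]:cols[1]]
    if m.mean() > 0.5 or win.size == 0:
        return None
    win[m] = np.nan
    med = np.nanmedian(win)
    noise = np.nanmedian(np.abs(win - med)) * 1.4826 + 1e-9
    peak = np.nanmax(win) - med
    if peak < min_snr * noise:
        return None
    sub = np.where(m, 0.0, np.clip(win - med, 0.0, None))
    out = []
    for axis, origin in ((1, rows[0]), (0, cols[0])):
        prof = np.nansum(sub, axis=axis)
        x = np.arange(len(prof), dtype=float)
        centroid = float(np.sum(x * prof) / np.sum(prof))
        width = max(math.sqrt(max(np.sum(prof * (x - centroid) ** 2)
                                  / np.sum(prof), 0.25)), 0.5)
        try:
            popt, _ = optimize.curve_fit(
                _gauss_offset, x, prof,
                p0=[prof.max(), centroid, width, 0.0],
                bounds=([0, 0, 0.2, -np.inf], [np.inf, len(prof), len(prof), np.inf]),
                maxfev=2000)
            centre = float(popt[1])
        except RuntimeError:
            centre = centroid
        out.append(origin + centre)
    return tuple(out)  # (row, col)


def _rotate_about(img, angle_deg, centre, order=1, cval=0.0):
    """Rotate an image about an arbitrary (row, col) point."""
    th = math.radians(angle_deg)
    rot = np.array([[math.cos(th), -math.sin(th)],
                    [math.sin(th), math.cos(th)]])
    c = np.asarray(centre, dtype=float)
    offset = c - rot @ c
    return ndimage.affine_transform(img, rot, offset=offset, order=order,
                                    cval=cval, mode="constant")


def find_centre_and_tilt(frame: DetectorFrame, d10_window: tuple[float, float] = (30.0, 50.0),
                         passes: int = 2) -> DetectorFrame:
    """Centre the frame on the equatorial 1,0 pair and level the equator.

    The ±1,0 reflections are located with sub-pixel Gaussian fits; the beam
    centre is set to their midpoint and the frame rotated so the line
    through the pair is horizontal.  If one 1,0 spot is masked, the ±1,1
    pair is used instead.  Runs ``passes`` locate→rotate rounds; the applied
    correction is recorded in ``provenance``.
    """
    out = frame.copy()
    total_tilt = 0.0
    start_centre = frame.beam_centre
    for _ in range(passes):
        pair = _find_equatorial_pair(out, d10_window)
        if pair is None:
            raise CentringError(
                "equatorial 1,0/1,1 pair not detected: signal-to-noise below "
                "threshold or reflections masked")
        (rneg, cneg), (rpos, cpos) = pair
        centre = ((rneg + rpos) / 2.0, (cneg + cpos) / 2.0)
        sz, sr = out.reciprocal_scale
        tilt = math.degrees(math.atan2((rpos - rneg) * sz, (cpos - cneg) * sr))
        out.beam_centre = centre
        if abs(tilt) > 1e-4:
            maskf = _rotate_about(out.tile_mask.astype(float), -tilt, centre,
                                  cval=1.0)
            out.pixels = np.clip(_rotate_about(out.pixels, -tilt, centre), 0, None)
            out.tile_mask = maskf > 1e-3
            total_tilt += tilt
    out.tilt = 0.0
    out.provenance = dict(out.provenance)
    out.provenance["centring"] = {
        "centre_before": list(start_centre),
        "centre_after": list(out.beam_centre),
        "tilt_removed_deg": total_tilt,
    }
    return out


def _find_equatorial_pair(frame: DetectorFrame, d10_window):
    """Locate a symmetric equatorial reflection pair; 1,0 preferred."""
    sz, sr = frame.reciprocal_scale
    z0, r0 = frame.beam_centre
    nz, nr = frame.pixels.shape
    half_rows = max(int(0.006 / sz), 8)
    for mult in (1.0, math.sqrt(3.0)):
        q_lo, q_hi = mult / d10_window[1], mult / d10_window[0]
        spots = []
        for sign in (-1.0, 1.0):
            c_lo = r0 + sign * q_hi / sr
            c_hi = r0 + sign * q_lo / sr
            cols = (max(int(min(c_lo, c_hi)) - 3, 0),
                    min(int(max(c_lo, c_hi)) + 4, nr))
            rows = (max(int(z0) - half_rows, 0), min(int(z0) + half_rows + 1, nz))
            spots.append(_locate_spot(frame.pixels, frame.tile_mask, rows, cols))
        if spots[0] is not None and spots[1] is not None:
            return spots[0], spots[1]
    return None


_FLIPS = {"identity": (1, 1), "h": (1, -1), "v": (-1, 1), "hv": (-1, -1)}


def mirror(frame: DetectorFrame, mode: str = "both",
           use: tuple[str, ...] | None = None) -> DetectorFrame:
    """Average symmetry-related quadrants of a centred frame.

    ``mode``: ``none`` | ``horizontal`` (average left/right) | ``vertical``
    (up/down) | ``both`` (all four) | ``quadrant-select`` (explicit subset of
    reflections via ``use``, e.g. ``("identity", "h")``).  Masked pixels are
    excluded from the average with the weights renormalized; positions where
    every contributing pixel is masked stay masked.
    """
    modes = {"none": ("identity",),
             "horizontal": ("identity", "h"),
             "vertical": ("identity", "v"),
             "both": ("identity", "h", "v", "hv")}
    if mode == "quadrant-select":
        if not use:
            raise ValueError("quadrant-select requires the `use` tuple")
        flips = tuple(use)
    elif mode in modes:
        flips = modes[mode]
    else:
        raise ValueError(f"unknown mirror mode {mode!r}")

    # snap the beam centre to the nearest pixel with one sub-pixel shift so
    # index reflection is an exact involution (mirroring stays idempotent)
    frame = _snap_centre(frame)
    z0 = int(round(frame.beam_centre[0]))
    r0 = int(round(frame.beam_centre[1]))
    nz, nr = frame.pixels.shape
    rows = np.arange(nz)
    cols = np.arange(nr)
    num = np.zeros((nz, nr))
    wsum = np.zeros((nz, nr))
    good = (~frame.tile_mask).astype(float)
    for name in flips:
        fz, fr = _FLIPS[name]
        rr = rows if fz == 1 else 2 * z0 - rows
        cc = cols if fr == 1 else 2 * r0 - cols
        valid_r = (rr >= 0) & (rr < nz)
        valid_c = (cc >= 0) & (cc < nr)
        rr = np.clip(rr, 0, nz - 1)
        cc = np.clip(cc, 0, nr - 1)
        img = frame.pixels[np.ix_(rr, cc)]
        w = good[np.ix_(rr, cc)] * np.outer(valid_r, valid_c)
        num += img * w
        wsum += w
    ok = wsum > 1e-6
    pixels = np.zeros_like(num)
    pixels[ok] = num[ok] / wsum[ok]
    out = frame.copy()
    out.pixels = np.clip(pixels, 0.0, None)
    out.tile_mask = ~ok
    out.provenance = dict(out.provenance)
    out.provenance["mirror"] = {"mode": mode, "use": list(flips)}
    return out


def _snap_centre(frame: DetectorFrame) -> DetectorFrame:
    """Translate the image so the beam centre sits on an integer pixel."""
    z0, r0 = frame.beam_centre
    dz = round(z0) - z0
    dr = round(r0) - r0
    if abs(dz) < 1e-6 and abs(dr) < 1e-6:
        return frame
    out = frame.copy()
    out.pixels = np.clip(
        ndimage.shift(frame.pixels, (dz, dr), order=1, cval=0.0), 0, None)
    maskf = ndimage.shift(frame.tile_mask.astype(float), (dz, dr), order=1,
                          cval=1.0)
    out.tile_mask = maskf > 1e-3
    out.beam_centre = (float(round(z0)), float(round(r0)))
    out.provenance = dict(out.provenance)
    out.provenance["centre_snap"] = [dz, dr]
    return out


def integrate(frame: DetectorFrame, axis: str, band: Band | tuple[float, float],
              side: str = "positive", signed: bool = False) -> Profile1D:
    """Integrate a centred frame over a transverse band.

    ``axis='meridional'``: profile vs axial q, summing columns with
    |q_r| ≤ band.hi (the standard ±half-width convention).  ``'equatorial'``:
    profile vs radial q, summing rows with |q_z| ≤ band.hi.  ``'axial'``:
    profile vs axial q over the radial band [lo, hi] on ``side``
    ('positive'|'negative'|'both' uses |q_r|).  ``'radial'``: profile vs
    radial q over the axial band [lo, hi] (both meridional halves); with
    ``signed=True`` the full signed radial axis is returned (for
    cross-meridional width fits).

    Masked pixels are excluded with the per-bin weight renormalized to the
    full band width; Poisson variance is propagated.
    """
    if isinstance(band, tuple):
        band = Band(*band)
    q_ax = frame.q_axial()
    q_rad = frame.q_radial()
    px = frame.pixels
    good = (~frame.tile_mask).astype(float)

    if axis == "meridional":
        sel = np.abs(q_rad) <= band.hi
        return _band_sum(px, good, sel, along="rows", coord=q_ax,
                         signed=signed, roi=_roi(axis, band, side="both"))
    if axis == "equatorial":
        sel = np.abs(q_ax) <= band.hi
        return _band_sum(px, good, sel, along="cols", coord=q_rad,
                         signed=signed, roi=_roi(axis, band, side="both"))
    if axis == "axial":
        if side == "both":
            sel = (np.abs(q_rad) >= band.lo) & (np.abs(q_rad) <= band.hi)
        elif side == "positive":
            sel = (q_rad >= band.lo) & (q_rad <= band.hi)
        elif side == "negative":
            sel = (q_rad <= -band.lo) & (q_rad >= -band.hi)
        else:
            raise ValueError(f"unknown side {side!r}")
        return _band_sum(px, good, sel, along="rows", coord=q_ax,
                         signed=signed, roi=_roi(axis, band, side=side))
    if axis == "radial":
        sel = (np.abs(q_ax) >= band.lo) & (np.abs(q_ax) <= band.hi)
        return _band_sum(px, good, sel, along="cols", coord=q_rad,
                         signed=signed, roi=_roi(axis, band, side="both"))
    raise ValueError(f"unknown integration axis {axis!r}")


def _roi(axis, band, side):
    return {"axis": axis, "band": [band.lo, band.hi], "side": side,
            "units": band.units}


def _band_sum(px, good, sel, along, coord, signed, roi):
    if not np.any(sel):
        raise ValueError("integration band entirely outside the detector")
    if along == "rows":          # sum selected columns for each row
        sub = px[:, sel]
        w = good[:, sel]
    else:                        # sum selected rows for each column
        sub = px[sel, :].T
        w = good[sel, :].T
    n_band = sub.shape[1]
    n_ok = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        renorm = np.where(n_ok > 0, n_band / np.maximum(n_ok, 1e-12), np.nan)
    raw = (sub * w).sum(axis=1)
    intensity = raw * renorm
    variance = np.clip(raw, 0.0, None) * renorm ** 2
    bad = n_ok == 0
    intensity[bad] = 0.0
    variance[bad] = np.inf
    if signed:
        order = np.argsort(coord)
        return Profile1D(q=coord[order], intensity=intensity[order],
                         variance=variance[order], roi=roi)
    pos = coord > 0
    order = np.argsort(coord[pos])
    return Profile1D(q=coord[pos][order], intensity=intensity[pos][order],
                     variance=variance[pos][order], roi=roi)


def arc_hull_baseline(profile: Profile1D, smoothing: int = 2,
                      depth: float = 0.0) -> tuple[Profile1D, Profile1D]:
    """Lower-convex-hull baseline with optional pre-smoothing and depth.

    The baseline is the lower convex hull of (q, boxcar-smoothed intensity),
    linearly interpolated between hull vertices; ``depth`` pushes it below
    the data by ``depth`` × the local noise scale (median absolute successive
    difference).  Returns ``(baseline, subtracted)``; the subtraction keeps
    negative residuals so band integrals stay unbiased.
    """
    if len(profile.q) < 3:
        raise ValueError("need at least 3 points for a hull baseline")
    y = profile.intensity
    if smoothing > 0:
        win = 2 * smoothing + 1
        kernel = np.ones(win) / win
        ypad = np.pad(y, smoothing, mode="edge")
        ysm = np.convolve(ypad, kernel, mode="valid")
    else:
        ysm = y.copy()
    hull_idx = _lower_hull(profile.q, ysm)
    base = np.interp(profile.q, profile.q[hull_idx], ysm[hull_idx])
    if depth:
        noise = np.median(np.abs(np.diff(y))) / math.sqrt(2.0)
        base = base - depth * noise
    baseline = replace(profile, intensity=base,
                       variance=np.zeros_like(base), baseline_state="baseline")
    subtracted = replace(profile, intensity=y - base,
                         variance=profile.variance.copy(),
                         baseline_state="subtracted")
    return baseline, subtracted


def _lower_hull(x, y):
    """Indices of the lower convex hull of the point set (monotone chain)."""
    idx: list[int] = []
    for i in range(len(x)):
        while len(idx) >= 2:
            i1, i2 = idx[-2], idx[-1]
            cross = ((x[i2] - x[i1]) * (y[i] - y[i1])
                     - (x[i] - x[i1]) * (y[i2] - y[i1]))
            if cross <= 0:       # i2 is above the chord i1->i: drop it
                idx.pop()
            else:
                break
        idx.append(i)
    return np.asarray(idx, dtype=int)


def subtract_background_frame(frame: DetectorFrame,
                              background: DetectorFrame) -> DetectorFrame:
    """Subtract a pre-recorded camera background frame (clipped at zero)."""
    if frame.pixels.shape != background.pixels.shape:
        raise ValueError("background frame shape mismatch")
    out = frame.copy()
    out.pixels = np.clip(frame.pixels - background.pixels, 0.0, None)
    out.tile_mask = frame.tile_mask | background.tile_mask
    out.provenance = dict(out.provenance)
    out.provenance["camera_background_subtracted"] = True
    return out
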