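"""2D detector frame container and TIFF/HDF5 I/O.

A :class:`DetectorFrame` holds one background-inclusive detector exposure
together with the geometry needed to map pixels to reciprocal spacings.
Axis 0 of the pixel array runs along the meridian (axial, parallel to the
muscle axis); axis 1 runs along the equator (radial).  Reciprocal spacings
use the crystallographic convention q = 1/d (nm^-1), so the M3 myosin
meridional reflection of a resting muscle sits near q = 1/14.44 = 0.069 nm^-1.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["DetectorFrame", "write_frames_tiff", "read_frames_tiff",
           "write_frames_hdf5", "read_frames_hdf5"]


@dataclass
class DetectorFrame:
    """One detector exposure with geometry and timing metadata.

    Parameters
    ----------
    pixels
        2D array of non-negative counts, indexed ``[axial, radial]``.
    pixel_size
        Physical pixel edge in µm (metadata only; the analysis works in
        reciprocal units via ``reciprocal_scale``).
    beam_centre
        Fractional pixel coordinates ``(axial, radial)`` of the direct beam.
    camera_length
        Sample-to-detector distance in m (metadata only).
    reciprocal_scale
        nm^-1 per pixel along ``(axial, radial)``; the pixel→q mapping is
        linear (small-angle approximation).
    tilt
        Rotation of the fibre axis relative to the detector columns, degrees.
    tile_mask
        Boolean array, True where the pixel is dead or in a tile gap.
    exposure, frame_time
        Integration time and frame timestamp (centre of the integration
        window), both in ms.
    """

    pixels: np.ndarray
    pixel_size: float = 75.0
    beam_centre: tuple[float, float] = (0.0, 0.0)
    camera_length: float = 8.26
    reciprocal_scale: tuple[float, float] = (2e-4, 2e-4)
    tilt: float = 0.0
    tile_mask: np.ndarray | None = None
    exposure: float = 8.0
    frame_time: float = 0.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.tile_mask is None:
            self.tile_mask = np.zeros(self.pixels.shape, dtype=bool)
        self.tile_mask = np.asarray(self.tile_mask, dtype=bool)
        if self.tile_mask.shape != self.pixels.shape:
            raise ValueError("tile_mask shape must match pixels")
        if np.any(self.pixels[~self.tile_mask] < 0):
            raise ValueError("pixel counts must be non-negative")
        if min(self.reciprocal_scale) <= 0:
            raise ValueError("reciprocal_scale must be positive")

    # -- coordinate helpers -------------------------------------------------
    def q_axial(self) -> np.ndarray:
        """Axial reciprocal coordinate of each row, nm^-1 (signed)."""
        iz = np.arange(self.pixels.shape[0], dtype=float)
        return (iz - self.beam_centre[0]) * self.reciprocal_scale[0]

    def q_radial(self) -> np.ndarray:
        """Radial reciprocal coordinate of each column, nm^-1 (signed)."""
        ir = np.arange(self.pixels.shape[1], dtype=float)
        return (ir - self.beam_centre[1]) * self.reciprocal_scale[1]

    def copy(self) -> "DetectorFrame":
        out = dataclasses.replace(self)
        out.pixels = self.pixels.copy()
        out.tile_mask = self.tile_mask.copy()
        out.provenance = dict(self.provenance)
        return out

    def metadata(self) -> dict:
        return {
            "pixel_size": self.pixel_size,
            "beam_centre": list(self.beam_centre),
            "camera_length": self.camera_length,
            "reciprocal_scale": list(self.reciprocal_scale),
            "tilt": self.tilt,
            "exposure": self.exposure,
            "frame_time": self.frame_time,
        }


def write_frames_tiff(path, frames: list[DetectorFrame]) -> None:
    """Write frames as a float32 TIFF stack; geometry goes in the description."""
    import tifffile

    stack = np.stack([f.pixels.astype(np.float32) for f in frames])
    mask = frames[0].tile_mask
    meta = {"frames": [f.metadata() for f in frames],
            "tile_mask_rle": _mask_pack(mask)}
    tifffile.imwrite(str(path), stack, description=json.dumps(meta))


def read_frames_tiff(path) -> list[DetectorFrame]:
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        stack = tf.asarray()
        meta = json.loads(tf.pages[0].description)
    if stack.ndim == 2:
        stack = stack[None]
    mask = _mask_unpack(meta["tile_mask_rle"], stack.shape[1:])
    out = []
    for img, m in zip(stack, meta["frames"]):
        out.append(DetectorFrame(
            pixels=np.asarray(img, dtype=float),
            pixel_size=m["pixel_size"],
            beam_centre=tuple(m["beam_centre"]),
            camera_length=m["camera_length"],
            reciprocal_scale=tuple(m["reciprocal_scale"]),
            tilt=m["tilt"], tile_mask=mask.copy(),
            exposure=m["exposure"], frame_time=m["frame_time"]))
    return out


def write_frames_hdf5(path, frames: list[DetectorFrame], group: str = "frames") -> None:
    import h5py

    with h5py.File(str(path), "a") as h5:
        if group in h5:
            del h5[group]
        g = h5.create_group(group)
        g.create_dataset("pixels", data=np.stack([f.pixels for f in frames]),
                         dtype="f4", compression="gzip")
        g.create_dataset("tile_mask", data=frames[0].tile_mask)
        g.attrs["metadata"] = json.dumps([f.metadata() for f in frames])


def read_frames_hdf5(path, group: str = "frames") -> list[DetectorFrame]:
    import h5py

    with h5py.File(str(path), "r") as h5:
        g = h5[group]
        stack = np.asarray(g["pixels"], dtype=float)
        mask = np.asarray(g["tile_mask"], dtype=bool)
        meta = json.loads(g.attrs["metadata"])
    return [DetectorFrame(pixels=img, tile_mask=mask.copy(), pixel_size=m["pixel_size"],
                          beam_centre=tuple(m["beam_centre"]),
                          camera_length=m["camera_length"],
                          reciprocal_scale=tuple(m["reciprocal_scale"]),
                          tilt=m["tilt"], exposure=m["exposure"],
                          frame_time=m["frame_time"])
            for img, m in zip(stack, meta)]


def _mask_pack(mask: np.ndarray) -> list[int]:
    # simple run-length encoding of the flattened boolean mask
    flat = mask.ravel()
    if flat.size == 0:
        return []
    edges = np.flatnonzero(np.diff(flat.view(np.int8))) + 1
    runs = np.diff(np.concatenate(([0], edges, [flat.size])))
    return [int(flat[0])] + [int(r) for r in runs]


def _mask_unpack(rle: list[int], shape) -> np.ndarray:
    if not rle:
        return np.zeros(shape, dtype=bool)
    val = bool(rle[0])
    out = np.empty(int(np.prod(shape)), dtype=bool)
    pos = 0
    for run in rle[1:]:
        out[pos:pos + run] = val
        pos += run
        val = not val
    return out.reshape(shape)
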