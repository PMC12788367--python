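"""Raw dual-stream thermal frame codec.

A capture from a compact radiometric camera carries two planes per frame: an
8-bit display plane and a radiometric plane storing one (MSB, LSB) byte pair
per pixel. The pair encodes absolute temperature in units of 1/64 K, so a
pixel decodes as

    R = (256*MSB + LSB) / 64 - 273.15          [raw proxy, deg C]
    T = gain * R + offset                       [calibrated, deg C]

with a linear calibration (``gain``, ``offset``) compensating sensor bias.

This module defines the package's bit-exact fixture layout (the ``.trf``
container), the split/decode/encode operations, hottest-pixel localization,
display-path rendering (contrast, 3x bicubic upscale, false color) and
temperature-map resizing.

Fixture layout (normative for this package)
-------------------------------------------
A ``.trf`` file is a 16-byte little-endian header::

    magic b"TRF1" | H uint16 | W uint16 | f_cam float32 | n_frames uint32

followed by ``n_frames`` records of ``3*H*W`` bytes each: the image plane
(H*W single-byte intensities, row-major) then the thermal plane (H*W byte
pairs, row-major, MSB first). Coordinates are 0-based with x = column and
y = row; ties in extrema break to the first pixel in row-major order.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import (
    ConfigurationError,
    EmptyInputError,
    EncodingRangeError,
    MalformedFrameError,
)

__all__ = [
    "RawFrame",
    "TemperatureMap",
    "DisplayImage",
    "bytes_per_image_plane",
    "split_raw_frame",
    "decode_temperature_map",
    "locate_max_temperature",
    "render_heatmap",
    "resize_temperature_map",
    "encode_raw_frame",
    "read_trf",
    "write_trf",
    "temperature_map_to_csv",
    "temperature_map_from_csv",
]

#: Counts per kelvin in the 16-bit radiometric format.
COUNTS_PER_KELVIN = 64
#: Absolute zero in degrees Celsius; byte pair (0, 0) decodes to this.
ABSOLUTE_ZERO_C = -273.15

_TRF_MAGIC = b"TRF1"
_TRF_HEADER = struct.Struct("<4sHHfI")


def bytes_per_image_plane(height: int, width: int) -> int:
    """Byte count of the display plane (one byte per pixel)."""
    return height * width


def _payload_length(height: int, width: int) -> int:
    return bytes_per_image_plane(height, width) + 2 * height * width


@dataclass(frozen=True)
class RawFrame:
    """One dual-stream capture: display plane + 2-byte-per-pixel thermal plane.

    Parameters
    ----------
    payload : bytes
        Concatenated planes in the fixture layout (image plane first).
    height, width : int
        Dimensions of a single modality, in pixels.
    frame_index : int
        Zero-based position of this frame within its stream.
    """

    payload: bytes
    height: int
    width: int
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise MalformedFrameError(
                f"frame_index must be >= 0, got {self.frame_index}"
            )
        expected = _payload_length(self.height, self.width)
        if len(self.payload) != expected:
            raise MalformedFrameError(
                f"payload for {self.height}x{self.width} frame must be "
                f"{expected} bytes, got {len(self.payload)}"
            )


@dataclass
class TemperatureMap:
    """H x W grid of calibrated temperatures in degrees Celsius."""

    values: np.ndarray
    gain: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ConfigurationError(
                f"temperature grid must be 2-D, got shape {self.values.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # (H, W)


@dataclass
class DisplayImage:
    """False-colored display rendering of an image plane."""

    pixels: np.ndarray  # (H', W', 3) uint8
    scale_factor: int = 3
    contrast: float = 1.0


def split_raw_frame(frame: RawFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a raw frame into its image and thermal planes.

    Returns
    -------
    image_plane : ndarray, shape (H, W), uint8
    thermal_plane : ndarray, shape (H, W, 2), uint8
        Per-pixel (MSB, LSB) pairs.
    """
    h, w = frame.height, frame.width
    buf = np.frombuffer(frame.payload, dtype=np.uint8)
    n_img = bytes_per_image_plane(h, w)
    image_plane = buf[:n_img].reshape(h, w).copy()
    thermal_plane = buf[n_img:].reshape(h, w, 2).copy()
    return image_plane, thermal_plane


def decode_temperature_map(
    thermal_plane: np.ndarray, gain: float = 1.0, offset: float = 0.0
) -> TemperatureMap:
    """Decode (MSB, LSB) byte pairs into calibrated temperatures.

    Each pixel decodes as ``gain * ((256*MSB + LSB)/64 - 273.15) + offset``.
    """
    if gain <= 0:
        raise ConfigurationError(f"calibration gain must be > 0, got {gain}")
    plane = np.asarray(thermal_plane, dtype=np.uint8)
    if plane.ndim != 3 or plane.shape[2] != 2:
        raise MalformedFrameError(
            f"thermal plane must have shape (H, W, 2), got {plane.shape}"
        )
    counts = 256.0 * plane[..., 0].astype(np.float64) + plane[..., 1]
    raw_c = counts / COUNTS_PER_KELVIN + ABSOLUTE_ZERO_C
    return TemperatureMap(values=gain * raw_c + offset, gain=gain, offset=offset)


def locate_max_temperature(tmap: TemperatureMap) -> tuple[tuple[int, int], float]:
    """Locate the hottest pixel; ties break to the first in row-major order.

    Returns ``((x, y), t_max)`` with x = column, y = row.
    """
    values = tmap.values
    if values.size == 0:
        raise EmptyInputError("cannot locate maximum of an empty temperature map")
    flat = int(np.argmax(values))
    y, x = divmod(flat, values.shape[1])
    return (x, y), float(values[y, x])


def render_heatmap(
    image_plane: np.ndarray,
    scale_factor: int = 3,
    contrast: float = 1.0,
    colormap: str = "inferno",
) -> DisplayImage:
    """Render the display plane: contrast scale, bicubic upscale, false color.

    The stored plane is single-byte grayscale; the luminance-to-color path
    replicates it to three channels before color mapping, so a monotone
    colormap preserves the intensity ordering of the input.
    """
    import matplotlib

    plane = np.asarray(image_plane, dtype=np.float64)
    if plane.ndim != 2:
        raise MalformedFrameError(
            f"image plane must be 2-D, got shape {plane.shape}"
        )
    scaled = np.clip(contrast * plane, 0.0, 255.0)
    if scale_factor != 1:
        scaled = ndimage.zoom(scaled, scale_factor, order=3, mode="nearest")
        scaled = np.clip(scaled, 0.0, 255.0)
    cmap = matplotlib.colormaps[colormap]
    rgb = cmap(scaled / 255.0)[..., :3]
    pixels = (rgb * 255.0 + 0.5).astype(np.uint8)
    return DisplayImage(pixels=pixels, scale_factor=scale_factor, contrast=contrast)


def resize_temperature_map(
    tmap: TemperatureMap, w_out: int, h_out: int
) -> TemperatureMap:
    """Bilinear resize with pixel-center alignment; identity when sizes match.

    Output pixel centers map to input coordinates via
    ``x_in = (x_out + 0.5) * W/W_out - 0.5`` (clamped at the edges), the
    convention used by mainstream image libraries; constant maps stay constant.
    """
    if w_out < 1 or h_out < 1:
        raise ConfigurationError(
            f"target dimensions must be >= 1, got ({w_out}, {h_out})"
        )
    h, w = tmap.shape
    if (w_out, h_out) == (w, h):
        return TemperatureMap(tmap.values.copy(), tmap.gain, tmap.offset)
    ys = (np.arange(h_out) + 0.5) * (h / h_out) - 0.5
    xs = (np.arange(w_out) + 0.5) * (w / w_out) - 0.5
    grid_y, grid_x = np.meshgrid(ys, xs, indexing="ij")
    out = ndimage.map_coordinates(
        tmap.values, [grid_y, grid_x], order=1, mode="nearest"
    )
    return TemperatureMap(out, tmap.gain, tmap.offset)


def encode_raw_frame(
    tmap: TemperatureMap,
    image_plane: np.ndarray | None = None,
    frame_index: int = 0,
) -> RawFrame:
    """Encode a temperature map (and optional display plane) into a raw frame.

    Inverts the decode: ``counts = round(((T - offset)/gain + 273.15) * 64)``,
    so a decode of the result reproduces the map within the 1/64 K * gain
    quantization step. When no display plane is given, a grayscale rendering
    of the map over its own range is synthesized.
    """
    h, w = tmap.shape
    kelvin = (tmap.values - tmap.offset) / tmap.gain - ABSOLUTE_ZERO_C
    counts = np.rint(kelvin * COUNTS_PER_KELVIN)
    if np.any(counts < 0) or np.any(counts > 0xFFFF):
        bad = float(tmap.values.flat[int(np.argmax(np.abs(counts - 0x7FFF)))])
        raise EncodingRangeError(
            f"temperature {bad} degC not representable in 16-bit counts"
        )
    counts = counts.astype(np.uint16)
    thermal = np.empty((h, w, 2), dtype=np.uint8)
    thermal[..., 0] = counts >> 8
    thermal[..., 1] = counts & 0xFF

    if image_plane is None:
        lo, hi = float(tmap.values.min()), float(tmap.values.max())
        span = hi - lo if hi > lo else 1.0
        image_plane = ((tmap.values - lo) / span * 255.0).astype(np.uint8)
    else:
        image_plane = np.asarray(image_plane, dtype=np.uint8)
        if image_plane.shape != (h, w):
            raise MalformedFrameError(
                f"image plane shape {image_plane.shape} does not match map {h}x{w}"
            )
    payload = image_plane.tobytes() + thermal.tobytes()
    return RawFrame(payload=payload, height=h, width=w, frame_index=frame_index)


# ---------------------------------------------------------------------------
# .trf container I/O
# ---------------------------------------------------------------------------

def write_trf(path: str | Path, frames: Sequence[RawFrame], f_cam: float) -> None:
    """Write a frame stream to a ``.trf`` fixture file."""
    frames = list(frames)
    if not frames:
        raise EmptyInputError("cannot write an empty frame stream")
    h, w = frames[0].height, frames[0].width
    with open(path, "wb") as fh:
        fh.write(_TRF_HEADER.pack(_TRF_MAGIC, h, w, float(f_cam), len(frames)))
        for frame in frames:
            if (frame.height, frame.width) != (h, w):
                raise MalformedFrameError("all frames in a stream must share dimensions")
            fh.write(frame.payload)


def read_trf(path: str | Path) -> tuple[list[RawFrame], float]:
    """Read a ``.trf`` fixture file; returns (frames, f_cam)."""
    with open(path, "rb") as fh:
        header = fh.read(_TRF_HEADER.size)
        if len(header) != _TRF_HEADER.size:
            raise MalformedFrameError("truncated .trf header")
        magic, h, w, f_cam, n_frames = _TRF_HEADER.unpack(header)
        if magic != _TRF_MAGIC:
            raise MalformedFrameError(f"bad magic {magic!r}, expected {_TRF_MAGIC!r}")
        frame_bytes = _payload_length(h, w)
        frames = []
        for k in range(n_frames):
            payload = fh.read(frame_bytes)
            if len(payload) != frame_bytes:
                raise MalformedFrameError(
                    f"frame {k}: expected {frame_bytes} bytes, got {len(payload)}"
                )
            frames.append(RawFrame(payload=payload, height=h, width=w, frame_index=k))
    return frames, float(f_cam)


def temperature_map_to_csv(
    tmap: TemperatureMap, path: str | Path, frame_index: int = 0
) -> None:
    """Export a map as CSV: first field the frame index, then row-major values."""
    row = np.concatenate([[frame_index], tmap.values.ravel()])
    with open(path, "w") as fh:
        fh.write(f"# height={tmap.shape[0]} width={tmap.shape[1]}\n")
        fh.write(",".join(repr(v) for v in row.tolist()) + "\n")


def temperature_map_from_csv(path: str | Path) -> tuple[int, TemperatureMap]:
    """Read a map written by :func:`temperature_map_to_csv`."""
    with open(path) as fh:
        header = fh.readline().strip()
        parts = dict(p.split("=") for p in header.lstrip("# ").split())
        h, w = int(parts["height"]), int(parts["width"])
        fields = [float(v) for v in fh.readline().strip().split(",")]
    frame_index = int(fields[0])
    values = np.array(fields[1:], dtype=np.float64).reshape(h, w)
    return frame_index, TemperatureMap(values)
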