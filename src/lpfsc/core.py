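"""Shared domain types and RF-frame container I/O.

Coordinate conventions used throughout the package:

* all lengths are in meters, 2-D coordinates are ``(x, y)`` with ``x``
  lateral and ``y`` axial (depth);
* image/phantom pixel ``(i, j)`` (row, column) sits at
  ``(origin_x + j * pixel_size, origin_y + i * pixel_size)``; pixel indices
  are 0-based and ``origin`` is the center of pixel ``(0, 0)``;
* the time axis starts at the laser firing: sample ``k`` of a channel was
  recorded at ``t0 + k / fs``.

RF amplitude carries arbitrary linear units; nothing in the pipeline
depends on an absolute pressure calibration.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "RFFrame",
    "FrameStack",
    "NoiseSpec",
    "ArrayGeometry",
    "Phantom",
    "PAImage",
    "circular_array",
    "linear_array",
    "phased_array",
    "read_rf",
    "write_rf",
    "save_image",
]


@dataclasses.dataclass(frozen=True)
class RFFrame:
    """One multi-channel radio-frequency acquisition.

    Parameters
    ----------
    data
        ``(n_samples, n_channels)`` float array, arbitrary pressure units.
    fs
        Sampling frequency in Hz.
    t0
        Time of the first sample relative to the laser firing, seconds.
    """

    data: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim == 1:
            data = data[:, None]
        if data.ndim != 2:
            raise ValueError(f"RF data must be 2-D, got shape {data.shape}")
        if data.shape[0] < 2:
            raise ValueError("RF frame needs at least 2 samples per channel")
        if data.shape[1] < 1:
            raise ValueError("RF frame needs at least 1 channel")
        if not np.all(np.isfinite(data)):
            raise ValueError("RF data contains non-finite entries")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "fs", float(self.fs))
        object.__setattr__(self, "t0", float(self.t0))

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def with_data(self, data: np.ndarray) -> "RFFrame":
        """Same acquisition metadata, new sample matrix."""
        return RFFrame(data=data, fs=self.fs, t0=self.t0)


@dataclasses.dataclass(frozen=True)
class FrameStack:
    """Ordered sequence of same-shape :class:`RFFrame` (repeat acquisitions)."""

    frames: tuple
    seed_info: dict | None = None

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if not frames:
            raise ValueError("FrameStack needs at least one frame")
        ref = frames[0]
        for k, f in enumerate(frames):
            if f.data.shape != ref.data.shape:
                raise ValueError(
                    f"frame {k} shape {f.data.shape} != {ref.data.shape}"
                )
            if f.fs != ref.fs:
                raise ValueError(f"frame {k} fs {f.fs} != {ref.fs}")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise level (dB SNR) and its seed."""

    snr_db: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


@dataclasses.dataclass(frozen=True)
class ArrayGeometry:
    """Transducer element layout.

    ``positions`` is an ``(n_elements, 2)`` array of element-center
    coordinates in meters.
    """

    kind: str
    positions: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in {"circular", "linear", "phased"}:
            raise ValueError(f"unknown array kind {self.kind!r}")
        pos = np.asarray(self.positions, dtype=np.float64)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 1:
            raise ValueError("positions must be (n_elements, 2)")
        object.__setattr__(self, "positions", pos)

    @property
    def n_elements(self) -> int:
        return self.positions.shape[0]


def circular_array(n_elements: int = 60, diameter: float = 9e-3) -> ArrayGeometry:
    """Ring of evenly spaced point detectors centered at the origin.

    The default matches a 60-element, 9-mm-diameter tomographic ring
    (adjacent angular spacing 6 degrees).  Element 0 sits on the +x axis.
    """
    angles = 2.0 * np.pi * np.arange(n_elements) / n_elements
    r = diameter / 2.0
    pos = np.column_stack([r * np.cos(angles), r * np.sin(angles)])
    return ArrayGeometry(kind="circular", positions=pos)


def linear_array(n_elements: int = 128, pitch: float = 0.3e-3) -> ArrayGeometry:
    """Linear array along the x axis at depth y = 0, centered on x = 0."""
    x = (np.arange(n_elements) - (n_elements - 1) / 2.0) * pitch
    pos = np.column_stack([x, np.zeros(n_elements)])
    return ArrayGeometry(kind="linear", positions=pos)


def phased_array(n_elements: int = 64, aperture: float = 9e-3) -> ArrayGeometry:
    """Compact phased array (endoscopic-style): 64 elements over 9 mm."""
    x = np.linspace(-aperture / 2.0, aperture / 2.0, n_elements)
    pos = np.column_stack([x, np.zeros(n_elements)])
    return ArrayGeometry(kind="phased", positions=pos)


@dataclasses.dataclass(frozen=True)
class Phantom:
    """Initial-pressure map on a square pixel grid.

    ``p0[i, j]`` is the (nonnegative) initial pressure at row ``i`` (depth
    index) and column ``j`` (lateral index).
    """

    p0: np.ndarray
    pixel_size: float
    c: float = 1500.0
    origin: tuple = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        p0 = np.asarray(self.p0, dtype=np.float64)
        if p0.ndim != 2:
            raise ValueError("p0 must be a 2-D array")
        if not np.all(np.isfinite(p0)) or np.any(p0 < 0):
            raise ValueError("p0 must be finite and nonnegative")
        if not self.c > 0:
            raise ValueError("sound speed must be positive")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        origin = self.origin
        if origin is None:
            # grid centered on the coordinate origin
            ny, nx = p0.shape
            origin = (
                -(nx - 1) / 2.0 * self.pixel_size,
                -(ny - 1) / 2.0 * self.pixel_size,
            )
        object.__setattr__(self, "p0", p0)
        object.__setattr__(self, "origin", (float(origin[0]), float(origin[1])))

    def pixel_coords(self) -> tuple:
        """``(x, y)`` coordinate arrays of shape ``p0.shape``."""
        ny, nx = self.p0.shape
        x = self.origin[0] + np.arange(nx) * self.pixel_size
        y = self.origin[1] + np.arange(ny) * self.pixel_size
        return np.meshgrid(x, y)


@dataclasses.dataclass(frozen=True)
class PAImage:
    """Reconstructed photoacoustic image on a square pixel grid."""

    pixels: np.ndarray
    pixel_size: float
    origin: tuple = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite")
        origin = self.origin
        if origin is None:
            ny, nx = px.shape
            origin = (
                -(nx - 1) / 2.0 * self.pixel_size,
                -(ny - 1) / 2.0 * self.pixel_size,
            )
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "origin", (float(origin[0]), float(origin[1])))


# ---------------------------------------------------------------------------
# RF container I/O
#
# There is no community file standard for photoacoustic channel data, so the
# dialect is pinned here bit-exactly: raw little-endian float64 column-major
# payload in ``<path>`` plus a JSON sidecar ``<path>.json`` holding the
# sampling metadata.  Writing the same frame twice produces byte-identical
# files.
# ---------------------------------------------------------------------------

_SIDECAR_SUFFIX = ".json"


def write_rf(frame: RFFrame, path) -> Path:
    """Write an :class:`RFFrame` to ``path`` (payload) + ``path.json`` (meta).

    Returns the payload path.
    """
    path = Path(path)
    payload = np.asfortranarray(frame.data, dtype="<f8")
    meta = {
        "format": "lpfsc-rf-v1",
        "shape": [frame.n_samples, frame.n_channels],
        "dtype": "<f8",
        "order": "F",
        "fs": frame.fs,
        "t0": frame.t0,
        "units": "arbitrary",
    }
    path.write_bytes(payload.tobytes(order="F"))
    sidecar = path.with_name(path.name + _SIDECAR_SUFFIX)
    sidecar.write_text(json.dumps(meta, sort_keys=True, indent=0) + "\n")
    return path


def read_rf(path) -> RFFrame:
    """Read an RF container written by :func:`write_rf`."""
    path = Path(path)
    sidecar = path.with_name(path.name + _SIDECAR_SUFFIX)
    if not path.exists():
        raise FileNotFoundError(f"RF payload not found: {path}")
    if not sidecar.exists():
        raise FileNotFoundError(f"RF sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("shape", "fs"):
        if key not in meta:
            raise ValueError(f"RF sidecar missing required key {key!r}")
    n_samples, n_channels = (int(v) for v in meta["shape"])
    raw = path.read_bytes()
    expected = n_samples * n_channels * 8
    if len(raw) != expected:
        raise ValueError(
            f"RF payload has {len(raw)} bytes, metadata implies {expected}"
        )
    data = np.frombuffer(raw, dtype="<f8").reshape(
        (n_samples, n_channels), order=meta.get("order", "F")
    )
    return RFFrame(data=data.copy(), fs=float(meta["fs"]), t0=float(meta.get("t0", 0.0)))


def save_image(image: PAImage, path) -> Path:
    """Export a :class:`PAImage` as 16-bit TIFF plus a float64 raw sidecar.

    The TIFF is peak-scaled to the uint16 range for viewing; the exact pixel
    values go to ``<path>.raw`` (little-endian float64, C order) with shape
    recorded in ``<path>.json``.
    """
    path = Path(path)
    px = image.pixels
    peak = np.max(np.abs(px))
    scaled = np.zeros_like(px) if peak == 0 else np.clip(px / peak, 0.0, 1.0)
    tifffile.imwrite(path, (scaled * 65535.0 + 0.5).astype(np.uint16))
    raw = path.with_name(path.name + ".raw")
    raw.write_bytes(np.ascontiguousarray(px, dtype="<f8").tobytes())
    meta = {
        "shape": list(px.shape),
        "dtype": "<f8",
        "order": "C",
        "pixel_size": image.pixel_size,
        "origin": list(image.origin),
    }
    path.with_name(path.name + ".json").write_text(
        json.dumps(meta, sort_keys=True) + "\n"
    )
    return path
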