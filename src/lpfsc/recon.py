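"""Delay-and-sum image formation from multi-channel RF data.

Conventional DAS: every pixel sums, over all elements, the RF sample at
the one-way time of flight from pixel to element (linear interpolation
between samples, zero outside the recorded window), with uniform element
weighting (no apodization).  The summed image is envelope-detected along
the depth direction (magnitude of the analytic signal per column) and
peak-normalized to [0, 1] for display and metric computation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.signal

from .core import ArrayGeometry, PAImage, RFFrame

__all__ = ["ReconGrid", "envelope", "das_reconstruct"]


@dataclasses.dataclass(frozen=True)
class ReconGrid:
    """Reconstruction pixel grid; default 128x128 over a 10-mm field."""

    nx: int = 128
    ny: int = 128
    pixel_size: float = 10e-3 / 128
    origin: tuple = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1 or not self.pixel_size > 0:
            raise ValueError("invalid grid")
        origin = self.origin
        if origin is None:
            origin = (
                -(self.nx - 1) / 2.0 * self.pixel_size,
                -(self.ny - 1) / 2.0 * self.pixel_size,
            )
        object.__setattr__(self, "origin", (float(origin[0]), float(origin[1])))

    def pixel_coords(self) -> tuple:
        x = self.origin[0] + np.arange(self.nx) * self.pixel_size
        y = self.origin[1] + np.arange(self.ny) * self.pixel_size
        return np.meshgrid(x, y)


def envelope(signal: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal (Hilbert envelope)."""
    s = np.asarray(signal, dtype=np.float64)
    if s.shape[0] < 4:
        raise ValueError("signal too short for envelope detection")
    return np.abs(scipy.signal.hilbert(s, axis=0))


def das_reconstruct(
    frame: RFFrame,
    geometry: ArrayGeometry,
    grid: ReconGrid | None = None,
    c: float = 1500.0,
    normalize: bool = True,
) -> PAImage:
    """Delay-and-sum reconstruction (see module docstring).

    With ``normalize=False`` the envelope image is returned without peak
    scaling; the map from RF to that image is positively homogeneous.
    """
    grid = grid or ReconGrid()
    if frame.n_channels != geometry.n_elements:
        raise ValueError(
            f"channel count {frame.n_channels} != element count {geometry.n_elements}"
        )
    X, Y = grid.pixel_coords()
    acc = np.zeros(X.size)
    sample_axis = np.arange(frame.n_samples, dtype=np.float64)
    for e, (ex, ey) in enumerate(geometry.positions):
        delays = np.hypot(X.ravel() - ex, Y.ravel() - ey) / c
        pos = (delays - frame.t0) * frame.fs
        acc += np.interp(pos, sample_axis, frame.data[:, e], left=0.0, right=0.0)
    img = acc.reshape(grid.ny, grid.nx)
    img = envelope(img) if grid.ny >= 4 else np.abs(img)
    if normalize:
        peak = np.max(img)
        if peak > 0:
            img = img / peak
    return PAImage(pixels=img, pixel_size=grid.pixel_size, origin=grid.origin)
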