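"""Synthetic photoacoustic acquisitions: phantoms, forward model, noise.

The generator emulates a tomographic in-silico study — a 512x512
vascular initial-pressure map on a 10-mm grid, received by a 60-element,
9-mm-diameter circular array of point detectors at 108 MHz (1019 samples,
sound speed 1500 m/s) — plus two physical-phantom presets: a pair of
150-um filaments 1 mm apart, and three 1-mm blood-filled tubes at 10, 15
and 20 mm depth for sector-probe imaging.

The forward model is an analytic point-source superposition: each
nonzero pixel radiates the emitted pulse delayed by its time of flight
and attenuated as 1/r (far-field, homogeneous medium, no dispersion or
frequency-dependent attenuation).  The emitted waveform is a broadband
bipolar Ricker wavelet by default (see :class:`PulseSpec`), emulating the
sharp pressure transients that broadband point sensors record; a
band-limited Gabor pulse is available for transducer-style acquisitions.

Additive white Gaussian noise is calibrated against the mean power of the
whole clean frame: ``10 log10(P_signal / P_noise) = snr_db``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core import ArrayGeometry, NoiseSpec, Phantom, RFFrame

__all__ = [
    "PulseSpec",
    "AcquisitionSpec",
    "make_vessel_phantom",
    "make_filament_phantom",
    "make_tube_phantom",
    "forward_simulate",
    "add_noise",
]

_DEFAULT_DT = 9.259e-9  # seconds between samples (108 MHz)


@dataclasses.dataclass(frozen=True)
class PulseSpec:
    """Emitted per-pixel waveform.

    ``'ricker'`` (default): second-derivative-of-Gaussian wavelet with
    spectral peak at ``f0`` — an even, bipolar, broadband pulse standing
    in for the sharp N-shaped pressure transients that broadband point
    sensors record from small absorbers in a full-wave simulation.  Its
    wide spectrum extends well above typical high-pass cutoffs, which is
    what gives the recorded channels the sparse-with-sparse-derivative
    structure the denoiser models.

    ``'gabor'``: Gaussian-enveloped cosine with -6 dB fractional
    bandwidth ``frac_bandwidth`` — a band-limited transducer-style pulse
    for emulating hardware probes (e.g., a 4-11 MHz transducer).

    Both shapes are even with peak amplitude 1 at t = 0, so a point
    source's recorded amplitude peak falls exactly at its nominal delay.
    """

    shape: str = "ricker"
    f0: float = 12e6
    frac_bandwidth: float = 0.7

    def __post_init__(self) -> None:
        if self.shape not in {"ricker", "gabor"}:
            raise ValueError(f"unsupported pulse shape {self.shape!r}")
        if not (self.f0 > 0 and 0 < self.frac_bandwidth < 2):
            raise ValueError("invalid pulse parameters")

    @property
    def sigma_t(self) -> float:
        """Characteristic time width (support ~ +/- 4-5 sigma_t)."""
        if self.shape == "ricker":
            return np.sqrt(2.0) / (2.0 * np.pi * self.f0)
        sigma_f = self.frac_bandwidth * self.f0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return 1.0 / (2.0 * np.pi * sigma_f)

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Pulse amplitude at times ``t`` (seconds, 0 = arrival); peak 1 at 0."""
        s = self.sigma_t
        if self.shape == "ricker":
            return (1.0 - (t / s) ** 2) * np.exp(-(t**2) / (2.0 * s**2))
        return np.cos(2.0 * np.pi * self.f0 * t) * np.exp(-(t**2) / (2.0 * s**2))


@dataclasses.dataclass(frozen=True)
class AcquisitionSpec:
    """Sampling parameters of one simulated acquisition."""

    fs: float = 1.0 / _DEFAULT_DT
    n_samples: int = 1019
    pulse: PulseSpec = dataclasses.field(default_factory=PulseSpec)
    c: float = 1500.0

    def __post_init__(self) -> None:
        if not (self.fs > 0 and self.c > 0 and self.n_samples >= 2):
            raise ValueError("invalid acquisition parameters")


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------


def _stamp_disc(img: np.ndarray, ci: float, cj: float, radius: float, value: float) -> None:
    """Max-blend a filled disc into ``img`` (row ci, col cj, radius in px)."""
    n = img.shape[0]
    r = max(radius, 0.5)
    i0, i1 = max(int(ci - r) - 1, 0), min(int(ci + r) + 2, n)
    j0, j1 = max(int(cj - r) - 1, 0), min(int(cj + r) + 2, n)
    if i0 >= i1 or j0 >= j1:
        return
    ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
    mask = (ii - ci) ** 2 + (jj - cj) ** 2 <= r**2
    patch = img[i0:i1, j0:j1]
    patch[mask] = np.maximum(patch[mask], value)


def make_vessel_phantom(size: int = 512, seed: int = 0) -> Phantom:
    """Random branching vascular initial-pressure map on a 10-mm grid.

    Curvilinear vessel trees are grown by momentum-biased random walks:
    trunks start near the center with widths up to ~6 px (at size 512),
    taper as they grow, and stochastically spawn thinner branches.  All
    structure stays inside a disc comfortably within a 9-mm-diameter
    detection ring; values lie in [0, 1]; identical output per seed.
    """
    if size < 64:
        raise ValueError("size must be >= 64")
    rng = np.random.default_rng(seed)
    img = np.zeros((size, size))
    center = (size - 1) / 2.0
    r_max = 0.33 * size
    scale = size / 512.0

    n_trunks = int(rng.integers(2, 5))
    # each walker: [row, col, angle, width_px, amplitude, steps_left]
    stack = []
    for _ in range(n_trunks):
        ang0 = rng.uniform(0, 2 * np.pi)
        r0 = rng.uniform(0.1, 0.5) * r_max
        stack.append(
            [
                center + r0 * np.sin(ang0),
                center + r0 * np.cos(ang0),
                rng.uniform(0, 2 * np.pi),
                rng.uniform(4.0, 6.0) * scale,
                rng.uniform(0.7, 1.0),
                int(rng.integers(250, 450) * scale),
            ]
        )
    while stack:
        i, j, ang, width, amp, steps = stack.pop()
        curl = rng.normal(0.0, 0.003)
        while steps > 0 and width >= 0.8 * scale:
            steps -= 1
            ang += rng.normal(0.0, 0.06) + curl
            i += np.sin(ang)
            j += np.cos(ang)
            if (i - center) ** 2 + (j - center) ** 2 > r_max**2:
                break
            _stamp_disc(img, i, j, width / 2.0, amp)
            width *= 0.9985
            if width > 1.6 * scale and rng.random() < 0.012:
                stack.append(
                    [
                        i,
                        j,
                        ang + rng.choice([-1.0, 1.0]) * rng.uniform(0.4, 1.0),
                        width * rng.uniform(0.5, 0.75),
                        amp * rng.uniform(0.85, 1.0),
                        int(steps * rng.uniform(0.4, 0.9)),
                    ]
                )
    return Phantom(p0=np.clip(img, 0.0, 1.0), pixel_size=10e-3 / size)


def make_filament_phantom(size: int = 512) -> Phantom:
    """Two 150-um absorbing filaments (cross-sections) 1 mm apart."""
    px = 10e-3 / size
    img = np.zeros((size, size))
    center = (size - 1) / 2.0
    r = 75e-6 / px
    off = 0.5e-3 / px
    _stamp_disc(img, center, center - off, r, 1.0)
    _stamp_disc(img, center, center + off, r, 1.0)
    return Phantom(p0=img, pixel_size=px)


def make_tube_phantom(size: int = 512) -> Phantom:
    """Three 1-mm tubes (ring cross-sections) at 10/15/20 mm depth.

    Laid out for a sector probe at y = 0: the grid spans 25.6 mm of depth
    (50-um pixels), laterally centered on the probe axis.  Tube walls are
    the absorbers (0.1-mm wall), as in blood-filled-tube targets where the
    wall boundaries dominate the photoacoustic contrast.
    """
    px = 50e-6
    img = np.zeros((size, size))
    origin = (-(size - 1) / 2.0 * px, 0.0)
    depths = (10e-3, 15e-3, 20e-3)
    laterals = (-2e-3, 0.0, 2e-3)
    r_out = 0.5e-3 / px
    r_in = 0.4e-3 / px
    for depth, lat in zip(depths, laterals):
        ci = depth / px
        cj = (lat - origin[0]) / px
        _stamp_disc(img, ci, cj, r_out, 1.0)
        # carve the lumen
        n = img.shape[0]
        i0, i1 = int(ci - r_in), int(ci + r_in) + 2
        j0, j1 = int(cj - r_in), int(cj + r_in) + 2
        ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
        mask = (ii - ci) ** 2 + (jj - cj) ** 2 <= r_in**2
        img[i0:i1, j0:j1][mask] = 0.0
    return Phantom(p0=img, pixel_size=px, origin=origin)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def forward_simulate(
    phantom: Phantom, geometry: ArrayGeometry, acq: AcquisitionSpec | None = None
) -> RFFrame:
    """Analytic point-source forward model.

    Each nonzero pixel contributes ``p0 * pulse(t − r/c) / max(r, r_min)``
    to every element, with ``r_min`` one pixel to avoid the singularity.
    Output is ``n_samples x n_elements``.
    """
    acq = acq or AcquisitionSpec()
    if phantom.c != acq.c:
        raise ValueError(
            f"sound-speed mismatch: phantom {phantom.c} vs acquisition {acq.c}"
        )
    nz_i, nz_j = np.nonzero(phantom.p0)
    out = np.zeros((acq.n_samples, geometry.n_elements))
    if nz_i.size == 0:
        return RFFrame(data=out, fs=acq.fs, t0=0.0)

    px = phantom.pixel_size
    x = phantom.origin[0] + nz_j * px
    y = phantom.origin[1] + nz_i * px
    amp0 = phantom.p0[nz_i, nz_j]

    if geometry.kind == "circular":
        radii = np.hypot(x, y)
        el_r = np.min(np.hypot(*geometry.positions.T))
        if np.max(radii) >= el_r:
            raise ValueError("phantom does not fit inside the circular aperture")

    # pulse support: +/- 4.5 envelope sigmas, in samples
    half = int(np.ceil(4.5 * acq.pulse.sigma_t * acq.fs)) + 1
    offsets = np.arange(-half, half + 1)
    r_min = px
    for e, (ex, ey) in enumerate(geometry.positions):
        r = np.hypot(x - ex, y - ey)
        a = amp0 / np.maximum(r, r_min)
        t_arr = r / acq.c
        k0 = np.round(t_arr * acq.fs).astype(np.int64)
        idx = k0[:, None] + offsets[None, :]
        t_rel = idx / acq.fs - t_arr[:, None]
        vals = a[:, None] * acq.pulse.waveform(t_rel)
        valid = (idx >= 0) & (idx < acq.n_samples)
        np.add.at(out[:, e], idx[valid], vals[valid])
    return RFFrame(data=out, fs=acq.fs, t0=0.0)


def add_noise(frame: RFFrame, spec: NoiseSpec) -> RFFrame:
    """Add white Gaussian noise at a whole-frame mean-power SNR (dB)."""
    p_signal = float(np.mean(frame.data**2))
    if p_signal == 0.0:
        raise ValueError("clean frame has zero power; SNR undefined")
    sigma = np.sqrt(p_signal * 10.0 ** (-spec.snr_db / 10.0))
    rng = np.random.default_rng(spec.seed)
    noisy = frame.data + sigma * rng.standard_normal(frame.data.shape)
    return frame.with_data(noisy)
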