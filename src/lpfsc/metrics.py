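"""Signal and image quality metrics: PSNR, global SSIM, CNR, FWHM.

Conventions (each selectable or documented where the field is split):

* PSNR defaults to ``20 log10(Smax / MSE)`` — the printed-formula
  convention with the *mean squared* error in the denominator; the
  standard root-mean-square convention ``20 log10(Smax / sqrt(MSE))`` is
  selectable.  ``Smax = max |reference|``.
* SSIM is the single global-statistics form (means, variances and
  covariance over all pixels), not the sliding-window variant;
  ``c1 = (0.01 L)^2`` and ``c2 = (0.03 L)^2`` with ``L`` the images'
  joint dynamic range unless overridden.
* CNR is ``20 log10(|Si − So| / sigma_o)`` with Si/So the mean intensity
  inside the target and background ROIs and sigma_o the background std.
* FWHM is the distance between the two half-maximum crossings nearest
  the profile peak, linearly interpolated between samples.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .core import PAImage

__all__ = [
    "ROISpec",
    "MetricsConfig",
    "MetricsReport",
    "psnr",
    "ssim_global",
    "cnr",
    "fwhm",
    "evaluate_image",
]


Rect = tuple  # (i0, i1, j0, j1), half-open pixel ranges


def _check_rect(rect: Rect, shape: tuple, name: str) -> None:
    i0, i1, j0, j1 = rect
    if not (0 <= i0 < i1 <= shape[0] and 0 <= j0 < j1 <= shape[1]):
        raise ValueError(f"{name} ROI {rect} outside image bounds {shape}")


def _rects_disjoint(a: Rect, b: Rect) -> bool:
    return a[1] <= b[0] or b[1] <= a[0] or a[3] <= b[2] or b[3] <= a[2]


@dataclasses.dataclass(frozen=True)
class ROISpec:
    """Target rectangle(s) and one background rectangle, pixel coordinates."""

    inside: tuple
    outside: Rect

    def __post_init__(self) -> None:
        inside = tuple(tuple(int(v) for v in r) for r in self.inside)
        outside = tuple(int(v) for v in self.outside)
        if not inside:
            raise ValueError("need at least one inside rectangle")
        for r in inside:
            if not _rects_disjoint(r, outside):
                raise ValueError(f"inside ROI {r} overlaps the background ROI")
        object.__setattr__(self, "inside", inside)
        object.__setattr__(self, "outside", outside)

    def validate(self, shape: tuple) -> None:
        for k, r in enumerate(self.inside):
            _check_rect(r, shape, f"inside[{k}]")
        _check_rect(self.outside, shape, "outside")

    def to_json(self) -> str:
        return json.dumps(
            {"inside": [list(r) for r in self.inside], "outside": list(self.outside)}
        )

    @classmethod
    def from_json(cls, text: str) -> "ROISpec":
        d = json.loads(text)
        return cls(
            inside=tuple(tuple(r) for r in d["inside"]), outside=tuple(d["outside"])
        )


@dataclasses.dataclass(frozen=True)
class MetricsConfig:
    """SSIM stabilization constants and the PSNR convention."""

    c1: float | None = None  # default (0.01 L)^2, L = joint dynamic range
    c2: float | None = None  # default (0.03 L)^2
    psnr_convention: str = "as_printed"

    def __post_init__(self) -> None:
        if self.c1 is not None and not self.c1 > 0:
            raise ValueError("c1 must be positive")
        if self.c2 is not None and not self.c2 > 0:
            raise ValueError("c2 must be positive")
        if self.psnr_convention not in {"as_printed", "rmse"}:
            raise ValueError(f"unknown PSNR convention {self.psnr_convention!r}")


def psnr(
    reference: np.ndarray, estimate: np.ndarray, convention: str = "as_printed"
) -> float:
    """Peak signal-to-noise ratio in dB (see module docstring)."""
    ref = np.asarray(reference, dtype=np.float64).ravel()
    est = np.asarray(estimate, dtype=np.float64).ravel()
    if ref.shape != est.shape:
        raise ValueError("reference and estimate must have equal size")
    mse = float(np.mean((ref - est) ** 2))
    smax = float(np.max(np.abs(ref)))
    if mse == 0.0:
        return np.inf
    if convention == "as_printed":
        return 20.0 * np.log10(smax / mse)
    if convention == "rmse":
        return 20.0 * np.log10(smax / np.sqrt(mse))
    raise ValueError(f"unknown PSNR convention {convention!r}")


def ssim_global(
    reference: np.ndarray, estimate: np.ndarray, cfg: MetricsConfig | None = None
) -> float:
    """Global-statistics structural similarity index."""
    cfg = cfg or MetricsConfig()
    ref = np.asarray(reference, dtype=np.float64)
    est = np.asarray(estimate, dtype=np.float64)
    if ref.shape != est.shape:
        raise ValueError("images must have the same shape")
    # joint dynamic range keeps the default-constant metric symmetric
    L = float(max(np.ptp(ref), np.ptp(est)))
    if L == 0:
        L = 1.0
    c1 = cfg.c1 if cfg.c1 is not None else (0.01 * L) ** 2
    c2 = cfg.c2 if cfg.c2 is not None else (0.03 * L) ** 2
    mu_r, mu_e = float(np.mean(ref)), float(np.mean(est))
    var_r, var_e = float(np.var(ref)), float(np.var(est))
    cov = float(np.mean((ref - mu_r) * (est - mu_e)))
    return ((2 * mu_r * mu_e + c1) * (2 * cov + c2)) / (
        (mu_r**2 + mu_e**2 + c1) * (var_r + var_e + c2)
    )


def cnr(image: PAImage | np.ndarray, roi: ROISpec) -> float:
    """Contrast-to-noise ratio in dB between target and background ROIs."""
    px = image.pixels if isinstance(image, PAImage) else np.asarray(image, float)
    roi.validate(px.shape)
    inside_vals = np.concatenate(
        [px[i0:i1, j0:j1].ravel() for (i0, i1, j0, j1) in roi.inside]
    )
    o = roi.outside
    outside_vals = px[o[0] : o[1], o[2] : o[3]].ravel()
    s_i = float(np.mean(inside_vals))
    s_o = float(np.mean(outside_vals))
    sigma_o = float(np.std(outside_vals))
    if sigma_o == 0.0:
        raise ValueError("background std is zero; CNR undefined")
    if s_i == s_o:
        return -np.inf
    return 20.0 * np.log10(abs(s_i - s_o) / sigma_o)


def _half_crossing(profile: np.ndarray, peak: int, half: float, step: int) -> float:
    """Fractional index of the half-max crossing nearest the peak."""
    k = peak
    n = profile.shape[0]
    while 0 <= k + step < n:
        nxt = k + step
        if profile[nxt] <= half:
            # linear interpolation between k and nxt
            frac = (profile[k] - half) / (profile[k] - profile[nxt])
            return k + step * frac
        k = nxt
    raise ValueError("profile has no half-maximum crossing on one side")


def fwhm(profile: np.ndarray, spacing: float = 1.0) -> float:
    """Full width at half maximum of a single-peaked profile."""
    p = np.asarray(profile, dtype=np.float64)
    if p.ndim != 1 or p.shape[0] < 3:
        raise ValueError("profile must be 1-D with at least 3 samples")
    peak = int(np.argmax(p))
    if peak == 0 or peak == p.shape[0] - 1:
        raise ValueError("profile peak must lie away from the ends")
    if np.count_nonzero(p == p[peak]) > 1:
        # tied global maxima: take the first, crossings still well defined
        pass
    half = p[peak] / 2.0
    left = _half_crossing(p, peak, half, -1)
    right = _half_crossing(p, peak, half, +1)
    return float((right - left) * spacing)


@dataclasses.dataclass
class MetricsReport:
    """Bundle of image metrics with the ROI definitions used."""

    ssim: float
    cnr_db: float
    fwhm_axial_m: tuple
    fwhm_lateral_m: tuple
    roi: ROISpec | None = None

    def to_json(self) -> str:
        d = {
            "ssim": self.ssim,
            "cnr_db": self.cnr_db,
            "fwhm_axial_m": list(self.fwhm_axial_m),
            "fwhm_lateral_m": list(self.fwhm_lateral_m),
            "roi": json.loads(self.roi.to_json()) if self.roi else None,
        }
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MetricsReport":
        d = json.loads(text)
        roi = None
        if d.get("roi"):
            roi = ROISpec(
                inside=tuple(tuple(r) for r in d["roi"]["inside"]),
                outside=tuple(d["roi"]["outside"]),
            )
        return cls(
            ssim=d["ssim"],
            cnr_db=d["cnr_db"],
            fwhm_axial_m=tuple(d["fwhm_axial_m"]),
            fwhm_lateral_m=tuple(d["fwhm_lateral_m"]),
            roi=roi,
        )


def evaluate_image(
    reference: PAImage,
    estimate: PAImage,
    roi: ROISpec,
    cfg: MetricsConfig | None = None,
) -> MetricsReport:
    """SSIM + CNR + per-target axial/lateral FWHM of ``estimate``.

    FWHM is measured on the depth (column) and lateral (row) cuts through
    the brightest pixel of each target rectangle.
    """
    cfg = cfg or MetricsConfig()
    if reference.pixels.shape != estimate.pixels.shape:
        raise ValueError("reference and estimate images must be aligned")
    px = estimate.pixels
    roi.validate(px.shape)
    ax, lat = [], []
    for (i0, i1, j0, j1) in roi.inside:
        sub = px[i0:i1, j0:j1]
        pi, pj = np.unravel_index(int(np.argmax(sub)), sub.shape)
        pi, pj = pi + i0, pj + j0
        ax.append(fwhm(px[:, pj], estimate.pixel_size))
        lat.append(fwhm(px[pi, :], estimate.pixel_size))
    return MetricsReport(
        ssim=ssim_global(reference.pixels, estimate.pixels, cfg),
        cnr_db=cnr(estimate, roi),
        fwhm_axial_m=tuple(ax),
        fwhm_lateral_m=tuple(lat),
        roi=roi,
    )
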