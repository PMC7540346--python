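"""Zero-phase non-causal recursive high-pass / low-pass filtering.

The denoiser models a channel as ``low-frequency component + sparse
component + white noise`` and needs a high-pass operator H such that the
high-passed residual of (signal − sparse estimate) behaves like the noise.
H must be exactly linear, (near-)symmetric, block constants, and admit fast
application — which the classic recursive zero-phase design provides:

    H(w) = B(w) / A(w),
    B(w) = (2 sin(w/2))^(2d),
    A(w) = B(w) + alpha * (2 cos(w/2))^(2d),

where ``d`` is the half-order and ``alpha`` sets the cutoff.  H has a
2d-order zero at DC, rises monotonically to 1 at Nyquist, and with
``alpha = tan(pi * fc)^(2d)`` has magnitude exactly 1/2 at the cutoff
``fc`` (cycles/sample) — the half-power convention adopted here.

On a finite signal the filter is realized with banded matrices and no
padding (implicit natural boundaries):

    B = F^T F,   F = d-fold first difference  (valid rows only),
    C = G^T G,   G = d-fold first sum,
    A = B + alpha * C   (symmetric positive definite, bandwidth d),

and ``H s = A^{-1} (B s)`` via a cached banded Cholesky solve.  Because F
annihilates polynomials of degree < d, constants (and for d >= 2, linear
trends) are blocked exactly everywhere, including the boundaries.  The
complementary low-pass is ``L = I − H``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg
import scipy.sparse

__all__ = [
    "HighPassFilter",
    "design_highpass",
    "apply_highpass",
    "apply_lowpass",
    "frequency_response",
]


def _binomial_kernel(d: int, sign: int) -> np.ndarray:
    """Coefficients of (1 + sign * z^{-1})^d."""
    k = np.array([1.0])
    for _ in range(d):
        k = np.convolve(k, [1.0, float(sign)])
    return k


def _valid_conv_matrix(kernel: np.ndarray, n: int) -> scipy.sparse.csr_matrix:
    """(n - len(kernel) + 1) x n banded matrix of valid convolution rows."""
    m = n - len(kernel) + 1
    if m < 1:
        raise ValueError("signal too short for the filter order")
    diags = [np.full(m, c) for c in kernel]
    offsets = list(range(len(kernel)))
    return scipy.sparse.diags(diags, offsets, shape=(m, n), format="csr")


def banded_upper(mat: scipy.sparse.spmatrix, bandwidth: int) -> np.ndarray:
    """Extract the upper banded form used by scipy's banded solvers."""
    n = mat.shape[0]
    ab = np.zeros((bandwidth + 1, n))
    for k in range(bandwidth + 1):
        ab[bandwidth - k, k:] = mat.diagonal(k)
    return ab


class _Operators:
    """Banded matrices and factorizations of H for one signal length."""

    def __init__(self, fc: float, d: int, n: int):
        if n <= 4 * d:
            raise ValueError(f"signal length {n} too short; need > {4 * d}")
        f = _binomial_kernel(d, -1)  # (1 - z^{-1})^d
        g = _binomial_kernel(d, +1)  # (1 + z^{-1})^d
        F = _valid_conv_matrix(f, n)
        G = _valid_conv_matrix(g, n)
        alpha = float(np.tan(np.pi * fc) ** (2 * d))
        self.B = (F.T @ F).tocsr()
        self.A = (self.B + alpha * (G.T @ G).tocsr()).tocsr()
        self.alpha = alpha
        self.n = n
        self._A_chol = scipy.linalg.cholesky_banded(
            banded_upper(self.A, d), lower=False
        )

    def solve_A(self, rhs: np.ndarray) -> np.ndarray:
        return scipy.linalg.cho_solve_banded((self._A_chol, False), rhs)

    def highpass(self, s: np.ndarray) -> np.ndarray:
        return self.solve_A(self.B @ s)


@dataclasses.dataclass(frozen=True)
class HighPassFilter:
    """Zero-phase recursive high-pass filter (see module docstring).

    ``fc`` is the half-power cutoff in cycles/sample, ``d`` the half-order
    (the DC zero has order 2d).  Banded operators are built lazily per
    signal length and cached on the instance.
    """

    fc: float
    d: int

    def __post_init__(self) -> None:
        if not (0.0 < self.fc < 0.5):
            raise ValueError(f"fc must lie in (0, 0.5), got {self.fc}")
        if int(self.d) != self.d or self.d < 1:
            raise ValueError(f"half-order d must be an integer >= 1, got {self.d}")
        object.__setattr__(self, "d", int(self.d))
        object.__setattr__(self, "_cache", {})

    def operators(self, n: int) -> _Operators:
        cache = self.__dict__["_cache"]
        if n not in cache:
            cache[n] = _Operators(self.fc, self.d, n)
        return cache[n]


def design_highpass(fc: float, d: int = 2) -> HighPassFilter:
    """Design the zero-phase recursive high-pass with half-power cutoff ``fc``."""
    return HighPassFilter(fc=fc, d=d)


def _check_signal(filt: HighPassFilter, signal: np.ndarray) -> np.ndarray:
    s = np.asarray(signal, dtype=np.float64)
    if s.ndim != 1:
        raise ValueError("signal must be 1-D")
    if s.shape[0] <= 4 * filt.d:
        raise ValueError(
            f"signal length {s.shape[0]} too short for d={filt.d}; need > {4 * filt.d}"
        )
    if not np.all(np.isfinite(s)):
        raise ValueError("signal contains non-finite entries")
    return s


def apply_highpass(filt: HighPassFilter, signal: np.ndarray) -> np.ndarray:
    """High-pass ``signal``; output has the same length as the input."""
    s = _check_signal(filt, signal)
    return filt.operators(s.shape[0]).highpass(s)


def apply_lowpass(filt: HighPassFilter, signal: np.ndarray) -> np.ndarray:
    """Complementary low-pass: ``L = I − H`` exactly."""
    s = _check_signal(filt, signal)
    return s - filt.operators(s.shape[0]).highpass(s)


def frequency_response(filt: HighPassFilter, n: int = 4097) -> tuple:
    """Measured magnitude response of the applied operator.

    Applies the filter to a centered unit impulse of length ``n`` and
    returns ``(freqs_cycles_per_sample, |H|)`` from the DFT of the impulse
    response.  This measures the finite-signal operator itself rather than
    the nominal transfer function.
    """
    imp = np.zeros(n)
    imp[n // 2] = 1.0
    h = apply_highpass(filt, imp)
    H = np.abs(np.fft.rfft(h))
    freqs = np.fft.rfftfreq(n)
    return freqs, H
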