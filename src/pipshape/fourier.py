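"""Harmonic analysis of radial profiles.

A closed curve written as radius r(s) over normalized arc-length
s in [0, 2*pi) has the Fourier series

    r(s) = a_0 + sum_k [ a_k cos(k s) + b_k sin(k s) ]

The shape descriptors are the harmonic *amplitudes* r_k = sqrt(a_k^2 +
b_k^2): invariant to the starting point of the traversal and to its
direction, which signed (a, b) pairs are not. r_0 = a_0 is the mean radius
and carries the absolute size; r_1 is driven to zero upstream by the
origin choice; r_2 measures the ellipse-like eccentricity of the curve and
r_3..r_7 progressively finer deformations. The retained descriptor is
(r0, r2, ..., r7). Phases are kept internally only for truncated
reconstruction of curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .curves import PlanarCurve, RadialProfile
from .errors import OriginNotAdjustedError, ParameterError

#: harmonic indices retained in the descriptor (r1 excluded by construction)
RETAINED_HARMONICS = (0, 2, 3, 4, 5, 6, 7)

DEFAULT_K = 32


@dataclass
class Spectrum:
    """Cosine/sine coefficients of one radial profile up to harmonic K."""

    a: np.ndarray  # (K+1,) cosine coefficients, a[0] = mean radius
    b: np.ndarray  # (K+1,) sine coefficients, b[0] = 0 by convention
    K: int
    n_samples: int
    plane_id: str = ""

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.K < 8:
            raise ParameterError("spectrum needs K >= 8")
        if len(self.a) != self.K + 1 or len(self.b) != self.K + 1:
            raise ParameterError("coefficient arrays must have length K+1")
        if not (np.isfinite(self.a).all() and np.isfinite(self.b).all()):
            raise ParameterError("non-finite Fourier coefficients")
        if self.a[0] <= 0:
            raise ParameterError("mean radius a_0 must be positive")

    def amplitudes(self) -> np.ndarray:
        """r_k = sqrt(a_k^2 + b_k^2) for k = 0..K."""
        return np.hypot(self.a, self.b)


@dataclass
class FourierDescriptor:
    """The retained per-curve descriptor (r0, r2..r7), millimetres."""

    r0: float
    amplitudes: np.ndarray  # (6,) r2..r7
    plane_id: str = ""

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.r0 <= 0:
            raise ParameterError("r0 must be positive")
        if len(self.amplitudes) != 6 or np.any(self.amplitudes < 0):
            raise ParameterError("descriptor needs 6 non-negative amplitudes")

    def values(self) -> np.ndarray:
        """The 7-vector (r0, r2, r3, r4, r5, r6, r7)."""
        return np.concatenate([[self.r0], self.amplitudes])


def spectrum(profile: RadialProfile, K: int = DEFAULT_K) -> Spectrum:
    """Discrete Fourier analysis of the radius samples over one period.

    With N uniform samples, a_0 is the sample mean and for k >= 1
    a_k = (2/N) sum r_j cos(k s_j), b_k = (2/N) sum r_j sin(k s_j);
    Parseval then gives sum_j (r_j - a_0)^2 / N = sum_k (a_k^2+b_k^2)/2
    up to the energy beyond harmonic K.
    """
    n = profile.n_samples
    if not 1 <= K < n // 2:
        raise ParameterError(f"K must satisfy 1 <= K < N/2 (N={n})")
    fft = np.fft.rfft(profile.radii)
    a = np.empty(K + 1)
    b = np.zeros(K + 1)
    a[0] = fft[0].real / n
    a[1:] = 2.0 * fft[1 : K + 1].real / n
    b[1:] = -2.0 * fft[1 : K + 1].imag / n
    return Spectrum(a=a, b=b, K=K, n_samples=n, plane_id=profile.plane_id)


def descriptor(spec: Spectrum) -> FourierDescriptor:
    """Retain (r0, r2..r7); requires the origin-adjusted precondition."""
    amps = spec.amplitudes()
    if amps[1] >= 1e-6 * spec.a[0] * (1 + 1e-9):
        raise OriginNotAdjustedError(
            f"{spec.plane_id}: first harmonic {amps[1]:.3e} not vanished "
            f"relative to r0 {spec.a[0]:.3e}; adjust the profile origin first"
        )
    return FourierDescriptor(
        r0=float(spec.a[0]), amplitudes=amps[2:8], plane_id=spec.plane_id
    )


def reconstruct_radii(
    spec: Spectrum, keep: Iterable[int] = RETAINED_HARMONICS, n_samples: int | None = None
) -> np.ndarray:
    """Inverse synthesis of r(s) using only the kept harmonics."""
    keep = sorted(set(int(k) for k in keep))
    if any(k < 0 or k > spec.K for k in keep):
        raise ParameterError("kept harmonics must lie in [0, K]")
    n = n_samples or spec.n_samples
    s = 2.0 * np.pi * np.arange(n) / n
    r = np.zeros(n)
    for k in keep:
        if k == 0:
            r += spec.a[0]
        else:
            r += spec.a[k] * np.cos(k * s) + spec.b[k] * np.sin(k * s)
    return r


def reconstruct(
    spec: Spectrum,
    keep: Iterable[int] = RETAINED_HARMONICS,
    n_samples: int | None = None,
) -> PlanarCurve:
    """Truncated curve for side-by-side display with the original outline.

    The radius series is laid out polar-wise with the arc-length parameter
    as the angle; for near-circular outlines this is visually faithful, and
    the radius-space residual obeys Parseval bookkeeping exactly.
    """
    r = reconstruct_radii(spec, keep, n_samples)
    s = 2.0 * np.pi * np.arange(len(r)) / len(r)
    pts = np.column_stack([r * np.cos(s), r * np.sin(s)])
    return PlanarCurve(points=pts, plane_id=spec.plane_id or "reconstruction")


def spectrum_to_frame(spec: Spectrum) -> np.ndarray:
    """CSV-ready (k, a_k, b_k, amplitude) rows."""
    amps = spec.amplitudes()
    k = np.arange(spec.K + 1)
    return np.column_stack([k, spec.a, spec.b, amps])
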