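"""Hilbert spiral transform phase demodulation.

A zero-mean fringe pattern ``b*cos(theta)`` has quadrature ``b*sin(theta)``.
In 2D this quadrature is produced by the spiral (vortex) Fourier multiplier
``SPF(u, v) = (u + i v)/sqrt(u^2 + v^2)`` combined with the local fringe
direction beta:

    AFP = b*cos(theta) - i * exp(-i*beta) * F^-1{ SPF * F[b*cos(theta)] }

The angle of this analytic fringe pattern is the wrapped phase; a 2D
unwrapper and least-squares plane removal complete the demodulation.  For
off-axis interferograms the classical Fourier-transform method (filter one
cross-correlation lobe, shift it to DC) is the 1D simplification of the
same relation and serves as the reference baseline here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.restoration import unwrap_phase as _unwrap2d

__all__ = [
    "AnalyticFringePattern",
    "spiral_phase_function",
    "hilbert_spiral_transform",
    "analytic_signal",
    "wrapped_phase",
    "unwrap_phase",
    "lsq_unwrap",
    "congruence_repair",
    "remove_plane",
    "count_residues",
    "ft_demodulate",
]


@dataclass
class AnalyticFringePattern:
    """Complex analytic fringe pattern: fringes + i*quadrature."""

    real: np.ndarray  # the (filtered) fringes, bitwise the input
    imag: np.ndarray  # spiral-transform quadrature
    direction_used: np.ndarray | None = None

    @property
    def complex(self) -> np.ndarray:
        return self.real + 1j * self.imag


def spiral_phase_function(shape: tuple[int, int]) -> np.ndarray:
    """Spiral phase Fourier multiplier on the fft-ordered frequency grid.

    ``SPF = (u + i v)/sqrt(u^2 + v^2)`` with u along columns (x) and v
    along rows (y); unit modulus everywhere except DC, which is nulled by
    convention (benign for zero-mean fringes).  For even sizes the Nyquist
    frequency sits in the negative half (numpy fftfreq convention).
    """
    if len(shape) != 2 or shape[0] < 2 or shape[1] < 2:
        raise ValueError("shape must be at least 2x2")
    v = np.fft.fftfreq(shape[0])[:, None]
    u = np.fft.fftfreq(shape[1])[None, :]
    rho = np.hypot(u, v)
    with np.errstate(invalid="ignore", divide="ignore"):
        spf = (u + 1j * v) / rho
    spf[0, 0] = 0.0
    return spf


def _mirror_pad(f: np.ndarray) -> np.ndarray:
    return np.pad(f, ((0, f.shape[0]), (0, f.shape[1])), mode="symmetric")


def _spiral_convolve(fringes: np.ndarray, pad: bool) -> np.ndarray:
    """F^-1{ SPF * F[f] }, optionally on a mirror-padded 2x grid."""
    f = np.asarray(fringes, dtype=float)
    work = _mirror_pad(f) if pad else f
    spec = np.fft.fft2(work)
    out = np.fft.ifft2(spiral_phase_function(work.shape) * spec)
    if pad:
        out = out[: f.shape[0], : f.shape[1]]
    return out


def hilbert_spiral_transform(fringes: np.ndarray, beta, pad: bool = True) -> np.ndarray:
    """Direction-guided quadrature of a zero-mean fringe pattern.

    Returns ``Re[-i * exp(-i*beta) * F^-1{SPF * F[fringes]}]`` — the
    real-valued fringe signal in quadrature to the input (vortex
    demodulation convention).  Linear in the fringes for fixed beta.
    Mirror-padding to twice the size (default) suppresses
    periodic-extension ringing at the borders.
    """
    f = np.asarray(fringes, dtype=float)
    b = np.asarray(getattr(beta, "angles", beta), dtype=float)
    if np.ndim(b) == 0:
        b = np.full(f.shape, float(b))
    if b.shape != f.shape:
        raise ValueError(f"beta shape {b.shape} does not match fringes {f.shape}")
    spiral = _spiral_convolve(f, pad=pad)
    return np.real(-1j * np.exp(-1j * b) * spiral)


def analytic_signal(fringes: np.ndarray, beta, pad: bool = True) -> AnalyticFringePattern:
    """Assemble the complex analytic fringe pattern from fringes and beta."""
    f = np.asarray(fringes, dtype=float)
    quad = hilbert_spiral_transform(f, beta, pad=pad)
    return AnalyticFringePattern(
        real=f, imag=quad, direction_used=np.asarray(getattr(beta, "angles", beta))
    )


def wrapped_phase(afp: AnalyticFringePattern | np.ndarray) -> np.ndarray:
    """Four-quadrant angle of the analytic signal, in (-pi, pi].

    Zero-magnitude pixels map to phase 0.
    """
    z = afp.complex if isinstance(afp, AnalyticFringePattern) else np.asarray(afp)
    if not np.all(np.isfinite(z)):
        raise ValueError("analytic signal must be finite")
    phi = np.angle(z)
    # numpy returns -pi for the negative real axis; the convention here is +pi
    phi = np.where(phi == -math.pi, math.pi, phi)
    return phi


def _wrap(d: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * d))


def lsq_unwrap(wrapped: np.ndarray, congruent: bool = True) -> np.ndarray:
    """Least-squares (Poisson/DCT) 2D phase unwrapping.

    Solves the discrete Poisson equation whose source is the divergence of
    the wrapped phase gradients, with Neumann boundaries (cosine
    transform).  Exact (up to a constant) whenever the wrapped gradient
    field is curl-free, i.e. on residue-free inputs.  With ``congruent``
    the smooth solution is snapped back onto the input modulo 2*pi, so
    rewrapping reproduces the input exactly; without it, residue-rich
    inputs yield the smooth minimum-norm surface instead.
    """
    from scipy.fft import dctn, idctn

    w = np.asarray(wrapped, dtype=float)
    h, wd = w.shape
    dx = np.zeros_like(w)
    dy = np.zeros_like(w)
    dx[:, :-1] = _wrap(w[:, 1:] - w[:, :-1])
    dy[:-1, :] = _wrap(w[1:, :] - w[:-1, :])
    rho = np.zeros_like(w)
    rho[:, 0] += dx[:, 0]
    rho[:, 1:] += dx[:, 1:] - dx[:, :-1]
    rho[0, :] += dy[0, :]
    rho[1:, :] += dy[1:, :] - dy[:-1, :]
    d = dctn(rho, norm="ortho")
    yy, xx = np.mgrid[0:h, 0:wd]
    denom = 2.0 * (np.cos(math.pi * xx / wd) + np.cos(math.pi * yy / h) - 2.0)
    denom[0, 0] = 1.0
    u = d / denom
    u[0, 0] = 0.0
    u = idctn(u, norm="ortho")
    u += (w - u).mean()
    if congruent:
        u = u + _wrap(w - u)
    return u


def congruence_repair(
    unwrapped: np.ndarray, size: tuple[int, int] = (13, 13), iters: int = 3
) -> np.ndarray:
    """Snap 2*pi-outlier pixels back to their local median sheet.

    Pixels sitting a near-multiple of 2*pi away from the median of their
    neighbourhood (unwrapper branch-cut leftovers) are shifted by that
    multiple; all corrections are exact 2*pi multiples, so congruence with
    the wrapped input is preserved.
    """
    from scipy.ndimage import median_filter

    u = np.asarray(unwrapped, dtype=float).copy()
    for _ in range(iters):
        med = median_filter(u, size=size, mode="mirror")
        k = np.round((u - med) / (2.0 * math.pi))
        if not k.any():
            break
        u -= 2.0 * math.pi * k
    return u


def unwrap_phase(wrapped: np.ndarray, method: str = "lsq", repair: bool = True) -> np.ndarray:
    """2D phase unwrapping.

    ``method="lsq"`` (default) is the congruent least-squares unwrapper
    with 2*pi-congruence repair — robust against long branch cuts around
    low-quality contours; ``method="quality"`` is the ecosystem's
    quality-guided network unwrapper.  Either way, rewrapping the result
    reproduces the input modulo 2*pi, and on residue-free inputs the
    unwrap is exact up to a 2*pi*k offset.
    """
    w = np.asarray(wrapped, dtype=float)
    if method == "quality":
        return np.asarray(_unwrap2d(w))
    if method != "lsq":
        raise ValueError(f"unknown unwrap method {method!r}")
    u = lsq_unwrap(w, congruent=True)
    if repair:
        u = congruence_repair(u)
    return u


def count_residues(wrapped: np.ndarray) -> int:
    """Number of nonzero 2x2 loop residues in a wrapped phase map."""
    w = np.asarray(wrapped, dtype=float)

    def wrap(d):
        return np.angle(np.exp(1j * d))

    d1 = wrap(w[:-1, 1:] - w[:-1, :-1])
    d2 = wrap(w[1:, 1:] - w[:-1, 1:])
    d3 = wrap(w[1:, :-1] - w[1:, 1:])
    d4 = wrap(w[:-1, :-1] - w[1:, :-1])
    loop = d1 + d2 + d3 + d4
    return int(np.count_nonzero(np.abs(loop) > math.pi))


def _plane_fit(phase: np.ndarray) -> tuple[float, float, float]:
    """Least-squares piston + tilt coefficients (c, ax, ay)."""
    h, wd = phase.shape
    y, x = np.mgrid[0:h, 0:wd].astype(float)
    A = np.column_stack([np.ones(phase.size), x.ravel(), y.ravel()])
    coef, *_ = np.linalg.lstsq(A, phase.ravel(), rcond=None)
    return float(coef[0]), float(coef[1]), float(coef[2])


def remove_plane(phase: np.ndarray) -> np.ndarray:
    """Subtract the least-squares plane (piston + tilt); idempotent."""
    p = np.asarray(phase, dtype=float)
    c, ax, ay = _plane_fit(p)
    h, wd = p.shape
    y, x = np.mgrid[0:h, 0:wd].astype(float)
    return p - (c + ax * x + ay * y)


def ft_demodulate(
    interferogram: np.ndarray,
    filter_center: tuple[float, float] | None = None,
    filter_radius: float | None = None,
) -> np.ndarray:
    """Classical Fourier-transform demodulation (off-axis baseline).

    A circular mask of ``filter_radius`` spectral pixels is applied around
    ``filter_center`` (offset from DC, in spectral pixels, (u, v) = (along
    x, along y)); the lobe is shifted to DC, inverse transformed, and the
    angle is unwrapped and plane-corrected.  When no centre is given, the
    strongest spectral peak outside a small DC guard is used.  A mask
    touching DC triggers an "autocorrelation leakage" warning — the
    resolution/error trade-off of the method.
    """
    img = np.asarray(interferogram, dtype=float)
    h, wd = img.shape
    spec = np.fft.fftshift(np.fft.fft2(img - img.mean()))
    cy, cx = h // 2, wd // 2
    if filter_center is None:
        mag = np.abs(spec).copy()
        yy, xx = np.mgrid[0:h, 0:wd]
        guard = np.hypot(xx - cx, yy - cy) <= max(3, min(h, wd) // 64)
        mag[guard] = 0.0
        mag[:, :cx] = 0.0  # one half-plane: pick the +u lobe
        iy, ix = np.unravel_index(int(np.argmax(mag)), mag.shape)
        filter_center = (ix - cx, iy - cy)
    u0, v0 = filter_center
    if filter_radius is None:
        filter_radius = max(4.0, 0.5 * math.hypot(u0, v0))
    if math.hypot(u0, v0) <= filter_radius:
        warnings.warn("autocorrelation leakage: filter mask touches DC", stacklevel=2)
    yy, xx = np.mgrid[0:h, 0:wd]
    mask = np.hypot(xx - (cx + u0), yy - (cy + v0)) <= filter_radius
    lobe = np.where(mask, spec, 0.0)
    # shift the carrier lobe to DC
    lobe = np.roll(lobe, (-int(round(v0)), -int(round(u0))), axis=(0, 1))
    field = np.fft.ifft2(np.fft.ifftshift(lobe))
    phi = unwrap_phase(np.angle(field))
    return remove_plane(phi)
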