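"""Local fringe direction estimation.

The spiral-transform demodulator needs, at every pixel, the angle beta of
the normal to the local fringe measured from the +x axis, modulo 2*pi.
It is built in three steps:

1. orientation (modulo pi) from a combined gradient / plane-fitting
   estimator over a small w x w window;
2. orientation unwrapping to a direction map (modulo 2*pi) via angle
   doubling, 2D phase unwrapping and halving;
3. sine–cosine smoothing: filter sin(beta) and cos(beta) by iteratively
   removing their locally highest-frequency detail, then recombine with
   atan2.

The pi-ambiguity of the orientation is intrinsic (a cosine fringe looks the
same upside down); step 2 resolves it locally, while the remaining *global*
sign (beta vs beta+pi, i.e. phase elevation vs depression) is fixed only by
convention — here the circular mean of beta is kept in the right half-plane,
and carrier-bearing pipelines re-anchor it from the demodulated carrier
ramp.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.restoration import unwrap_phase as _unwrap2d

__all__ = [
    "OrientationMap",
    "DirectionMap",
    "estimate_orientation",
    "unwrap_orientation",
    "sincos_filter",
    "circular_rms",
    "direction_from_phase",
    "anchor_direction_sign",
]


@dataclass
class OrientationMap:
    """Local fringe orientation, modulo pi, with a validity mask.

    ``quality`` combines the plane-fit gradient magnitude with the
    structure-tensor coherence; it weights the orientation during
    disambiguation so that fringe crests and fold lines (degenerate,
    noise-dominated) do not steer the unwrapping.
    """

    angles: np.ndarray  # radians in [0, pi)
    validity: np.ndarray  # bool raster
    window: int  # plane-fit window size, odd, 3..13
    quality: np.ndarray | None = None


@dataclass
class DirectionMap:
    """Local fringe direction beta, modulo 2*pi."""

    angles: np.ndarray  # radians in [0, 2*pi)
    window: int
    validity: np.ndarray | None = None


def _as_angles(direction) -> np.ndarray:
    return np.asarray(getattr(direction, "angles", direction), dtype=float)


def _mod_fold(angles: np.ndarray, period: float) -> np.ndarray:
    """np.mod that never returns the period itself (rounding artifact)."""
    r = np.mod(angles, period)
    return np.where(r >= period, 0.0, r)


def _fill_invalid(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid pixels by their nearest valid neighbour."""
    if valid.all():
        return values
    if not valid.any():
        return values
    idx = ndimage.distance_transform_edt(~valid, return_distances=False, return_indices=True)
    return values[tuple(idx)]


def estimate_orientation(fringes: np.ndarray, w: int) -> OrientationMap:
    """Local fringe orientation (mod pi) by gradient + plane fitting.

    A plane is least-squares fitted to the intensities of each w x w
    neighbourhood; its gradient is the local fringe normal.  The per-pixel
    plane gradients are then averaged as a structure tensor over the same
    window, whose principal direction gives a noise-robust orientation in
    [0, pi).  Pixels whose plane-fit gradient magnitude is degenerate
    (below 1e-6 of the dynamic range) are flagged invalid.
    """
    f = np.asarray(fringes, dtype=float)
    if f.ndim != 2:
        raise ValueError("fringes must be a 2D raster")
    if w % 2 == 0 or not (3 <= w <= 13):
        raise ValueError("window must be odd and within [3, 13]")
    rng = float(np.ptp(f))
    if rng == 0.0:
        raise ValueError("no fringes: gradient everywhere degenerate")

    # LS plane fit over the window reduces to correlation with ramp kernels
    half = w // 2
    ramp = np.arange(-half, half + 1, dtype=float)
    norm = float(np.sum(ramp**2)) * w
    kx = np.tile(ramp, (w, 1)) / norm  # slope along x (columns)
    ky = kx.T
    gx = ndimage.correlate(f, kx, mode="mirror")
    gy = ndimage.correlate(f, ky, mode="mirror")

    mag = np.hypot(gx, gy)
    valid = mag > 1e-6 * rng
    if not valid.any():
        raise ValueError("no fringes: gradient everywhere degenerate")

    # structure tensor of the plane-fit gradients, averaged over the window
    sxx = ndimage.uniform_filter(gx * gx, size=w, mode="mirror")
    syy = ndimage.uniform_filter(gy * gy, size=w, mode="mirror")
    sxy = ndimage.uniform_filter(gx * gy, size=w, mode="mirror")
    theta = 0.5 * np.arctan2(2.0 * sxy, sxx - syy)  # (-pi/2, pi/2]
    theta = _mod_fold(theta, math.pi)
    theta = _fill_invalid(theta, valid)
    trace = sxx + syy
    anis = np.sqrt((sxx - syy) ** 2 + 4.0 * sxy**2)
    coherence = np.where(trace > 1e-30, anis / np.maximum(trace, 1e-30), 0.0)
    quality = mag * coherence
    return OrientationMap(angles=theta, validity=valid, window=w, quality=quality)


def unwrap_orientation(orientation: OrientationMap, smoothing: float = 8.0) -> DirectionMap:
    """Resolve the pi-ambiguity: orientation (mod pi) -> direction (mod 2*pi).

    The classical reduction — double the angles (a continuous mod-2*pi
    field), 2D-unwrap them, halve — is applied to a quality-weighted
    complex-smoothed orientation field (Gaussian of ``exp(2i*theta)``,
    scale ``smoothing`` px), and the resulting half-turn flips are then
    transferred to the full-resolution orientation.  The smoothing bridges
    fringe crests and other degenerate bands whose orientation is noise-
    dominated and which otherwise seed large spurious flip domains;
    ``smoothing=0`` recovers the raw per-pixel doubling scheme.

    Invalid pixels are filled from their nearest valid neighbour first.
    The global half-turn is fixed by the convention that the circular mean
    of beta lies in the right half-plane (mean cos(beta) >= 0); for fringes
    with no net x-facing this anchor is neutral and the conjugate ambiguity
    remains, as it must for single-shot data.
    """
    valid = orientation.validity
    if valid is not None and valid.mean() <= 0.5:
        raise ValueError("orientation validity below 50%: cannot unwrap reliably")
    ang = _fill_invalid(orientation.angles, valid) if valid is not None else orientation.angles

    if smoothing and smoothing > 0:
        weight = orientation.quality if orientation.quality is not None else np.ones_like(ang)
        z = weight * np.exp(2j * ang)
        zs = ndimage.gaussian_filter(z.real, smoothing, mode="mirror") + 1j * ndimage.gaussian_filter(
            z.imag, smoothing, mode="mirror"
        )
        doubled = np.angle(zs)  # (-pi, pi]
    else:
        doubled = np.angle(np.exp(2j * ang))
    unwrapped = np.asarray(_unwrap2d(doubled))
    coarse = unwrapped / 2.0
    # transfer the half-turn decision to the full-resolution orientation
    flip = np.abs(np.angle(np.exp(1j * (ang - coarse)))) > math.pi / 2
    beta = _mod_fold(np.where(flip, ang + math.pi, ang), 2.0 * math.pi)
    if np.cos(beta).mean() < 0.0:
        beta = _mod_fold(beta + math.pi, 2.0 * math.pi)
    return DirectionMap(angles=beta, window=orientation.window, validity=valid)


def _detail(img: np.ndarray) -> np.ndarray:
    """Locally highest-frequency component: img minus median3+Gaussian smooth."""
    smooth = ndimage.gaussian_filter(
        ndimage.median_filter(img, size=3, mode="mirror"), sigma=1.0, mode="mirror"
    )
    return img - smooth


def sincos_filter(direction: DirectionMap, n_modes: int = 3) -> DirectionMap:
    """Smooth a direction map through its sine and cosine.

    sin(beta) and cos(beta) are filtered by removing their first
    ``n_modes`` highest-spatial-frequency empirical detail components
    (iterative median3+Gaussian residual removal, the mode-elimination
    step of bidimensional empirical decompositions), then recombined as
    atan2(sin_f, cos_f) mod 2*pi.  Working on the sine/cosine pair avoids
    smearing across the 0/2*pi seam.
    """
    beta = _as_angles(direction)
    s = np.sin(beta)
    c = np.cos(beta)
    for _ in range(max(int(n_modes), 0)):
        s = s - _detail(s)
        c = c - _detail(c)
    out = _mod_fold(np.arctan2(s, c), 2.0 * math.pi)
    w = getattr(direction, "window", 0)
    return DirectionMap(angles=out, window=w, validity=getattr(direction, "validity", None))


def direction_from_phase(phase: np.ndarray, sigma: float = 2.0, window: int = 0) -> DirectionMap:
    """Direction map from the gradient of an (estimated) unwrapped phase.

    beta = atan2(d(phi)/dy, d(phi)/dx) mod 2*pi of the Gaussian-smoothed
    phase.  Used to refine a direction estimate from a provisional
    demodulation: the phase gradient carries the fringe normal with its
    sign already resolved, including across fold lines where local
    orientation estimators are blind.
    """
    p = ndimage.gaussian_filter(np.asarray(phase, dtype=float), sigma, mode="mirror")
    gy, gx = np.gradient(p)
    beta = _mod_fold(np.arctan2(gy, gx), 2.0 * math.pi)
    return DirectionMap(angles=beta, window=window)


def circular_rms(a, b, align_halfturn: bool = False) -> float:
    """RMS of the pointwise angular difference wrapped to (-pi, pi].

    With ``align_halfturn`` the better of the two global half-turn
    alignments (offset 0 or pi) is scored, discounting the conjugate-phase
    ambiguity inherent to single-shot direction estimation.
    """
    da = _as_angles(a) - _as_angles(b)
    if da.size == 0:
        raise ValueError("empty direction maps")
    wrapped = np.angle(np.exp(1j * da))
    rms = float(np.sqrt(np.mean(wrapped**2)))
    if align_halfturn:
        flipped = np.angle(np.exp(1j * (da + math.pi)))
        rms = min(rms, float(np.sqrt(np.mean(flipped**2))))
    return rms


def anchor_direction_sign(fringes: np.ndarray, direction: DirectionMap) -> DirectionMap:
    """Fix the global half-turn of beta from the demodulated carrier ramp.

    For carrier-bearing fringes the demodulated phase must increase along
    +x.  The quadrature is computed once with the candidate beta; if the
    circular mean of the x-difference of the resulting wrapped phase is
    negative, beta is shifted by pi.  Carrier-free inputs (near-zero mean
    ramp) are returned unchanged — their sign is genuinely ambiguous.
    """
    from .hst_demod import hilbert_spiral_transform

    beta = _as_angles(direction)
    quad = hilbert_spiral_transform(fringes, beta)
    phi = np.angle(np.asarray(fringes) + 1j * quad)
    dphi = np.angle(np.exp(1j * np.diff(phi, axis=1)))
    mean_ramp = float(dphi.mean())
    if mean_ramp < -1e-3:
        beta = _mod_fold(beta + math.pi, 2.0 * math.pi)
        return DirectionMap(angles=beta, window=direction.window, validity=direction.validity)
    if abs(mean_ramp) <= 1e-3:
        warnings.warn(
            "carrier-free fringes: global direction sign (conjugate phase) is ambiguous",
            stacklevel=2,
        )
    return direction
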