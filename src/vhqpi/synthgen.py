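"""Synthetic interferogram generation.

Ground-truth phantoms for exercising the full demodulation chain without
experimental data.  The phase object is the Evans–Skalak closed-form height
profile of an unstressed red blood cell; interferograms follow the two-beam
model ``I = a + b*cos(theta) + n`` with a straight-line carrier of period
``T`` pixels along x, an optional Gaussian incoherent background and seeded
additive Gaussian noise.

Coordinate convention: origin at the raster corner, ``x`` is the column
index and ``y`` the row index, both 0-based.  All phases are in radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FringeModel",
    "RBCPhantomParams",
    "SyntheticSpec",
    "rbc_height",
    "rbc_phase",
    "generate_interferogram",
    "ideal_direction",
    "aberration_background",
]


@dataclass
class FringeModel:
    """Additive ground-truth decomposition of a two-beam interferogram.

    The composed intensity is ``background + amplitude*cos(theta) + noise``
    at every pixel, exactly.
    """

    background: np.ndarray
    amplitude: np.ndarray
    theta: np.ndarray
    noise: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.background, self.amplitude, self.theta, self.noise)}
        if len(shapes) != 1:
            raise ValueError("all FringeModel rasters must share one shape")
        if np.any(self.amplitude < 0):
            raise ValueError("fringe amplitude must be non-negative")

    def compose(self) -> np.ndarray:
        """Recompose the intensity raster from the three terms."""
        return self.background + self.amplitude * np.cos(self.theta) + self.noise


@dataclass
class RBCPhantomParams:
    """Evans–Skalak red-blood-cell shape parameters.

    ``D0`` is the cell diameter in micrometres; ``a0, a1, a2`` are the
    dimensionless shape constants of the unstressed-cell model.  The height
    is real only inside the support disk ``x^2 + y^2 <= (D0/2)^2``; outside
    it the cell is taken to sit on a flat substrate (height 0).
    """

    D0: float = 7.82
    a0: float = 0.0518
    a1: float = 2.0026
    a2: float = -4.491
    pixel_pitch: float | None = None  # um per pixel; None -> cell spans 1/3 of the grid
    center: tuple[float, float] = (0.0, 0.0)  # (x, y) offset in um from grid centre

    def __post_init__(self) -> None:
        if not (np.isfinite(self.D0) and self.D0 > 0):
            raise ValueError("D0 must be a positive finite diameter")

    def resolve_pitch(self, grid_size: int) -> float:
        """Pixel pitch in um/px; default makes the cell span grid_size/3 px."""
        if self.pixel_pitch is not None:
            return float(self.pixel_pitch)
        return 3.0 * self.D0 / grid_size


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic interferogram.

    ``period`` is the straight carrier period in pixels along x; ``np.inf``
    means carrier-free.  Finite periods below 4 px are rejected (Nyquist
    floor).  ``noise_amp`` scales a seeded unit-variance Gaussian raster.
    ``background`` is ``None`` or ``("gaussian", amplitude, sigma_px)``;
    the shorthand ``"gaussian"`` uses amplitude 1.0 and sigma = size/3.
    """

    size: int = 512
    period: float = 20.0
    phase_scale: float = 5.0
    noise_amp: float = 0.05
    background: str | tuple | None = None
    seed: int = 0
    params: RBCPhantomParams = field(default_factory=RBCPhantomParams)

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError("grid size must be at least 32 px")
        if np.isfinite(self.period) and self.period < 4:
            raise ValueError("carrier beyond Nyquist floor: period must be >= 4 px (or inf)")

    def background_raster(self) -> np.ndarray:
        """Evaluate the configured incoherent background on the grid."""
        n = self.size
        if self.background is None or self.background == "none":
            return np.zeros((n, n))
        if self.background == "gaussian":
            amp, sigma = 1.0, n / 3.0
        else:
            kind, amp, sigma = self.background
            if kind != "gaussian":
                raise ValueError(f"unknown background kind: {kind!r}")
        y, x = np.mgrid[0:n, 0:n].astype(float)
        c = (n - 1) / 2.0
        return amp * np.exp(-(((x - c) ** 2 + (y - c) ** 2) / (2.0 * sigma**2)))


def rbc_height(x, y, params: RBCPhantomParams | None = None) -> np.ndarray | float:
    """Evans–Skalak height z(x, y) of the unstressed red blood cell, in um.

    ``x`` and ``y`` are micrometre coordinates measured from the cell
    centre.  Outside the support disk (``x^2+y^2 > (D0/2)^2``) the height
    is 0 by convention.

    Parameters
    ----------
    x, y : float or ndarray
        Coordinates in micrometres.
    params : RBCPhantomParams, optional
        Shape constants; defaults are the standard unstressed-cell values.
    """
    if params is None:
        params = RBCPhantomParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("rbc_height requires finite coordinates")
    r2 = x**2 + y**2
    d2 = params.D0**2
    inside = r2 <= d2 / 4.0
    r2c = np.where(inside, r2, 0.0)  # keep sqrt real; masked out below
    z = (
        params.D0
        * np.sqrt(1.0 - 4.0 * r2c / d2)
        * (params.a0 + params.a1 * r2c / d2 + params.a2 * r2c**2 / d2**2)
    )
    z = np.where(inside, z, 0.0)
    if z.ndim == 0:
        return float(z)
    return z


def rbc_phase(
    grid_size: int,
    spec: SyntheticSpec | None = None,
    params: RBCPhantomParams | None = None,
) -> np.ndarray:
    """Sample ``phase_scale * z`` on the pixel grid (radians).

    The cell is centred on the raster (plus any ``params.center`` offset in
    um) and spans one third of the field unless an explicit pixel pitch is
    given.
    """
    if grid_size < 32:
        raise ValueError("grid size must be at least 32 px")
    if spec is None:
        spec = SyntheticSpec(size=grid_size)
    if params is None:
        params = spec.params
    pitch = params.resolve_pitch(grid_size)
    c = (grid_size - 1) / 2.0
    y, x = np.mgrid[0:grid_size, 0:grid_size].astype(float)
    xu = (x - c) * pitch - params.center[0]
    yu = (y - c) * pitch - params.center[1]
    return spec.phase_scale * np.asarray(rbc_height(xu, yu, params))


def carrier_ramp(size: int, period: float) -> np.ndarray:
    """Linear carrier phase 2*pi*x/T on the grid; zero if T is infinite."""
    x = np.arange(size, dtype=float)
    if np.isinf(period):
        ramp = np.zeros(size)
    else:
        ramp = 2.0 * math.pi * x / period
    return np.broadcast_to(ramp, (size, size)).copy()


def generate_interferogram(
    spec: SyntheticSpec, phase: np.ndarray
) -> tuple[np.ndarray, FringeModel]:
    """Compose ``I = a + cos(phase + 2*pi*x/T) + noise_amp*G`` and its truth.

    ``G`` is a standard-normal raster drawn from ``default_rng(spec.seed)``;
    the same seed yields a bit-identical interferogram.  Returns the
    intensity raster together with the exact :class:`FringeModel`
    decomposition used to build it.
    """
    phase = np.asarray(phase, dtype=float)
    if phase.shape != (spec.size, spec.size):
        raise ValueError(
            f"phase shape {phase.shape} does not match spec size {spec.size}"
        )
    theta = phase + carrier_ramp(spec.size, spec.period)
    background = spec.background_raster()
    rng = np.random.default_rng(spec.seed)
    noise = spec.noise_amp * rng.standard_normal(phase.shape)
    model = FringeModel(
        background=background,
        amplitude=np.ones_like(phase),
        theta=theta,
        noise=noise,
    )
    return model.compose(), model


def ideal_direction(spec: SyntheticSpec, phase: np.ndarray):
    """Ground-truth fringe direction map from the known total phase.

    beta = atan2(d(theta)/dy, d(theta)/dx) mod 2*pi — the angle of the local
    fringe normal versus the +x axis, computed by central finite differences
    of theta = phase + carrier.  Pixels with (numerically) zero gradient are
    filled from the nearest valid neighbour and flagged in the validity
    mask.
    """
    from .fringe_direction import DirectionMap, _fill_invalid

    phase = np.asarray(phase, dtype=float)
    theta = phase + carrier_ramp(phase.shape[1], spec.period)[: phase.shape[0], : phase.shape[1]]
    gy, gx = np.gradient(theta)
    mag = np.hypot(gx, gy)
    valid = mag > 1e-12 * max(1.0, float(np.ptp(theta)))
    beta = np.mod(np.arctan2(gy, gx), 2.0 * math.pi)
    if not valid.all():
        beta = _fill_invalid(beta, valid)
    return DirectionMap(angles=beta, window=0, validity=valid)


def aberration_background(grid_size: int, coeffs: dict[tuple[int, int], float]) -> np.ndarray:
    """Low-order bivariate polynomial phase background (radians).

    ``coeffs`` maps ``(i, j)`` exponent pairs to coefficients of
    ``x^i * y^j`` evaluated on coordinates normalised to [-1, 1] across the
    grid (so a coefficient is the radian amplitude of its term at the field
    edge).  Total order ``i + j`` is limited to 4.  Used to contaminate
    phantoms for aberration-correction tests, emulating instrumental terms
    such as astigmatism (``x^2 - y^2``).
    """
    for (i, j) in coeffs:
        if i + j > 4 or i < 0 or j < 0:
            raise ValueError("polynomial order must be <= 4")
    c = (grid_size - 1) / 2.0
    y, x = np.mgrid[0:grid_size, 0:grid_size].astype(float)
    xn = (x - c) / c
    yn = (y - c) / c
    out = np.zeros((grid_size, grid_size))
    for (i, j), a in coeffs.items():
        out += a * xn**i * yn**j
    return out
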