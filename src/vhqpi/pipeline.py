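"""End-to-end single-shot phase demodulation pipeline.

Orchestration: variational decomposition of the interferogram, an adaptive
window-size search for the fringe direction estimator, spiral-transform
demodulation, 2D unwrapping, residual plane removal and (optionally)
variational aberration correction of the unwrapped phase.

The window search runs the full direction + demodulation chain for every
plane-fitting window w in {3, 5, ..., 13} and keeps the phase map with the
minimal mean gradient magnitude: direction errors inject artificial phase
jumps that a gradient mean detects immediately, so the smoothest phase
marks the best direction estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import uvid
from .fringe_direction import (
    DirectionMap,
    anchor_direction_sign,
    direction_from_phase,
    estimate_orientation,
    sincos_filter,
    unwrap_orientation,
)
from .hst_demod import (
    hilbert_spiral_transform,
    lsq_unwrap,
    remove_plane,
    unwrap_phase,
    wrapped_phase,
)

__all__ = [
    "VhqpiConfig",
    "WindowSearchRecord",
    "mean_phase_gradient",
    "select_window_and_demodulate",
    "refine_direction",
    "vhqpi",
    "correct_aberrations",
]


@dataclass
class VhqpiConfig:
    """Tunable parameters of the pipeline; defaults are the fixed,
    versatile values of the method (mu=100, tau=0.25, w swept 3..13)."""

    mu: float = uvid.DEFAULT_MU
    tau: float = uvid.DEFAULT_TAU
    tol: float = uvid.DEFAULT_TOL
    max_iters: int = uvid.DEFAULT_MAX_ITERS
    denoiser: str = "auto"
    w_min: int = 3
    w_max: int = 13
    w_step: int = 2
    n_modes: int = 3
    orient_smoothing: float = 8.0
    refine_max: int = 15
    refine_patience: int = 4
    refine_sigma: float = 2.0
    refine_min_gain: float = 0.01
    aberration_correct: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("w_min", "w_max"):
            w = getattr(self, name)
            if w % 2 == 0 or not (3 <= w <= 13):
                raise ValueError(f"{name}={w}: windows must be odd and within [3, 13]")
        if self.w_step % 2 != 0 or self.w_step < 2:
            raise ValueError("w_step must be a positive even increment")
        if self.w_min > self.w_max:
            raise ValueError("w_min must not exceed w_max")

    @property
    def windows(self) -> list[int]:
        return list(range(self.w_min, self.w_max + 1, self.w_step))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class WindowSearchRecord:
    """Bookkeeping of the plane-fit window sweep."""

    entries: list[dict] = field(default_factory=list)  # w, mean_gradient, phase, direction
    selected_w: int = -1

    def gradient_for(self, w: int) -> float:
        for e in self.entries:
            if e["w"] == w:
                return e["mean_gradient"]
        raise KeyError(f"window {w} not in record")


def mean_phase_gradient(phase: np.ndarray) -> float:
    """Mean gradient magnitude (central differences) over interior pixels."""
    p = np.asarray(phase, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("phase must be finite")
    gy, gx = np.gradient(p)
    mag = np.hypot(gx, gy)
    return float(mag[1:-1, 1:-1].mean())


def _demodulate_with_direction(fringes: np.ndarray, beta) -> np.ndarray:
    quad = hilbert_spiral_transform(fringes, beta)
    return unwrap_phase(wrapped_phase(np.asarray(fringes) + 1j * quad))


def select_window_and_demodulate(
    fringes: np.ndarray, cfg: VhqpiConfig | None = None
) -> tuple[np.ndarray, WindowSearchRecord]:
    """Adaptive window search over the direction-estimation chain.

    For each window w: orientation -> direction unwrap -> sine–cosine
    filtering -> carrier sign anchoring -> spiral-transform demodulation ->
    unwrapping -> mean phase gradient.  Returns the phase of minimal mean
    gradient (ties broken toward the smaller window) with the full search
    record.
    """
    if cfg is None:
        cfg = VhqpiConfig()
    record = WindowSearchRecord()
    errors: list[str] = []
    for w in cfg.windows:
        try:
            orient = estimate_orientation(fringes, w)
            beta = unwrap_orientation(orient, smoothing=cfg.orient_smoothing)
            beta = sincos_filter(beta, n_modes=cfg.n_modes)
            beta = anchor_direction_sign(fringes, beta)
            phase = _demodulate_with_direction(fringes, beta)
            grad = mean_phase_gradient(phase)
        except ValueError as exc:
            errors.append(f"w={w}: {exc}")
            continue
        record.entries.append(
            {"w": w, "mean_gradient": grad, "phase": phase, "direction": beta}
        )
    if not record.entries:
        raise ValueError("direction estimation failed for every window: " + "; ".join(errors))
    best = min(record.entries, key=lambda e: (e["mean_gradient"], e["w"]))
    record.selected_w = best["w"]
    return best["phase"], record


def refine_direction(
    fringes: np.ndarray,
    phase: np.ndarray,
    cfg: VhqpiConfig | None = None,
) -> tuple[np.ndarray, DirectionMap | None]:
    """Iterative direction refinement from the demodulated phase.

    The direction map is re-derived from the gradient of the smooth
    (non-congruent) least-squares unwrap of each provisional demodulation
    and the fringes demodulated again; the iterate whose unwrapped phase
    has the lowest mean gradient is kept (stopping after
    ``refine_patience`` passes without improvement).  This extends the
    gradient-minimising window search to the direction field itself and is
    what recovers fringe folds — regions where the carrier locally
    reverses — that per-pixel orientation estimators cannot see.
    """
    if cfg is None:
        cfg = VhqpiConfig()
    best_phase = phase
    best_grad = mean_phase_gradient(phase)
    best_beta: DirectionMap | None = None
    current = phase
    stall = 0
    for _ in range(cfg.refine_max):
        smooth = lsq_unwrap(
            wrapped_phase(np.exp(1j * np.asarray(current))), congruent=False
        )
        beta = direction_from_phase(smooth, sigma=cfg.refine_sigma)
        current = _demodulate_with_direction(fringes, beta)
        grad = mean_phase_gradient(current)
        # accept only clear wins: repairing a sheet error removes branch
        # walls and drops the mean gradient by percents, while gradually
        # flattening a genuine fringe fold lowers it by far less — the
        # margin keeps the rescue and rejects the drift
        if grad < best_grad * (1.0 - cfg.refine_min_gain):
            best_grad, best_phase, best_beta = grad, current, beta
            stall = 0
        else:
            stall += 1
            if stall >= cfg.refine_patience:
                break
    return best_phase, best_beta


def vhqpi(
    interferogram: np.ndarray, cfg: VhqpiConfig | None = None
) -> tuple[np.ndarray, uvid.DecompositionResult, WindowSearchRecord]:
    """Full pipeline: interferogram in, unwrapped phase map out.

    Runs the variational decomposition, the window-searched direction-aided
    spiral demodulation and residual plane removal; with
    ``cfg.aberration_correct`` the unwrapped phase is additionally cleaned
    of its slowly varying background.  Deterministic for a given input and
    configuration.
    """
    if cfg is None:
        cfg = VhqpiConfig()
    img = np.asarray(interferogram, dtype=float)
    if img.ndim != 2 or min(img.shape) < 64:
        raise ValueError("vhqpi requires a 2D interferogram of at least 64x64")
    try:
        dec = uvid.uvid_filter(
            img, mu=cfg.mu, tau=cfg.tau, tol=cfg.tol,
            max_iters=cfg.max_iters, denoiser=cfg.denoiser,
        )
    except Exception as exc:
        raise RuntimeError(f"uVID decomposition stage failed: {exc}") from exc
    phase, record = select_window_and_demodulate(dec.fringes, cfg)
    if cfg.refine_max > 0:
        phase, _ = refine_direction(dec.fringes, phase, cfg)
    phase = remove_plane(phase)
    if cfg.aberration_correct:
        phase = correct_aberrations(phase, mu=cfg.mu, tau=cfg.tau, max_iters=cfg.max_iters)
    return phase, dec, record


def correct_aberrations(
    phase: np.ndarray,
    mu: float = uvid.DEFAULT_MU,
    tau: float = uvid.DEFAULT_TAU,
    tol: float = uvid.DEFAULT_TOL,
    max_iters: int = uvid.DEFAULT_MAX_ITERS,
) -> np.ndarray:
    """Variational aberration correction of an unwrapped phase map.

    The phase raster itself (not the interferogram) is decomposed; the
    slowly varying structure — instrumental background such as astigmatism
    — is discarded and the detail-carrying texture returned, re-centred to
    zero mean.  The denoising stage is skipped: unwrapped phase maps carry
    no separable high-frequency noise term worth splitting.
    """
    p = np.asarray(phase, dtype=float)
    structure, texture, _ = uvid.structure_texture(
        p, mu=mu, tau=tau, tol=tol, max_iters=max_iters
    )
    return texture - float(texture.mean())
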