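"""Evaluation metrics for retrieved phase maps.

Two scores: RMS error against a reference phase (with optional alignment
over the sign/piston group — the global ambiguities of single-shot
demodulation) and the standard deviation of sample-free regions, the
noise-robustness figure used to compare demodulators.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rms_error", "background_std", "error_map", "interior_mask"]


def interior_mask(
    shape: tuple[int, int], border: int = 16, exclude_disk: float | None = None
) -> np.ndarray:
    """Interior region: drop a border margin and optionally a central disk.

    The disk exclusion serves closed-fringe phantoms, whose direction
    vortex at the pattern centre is a known singular error source.
    """
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    if border > 0:
        mask[border:-border, border:-border] = True
    else:
        mask[:] = True
    if exclude_disk:
        y, x = np.mgrid[0:h, 0:w].astype(float)
        r = np.hypot(x - (w - 1) / 2.0, y - (h - 1) / 2.0)
        mask &= r > exclude_disk
    return mask


def _aligned_diff(phase, reference, mask, align):
    p = np.asarray(phase, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape:
        raise ValueError("phase and reference shapes differ")
    if mask is None:
        mask = np.ones(p.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != p.shape:
        raise ValueError("mask shape differs from phase")
    if not mask.any():
        raise ValueError("empty region mask")
    if not align:
        return p - r, mask
    best = None
    for sign in (1.0, -1.0):
        d = sign * p - r
        d = d - d[mask].mean()
        score = float(np.sqrt(np.mean(d[mask] ** 2)))
        if best is None or score < best[0]:
            best = (score, d)
    return best[1], mask


def rms_error(phase, reference, mask=None, align: bool = True) -> float:
    """RMS difference over the masked pixels, in radians.

    With ``align`` (default) the global sign and piston are first chosen
    to minimise the RMS — the conjugate-phase and constant-offset
    ambiguities of single-shot demodulation are not scored.
    """
    d, m = _aligned_diff(phase, reference, mask, align)
    return float(np.sqrt(np.mean(d[m] ** 2)))


def background_std(phase, mask) -> float:
    """Standard deviation of the phase over a sample-free region, radians.

    Population convention (ddof=0), i.e. exactly the RMS of the region
    about its own mean.
    """
    p = np.asarray(phase, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region mask")
    return float(np.std(p[mask]))


def error_map(phase, reference, align: bool = True) -> np.ndarray:
    """Aligned pointwise difference raster (radians), for error localization."""
    d, _ = _aligned_diff(phase, reference, None, align)
    return d
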