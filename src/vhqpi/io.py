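"""Raster file I/O and configuration loading.

Internal representation is always a float 2D array.  Float32 TIFF is the
primary interchange format (bitwise round-trip); 8/16-bit integer inputs
are rescaled to [0, 1] with the quantization scale recorded.  Phase maps
are stored as float32 TIFF in radians — integer export would silently
destroy sub-0.01-rad structure.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .pipeline import VhqpiConfig

__all__ = ["read_raster", "write_raster", "load_config", "dump_config"]


def read_raster(path) -> tuple[np.ndarray, dict]:
    """Read a TIFF/PNG raster as float, with scale metadata.

    Integer images are rescaled to [0, 1]; ``meta["scale"]`` records the
    divisor (e.g. 255 for 8-bit).  Multi-channel images are converted to
    luminance with a warning.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        data = tifffile.imread(path)
    elif suffix == ".png":
        data = iio.imread(path)
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r}")
    meta: dict = {"dtype": str(data.dtype), "scale": 1.0}
    if data.ndim == 3:
        warnings.warn(f"{path.name}: multi-channel image converted to luminance", stacklevel=2)
        data = data[..., :3].mean(axis=-1)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a 2D image, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        meta["scale"] = scale
        data = data.astype(np.float64) / scale
    else:
        data = np.asarray(data, dtype=np.float64)
    return data, meta


def write_raster(path, raster: np.ndarray, quantize: int | None = None) -> None:
    """Write a raster; float32 TIFF by default, integer PNG only on request.

    ``quantize`` (8 or 16) rescales to the full integer range — an explicit
    opt-in, since quantization is lossy.
    """
    path = Path(path)
    r = np.asarray(raster)
    if quantize is None:
        if path.suffix.lower() not in (".tif", ".tiff"):
            raise ValueError("unquantized rasters must be written as float32 TIFF")
        tifffile.imwrite(path, r.astype(np.float32))
        return
    if quantize not in (8, 16):
        raise ValueError("quantize must be 8 or 16")
    lo, hi = float(r.min()), float(r.max())
    span = hi - lo if hi > lo else 1.0
    maxval = 2**quantize - 1
    q = np.round((r - lo) / span * maxval)
    dtype = np.uint8 if quantize == 8 else np.uint16
    iio.imwrite(path, q.astype(dtype))


_CONFIG_KEYS = {f.name for f in dataclasses.fields(VhqpiConfig)}


def load_config(path) -> VhqpiConfig:
    """Load a YAML/JSON pipeline configuration.

    Unknown keys are rejected with the offending key path; omitted keys
    take the method defaults (mu=100, tau=0.25, w in [3, 13], ...).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
    try:
        return VhqpiConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: invalid configuration: {exc}") from exc


def dump_config(cfg: VhqpiConfig, path) -> None:
    """Write a configuration back to YAML (normalized key order)."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
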