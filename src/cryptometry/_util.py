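"""Shared numeric helpers: luminance, rounding, raster checks."""

from __future__ import annotations

import numpy as np

#: ITU-R BT.601 luma weights, the conventional grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


def luminance(rgb: np.ndarray) -> np.ndarray:
    """Return the BT.601 luminance of an (H, W, 3) raster as float64."""
    arr = np.asarray(rgb, dtype=np.float64)
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) RGB raster, got shape {arr.shape}")
    return arr @ _LUMA


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with halves away from zero (toward +inf
    for the non-negative image data used here)."""
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


def as_uint8(x: np.ndarray) -> np.ndarray:
    return np.clip(round_half_up(x), 0, 255).astype(np.uint8)


def check_rgb(arr: np.ndarray, name: str = "image") -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"{name} must be (H, W, 3), got shape {arr.shape}")
    return arr
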