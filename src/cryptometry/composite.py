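"""Best-contrast focus fusion of Z stacks and mosaicking of stage tiles.

Whole mounts are thicker than the depth of field of a macro zoom lens, so
acquisition captures a Z stack per stage tile and composites a uniformly
focused image.  "Best contrast" is operationalized as the per-pixel
argmax of windowed intensity variance on the luminance channel — the
standard focus measure — with whole-pixel plane selection (no per-channel
mixing, which would cause color fringing).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from cryptometry._util import as_uint8, luminance

DEFAULT_WINDOW = 15


def local_variance(gray: np.ndarray, window_px: int) -> np.ndarray:
    """Windowed variance of a grayscale image (uniform window, reflect
    boundary)."""
    g = np.asarray(gray, dtype=np.float64)
    mean = ndi.uniform_filter(g, window_px, mode="reflect")
    mean2 = ndi.uniform_filter(g * g, window_px, mode="reflect")
    return np.maximum(mean2 - mean * mean, 0.0)


def fuse_stack(stack, window_px=DEFAULT_WINDOW):
    """Fuse a Z stack into one uniformly focused raster.

    Each output pixel is copied whole from the plane whose windowed
    luminance variance is highest at that pixel; ties break toward the
    lowest plane index, so a stack of identical planes returns plane 0.
    """
    if len(stack) == 0:
        raise ValueError("cannot fuse an empty stack")
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be odd and >= 3")
    planes = [np.asarray(p) for p in stack]
    shape = planes[0].shape
    if any(p.shape != shape for p in planes):
        raise ValueError("all planes must share dimensions")
    if len(planes) == 1:
        return planes[0].copy()
    sharpness = np.stack(
        [local_variance(luminance(p), window_px) for p in planes]
    )
    choice = np.argmax(sharpness, axis=0)  # first max -> lowest plane index
    out = np.empty_like(planes[0])
    for k, p in enumerate(planes):
        out[choice == k] = p[choice == k]
    return out


def stitch(tiles, canvas_shape, blend="none"):
    """Reassemble tiles (from ``phantom.gen_tiles`` or a stage manifest).

    ``tiles`` is an iterable of ``(raster, (row, col), (y, x))``; tiles
    are processed in row-major (row, col) order.  ``blend='none'`` is
    last-writer-wins at overlaps; ``blend='feather'`` weights each tile by
    its distance to its own border (linear ramp) so overlapping identical
    tiles reproduce the source and non-overlap pixels are bit-equal to
    their single covering tile.
    """
    if blend not in ("none", "feather"):
        raise ValueError("blend must be 'none' or 'feather'")
    tiles = sorted(tiles, key=lambda t: t[1])
    if not tiles:
        raise ValueError("no tiles supplied")
    h, w = canvas_shape
    nch = tiles[0][0].shape[2] if tiles[0][0].ndim == 3 else 1
    coverage = np.zeros((h, w), dtype=np.int32)
    for tile, _, (y, x) in tiles:
        th, tw = tile.shape[:2]
        if y < 0 or x < 0 or y + th > h or x + tw > w:
            raise ValueError(f"tile at origin ({y}, {x}) exceeds the canvas")
        coverage[y : y + th, x : x + tw] += 1
    if (coverage == 0).any():
        ys, xs = np.nonzero(coverage == 0)
        raise ValueError(
            "canvas not fully covered; uncovered bounding box rows "
            f"{ys.min()}..{ys.max()}, cols {xs.min()}..{xs.max()}"
        )

    if blend == "none":
        out = np.zeros((h, w, nch) if nch > 1 else (h, w), dtype=tiles[0][0].dtype)
        for tile, _, (y, x) in tiles:
            th, tw = tile.shape[:2]
            out[y : y + th, x : x + tw] = tile
        return out

    acc = np.zeros((h, w, nch), dtype=np.float64)
    wsum = np.zeros((h, w), dtype=np.float64)
    for tile, _, (y, x) in tiles:
        th, tw = tile.shape[:2]
        ry = np.minimum(np.arange(th), np.arange(th)[::-1]) + 1.0
        rx = np.minimum(np.arange(tw), np.arange(tw)[::-1]) + 1.0
        wt = np.minimum.outer(ry, rx)
        t = tile.reshape(th, tw, nch).astype(np.float64)
        acc[y : y + th, x : x + tw] += t * wt[..., None]
        wsum[y : y + th, x : x + tw] += wt
    out = as_uint8(acc / wsum[..., None])
    return out if nch > 1 else out[..., 0]
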