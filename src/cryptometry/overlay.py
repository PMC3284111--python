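"""Translation registration and blending of serially stained layers.

The HID-AB restain of a whole mount is captured in a second session, so
its raster is displaced from the methylene-blue capture by a small stage
translation; no rotation or scale change occurs because the slide itself
never moves relative to the tissue.  Registration is therefore a search
over integer (dx, dy) translations maximizing the normalized
cross-correlation (NCC) of luminance — the algorithmic counterpart of
nudging a 50%-opacity layer until all edges line up.

Shift convention: ``estimate_shift(reference, moving)`` returns the
displacement *of the moving layer relative to the reference*, i.e. the
(dx, dy) such that ``apply_shift(moving, -dx, -dy)`` aligns it with the
reference.  This matches the phantom generator, which stores the shift it
applied to the HID-AB capture.
"""

from __future__ import annotations

import logging

import numpy as np

from cryptometry._util import as_uint8, luminance

logger = logging.getLogger(__name__)

#: NCC below this after registration suggests the true shift lay outside
#: the search window (or the layers simply do not correspond).
LOW_SCORE_WARNING = 0.2


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def estimate_shift(reference, moving, max_shift_px=50, channel="luminance"):
    """Find the integer displacement of ``moving`` relative to ``reference``.

    Exhaustively evaluates NCC over all shifts in
    ``[-max_shift_px, +max_shift_px]^2`` using, for each candidate, the
    region where the two rasters overlap.  Ties are broken toward the
    smallest ``|dx| + |dy|``, then the smallest dy, then the smallest dx.

    ``channel`` selects what is correlated: ``"luminance"`` (the direct
    analogue of eyeballing a half-opacity overlay) or ``"gradient"``
    (Sobel gradient magnitude of luminance).  The gradient channel is the
    right choice *across* stains, where a region dark in one stain may be
    bright in the other yet tissue edges coincide.

    Returns ``(dx, dy, score)`` with score in [-1, 1].
    """
    ref = luminance(reference)
    mov = luminance(moving)
    if channel == "gradient":
        from scipy import ndimage as ndi

        ref = ndi.generic_gradient_magnitude(ref, ndi.sobel)
        mov = ndi.generic_gradient_magnitude(mov, ndi.sobel)
    elif channel != "luminance":
        raise ValueError("channel must be 'luminance' or 'gradient'")
    if ref.shape != mov.shape:
        raise ValueError("reference and moving images must share dimensions")
    if max_shift_px < 0:
        raise ValueError("max_shift_px must be >= 0")
    if ref.std() == 0 or mov.std() == 0:
        raise ValueError("cannot register a constant (zero-variance) image")
    h, w = ref.shape
    if max_shift_px >= min(h, w):
        raise ValueError("max_shift_px must be smaller than the image")

    shifts = [
        (dx, dy)
        for dy in range(-max_shift_px, max_shift_px + 1)
        for dx in range(-max_shift_px, max_shift_px + 1)
    ]
    shifts.sort(key=lambda s: (abs(s[0]) + abs(s[1]), s[1], s[0]))

    best = None
    for dx, dy in shifts:
        # moving was displaced by (dx, dy): moving[y, x] ~ ref[y-dy, x-dx]
        my0, mx0 = max(0, dy), max(0, dx)
        ry0, rx0 = max(0, -dy), max(0, -dx)
        oh, ow = h - abs(dy), w - abs(dx)
        a = mov[my0 : my0 + oh, mx0 : mx0 + ow]
        b = ref[ry0 : ry0 + oh, rx0 : rx0 + ow]
        score = _ncc(a, b)
        if best is None or score > best[2]:
            best = (dx, dy, score)
    dx, dy, score = best
    if score < LOW_SCORE_WARNING:
        logger.warning(
            "registration NCC %.3f at shift (%d, %d) is low; the true shift "
            "may exceed max_shift_px=%d",
            score,
            dx,
            dy,
            max_shift_px,
        )
    return dx, dy, score


def apply_shift(layer, dx, dy, fill=(255, 255, 255)):
    """Translate a raster by integer (dx, dy); vacated margins get ``fill``.

    Positive dx moves content right, positive dy moves it down (row-major,
    origin top-left).  Dimensions are preserved.
    """
    arr = np.asarray(layer)
    h, w = arr.shape[:2]
    if abs(dx) >= w or abs(dy) >= h:
        raise ValueError("shift magnitude must be smaller than the image")
    out = np.empty_like(arr)
    if arr.ndim == 3:
        out[:] = np.asarray(fill, dtype=arr.dtype)[: arr.shape[2]]
    else:
        out[:] = fill if np.isscalar(fill) else fill[0]
    sy0, sx0 = max(0, -dy), max(0, -dx)
    ty0, tx0 = max(0, dy), max(0, dx)
    oh, ow = h - abs(dy), w - abs(dx)
    out[ty0 : ty0 + oh, tx0 : tx0 + ow] = arr[sy0 : sy0 + oh, sx0 : sx0 + ow]
    return out


def blend(bottom, top, opacity=0.5):
    """Alpha-blend ``top`` over ``bottom``: (1-opacity)*bottom + opacity*top,
    per channel, rounded half-up — the QC overlay used to judge alignment."""
    if not 0.0 <= opacity <= 1.0:
        raise ValueError("opacity must lie in [0, 1]")
    b = np.asarray(bottom, dtype=np.float64)
    t = np.asarray(top, dtype=np.float64)
    if b.shape != t.shape:
        raise ValueError("layers must share dimensions")
    return as_uint8((1.0 - opacity) * b + opacity * t)
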