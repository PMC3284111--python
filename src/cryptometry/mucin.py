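"""HID-AB mucin-class segmentation, percent areas, MDF calling, and
stain-deposition categories.

High iron diamine (HID) deposits dark brown over sulphomucin; alcian
blue (AB) stains sialomucin blue; epithelium secreting neither stays
unstained.  Each focus patch is classified pixel-wise in HSV space with
precedence HID → AB → UNSTAINED, percent class areas are reported
against the focus area, and a focus whose unstained percent reaches the
MDF threshold (default 85%) is called a mucin-depleted focus — unless it
overlaps gut-associated lymphoid tissue, which is natively stain-poor.

The numeric HSV gates below are calibrated to the phantom palette and
are fully configurable; real-slide use requires recalibration against a
scanner/stain-batch reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from skimage import color

# Class codes in a MucinClassMap.
OUTSIDE, HID, AB, UNSTAINED = 0, 1, 2, 3

#: Percent unstained area at or above which a focus is a mucin-depleted
#: focus (inclusive bound).
MDF_THRESHOLD = 85.0


class StainCategory(str, Enum):
    """Four operational stain-deposition categories."""

    SULFO_ABUNDANT = "sulfo_abundant"  # dominant brown (HID)
    MIXED = "mixed"  # substantial brown and blue
    SULFO_DEPLETED = "sulfo_depleted"  # blue without brown
    FULLY_DEPLETED = "fully_depleted"  # neither stain (MDF territory)


@dataclass(frozen=True)
class MucinThresholds:
    """HSV gates for the three color classes (hue in degrees, saturation
    and value in [0, 1]).  Precedence is HID, then AB, then UNSTAINED."""

    hue_brown: tuple[float, float] = (10.0, 50.0)
    v_hid: float = 0.55  # brown must be at most this bright
    dark_s: float = 0.60  # very dark saturated pixels also count as HID
    dark_v: float = 0.35
    hue_blue: tuple[float, float] = (180.0, 260.0)
    s_ab: float = 0.25  # blue must be at least this saturated


@dataclass
class MucinClassMap:
    """Per-pixel class assignment over one focus patch."""

    classes: np.ndarray  # uint8 of OUTSIDE/HID/AB/UNSTAINED
    thresholds: MucinThresholds

    def counts(self) -> dict:
        return {
            c: int((self.classes == c).sum()) for c in (HID, AB, UNSTAINED)
        }

    @property
    def n_in_mask(self) -> int:
        return int((self.classes != OUTSIDE).sum())


def segment_classes(
    patch_rgb, focus_mask, thresholds: MucinThresholds | None = None
) -> MucinClassMap:
    """Classify each in-mask pixel as HID, AB, or UNSTAINED.

    A pixel is HID if its hue falls in the brown range with value at most
    ``v_hid``, or if it is very dark yet saturated (``dark_s``/``dark_v``
    — heavy HID deposits approach black); otherwise AB if its hue falls
    in the blue range with saturation at least ``s_ab``; otherwise
    UNSTAINED.  Pixels outside the mask are OUTSIDE.
    """
    thr = thresholds or MucinThresholds()
    mask = np.asarray(focus_mask, dtype=bool)
    if not mask.any():
        raise ValueError("focus mask is empty")
    rgb = np.asarray(patch_rgb)
    if rgb.shape[:2] != mask.shape:
        raise ValueError("patch and mask dimensions differ")
    hsv = color.rgb2hsv(rgb.astype(np.float64) / 255.0)
    hue = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    val = hsv[..., 2]

    is_brown = (hue >= thr.hue_brown[0]) & (hue <= thr.hue_brown[1]) & (val <= thr.v_hid)
    is_dark = (sat >= thr.dark_s) & (val <= thr.dark_v)
    is_hid = is_brown | is_dark
    is_blue = (hue >= thr.hue_blue[0]) & (hue <= thr.hue_blue[1]) & (sat >= thr.s_ab)

    classes = np.full(mask.shape, OUTSIDE, dtype=np.uint8)
    classes[mask] = UNSTAINED
    classes[mask & is_blue] = AB
    classes[mask & is_hid] = HID  # HID precedence wins over AB
    return MucinClassMap(classes=classes, thresholds=thr)


def percent_areas(class_map: MucinClassMap) -> tuple[float, float, float]:
    """Percent (sulphomucin/HID, sialomucin/AB, unstained) of focus area.

    The three percents sum to 100 by construction (every in-mask pixel
    has exactly one class).
    """
    n = class_map.n_in_mask
    if n == 0:
        raise ValueError("class map has no in-mask pixels")
    c = class_map.counts()
    return (
        100.0 * c[HID] / n,
        100.0 * c[AB] / n,
        100.0 * c[UNSTAINED] / n,
    )


def call_mdf(percents, galt_overlap: bool = False, threshold: float = MDF_THRESHOLD) -> bool:
    """MDF call: unstained percent at or above the threshold (inclusive),
    unless the focus overlaps GALT (stain-poor tissue masquerading as
    depletion)."""
    p_sulfo, p_sialo, p_un = percents
    for p in (p_sulfo, p_sialo, p_un):
        if not -1e-9 <= p <= 100.0 + 1e-9:
            raise ValueError("percents must lie in [0, 100]")
    return bool(p_un >= threshold) and not galt_overlap


def stain_category(
    percents,
    min_dominant: float = 70.0,
    min_mixed: float = 15.0,
    depletion_threshold: float = MDF_THRESHOLD,
) -> StainCategory:
    """Assign one of the four stain-deposition categories.

    Fully depleted if unstained reaches the depletion threshold; else
    sulpho-abundant if HID percent >= ``min_dominant``; else mixed if
    both stain percents >= ``min_mixed``; else sulpho-depleted if AB
    exceeds HID; else sulpho-abundant.
    """
    p_sulfo, p_sialo, p_un = percents
    if p_un >= depletion_threshold:
        return StainCategory.FULLY_DEPLETED
    if p_sulfo >= min_dominant:
        return StainCategory.SULFO_ABUNDANT
    if p_sulfo >= min_mixed and p_sialo >= min_mixed:
        return StainCategory.MIXED
    if p_sialo > p_sulfo:
        return StainCategory.SULFO_DEPLETED
    return StainCategory.SULFO_ABUNDANT


def synthetic_class_map(n_pixels: int, percent_unstained: float, rng=None) -> MucinClassMap:
    """Build a synthetic class map with an exact unstained percent, the
    remainder split between HID and AB — used for threshold sweeps."""
    if not 0 <= percent_unstained <= 100:
        raise ValueError("percent_unstained must lie in [0, 100]")
    n_un = int(round(n_pixels * percent_unstained / 100.0))
    n_hid = (n_pixels - n_un + 1) // 2
    n_ab = n_pixels - n_un - n_hid
    flat = np.concatenate(
        [
            np.full(n_hid, HID, dtype=np.uint8),
            np.full(n_ab, AB, dtype=np.uint8),
            np.full(n_un, UNSTAINED, dtype=np.uint8),
        ]
    )
    if rng is not None:
        rng.shuffle(flat)
    side = int(np.ceil(np.sqrt(n_pixels)))
    classes = np.full(side * side, OUTSIDE, dtype=np.uint8)
    classes[:n_pixels] = flat
    return MucinClassMap(
        classes=classes.reshape(side, side), thresholds=MucinThresholds()
    )
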