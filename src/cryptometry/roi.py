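"""Circumscribed outlines -> labeled ACF masks, white-background excision,
cross-layer label transfer, and GALT exclusion.

The digital-excision workflow circumscribes each visible focus with a
closed outline, selects everything inside (the drawn border counts as
part of the focus), and lifts those pixels onto a white background.  The
same outlines, translated by the registered inter-layer shift, extract
the corresponding HID-AB regions.  Foci lying mostly inside
gut-associated lymphoid tissue (GALT) are flagged: GALT is natively
stain-poor and would otherwise masquerade as mucin-depleted foci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage as ndi

from cryptometry.imgio import RoiSet

logger = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=int)  # 8-connectivity throughout

#: A focus with at least this fraction of its area inside GALT is excluded
#: from MDF calling; any lesser contact is flagged as peripheral.
GALT_OVERLAP_THRESHOLD = 0.5


@dataclass
class AcfMaskSet:
    """Labeled focus masks over one whole-mount raster.

    ``labels`` uses 0 for background and k for focus k (consecutive
    positive integers); ``roi_ids[k-1]`` preserves the originating ROI id.
    Bounding boxes are 0-based half-open (r0, r1, c0, c1).
    """

    labels: np.ndarray
    roi_ids: list[int] = field(default_factory=list)
    galt_overlap: dict = field(default_factory=dict)  # label -> bool
    galt_peripheral: dict = field(default_factory=dict)

    @property
    def n_foci(self) -> int:
        return len(self.roi_ids)

    def bbox(self, label: int) -> tuple[int, int, int, int]:
        ys, xs = np.nonzero(self.labels == label)
        if len(ys) == 0:
            raise KeyError(f"no focus with label {label}")
        return int(ys.min()), int(ys.max()) + 1, int(xs.min()), int(xs.max()) + 1

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def flags(self, label: int) -> tuple[bool, bool]:
        return (
            bool(self.galt_overlap.get(label, False)),
            bool(self.galt_peripheral.get(label, False)),
        )


def outlines_to_labels(rois: RoiSet, image_shape) -> AcfMaskSet:
    """Fill each circumscribed ACF polygon into a label map.

    Interior *and* boundary pixels (pixel centers covered by the closed
    polygon) are assigned; labels are consecutive in ascending ROI-id
    order.  Overlapping polygons are an error — foci are distinct lesions.
    """
    h, w = image_shape
    labels = np.zeros((h, w), dtype=np.int32)
    rois_sorted = sorted(rois.by_role("acf"), key=lambda r: r.id)
    roi_ids = []
    for k, roi in enumerate(rois_sorted, start=1):
        roi.validate()
        poly = roi.polygon()
        x0, y0, x1, y1 = poly.bounds
        if x0 < -0.5 or y0 < -0.5 or x1 > w - 0.5 or y1 > h - 0.5:
            raise ValueError(f"ROI {roi.id} lies outside the image bounds")
        r0, r1 = max(0, int(np.floor(y0))), min(h - 1, int(np.ceil(y1)))
        c0, c1 = max(0, int(np.floor(x0))), min(w - 1, int(np.ceil(x1)))
        yy, xx = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
        inside = shapely.covers(poly, shapely.points(xx.ravel(), yy.ravel()))
        inside = inside.reshape(yy.shape)
        window = labels[r0 : r1 + 1, c0 : c1 + 1]
        if np.any(window[inside] != 0):
            other = int(window[inside][window[inside] != 0][0])
            raise ValueError(
                f"ROI {roi.id} overlaps ROI {roi_ids[other - 1]}; "
                "circumscribed foci must be distinct"
            )
        window[inside] = k
        roi_ids.append(roi.id)
    return AcfMaskSet(labels=labels, roi_ids=roi_ids)


def extract_on_white(image, masks: AcfMaskSet) -> np.ndarray:
    """Copy focus pixels verbatim; set everything else to pure white —
    the digital analogue of flattening to 'excised ACF on a white
    background'."""
    image = np.asarray(image)
    if image.shape[:2] != masks.labels.shape:
        raise ValueError("image and mask dimensions differ")
    out = np.full_like(image, 255)
    sel = masks.labels > 0
    out[sel] = image[sel]
    return out


def transfer_labels(masks: AcfMaskSet, shift) -> AcfMaskSet:
    """Translate the label map by (dx, dy) so methylene-drawn outlines
    extract the registered HID-AB layer.  Foci shifted entirely out of
    frame are dropped (with a warning) and remaining labels renumbered
    consecutively."""
    dx, dy = shift
    h, w = masks.labels.shape
    moved = np.zeros_like(masks.labels)
    sy0, sx0 = max(0, -dy), max(0, -dx)
    ty0, tx0 = max(0, dy), max(0, dx)
    oh, ow = h - abs(dy), w - abs(dx)
    if oh > 0 and ow > 0:
        moved[ty0 : ty0 + oh, tx0 : tx0 + ow] = masks.labels[
            sy0 : sy0 + oh, sx0 : sx0 + ow
        ]
    out_labels = np.zeros_like(moved)
    new_ids = []
    new_k = 0
    for k in range(1, masks.n_foci + 1):
        sel = moved == k
        if not sel.any():
            logger.warning(
                "focus %d (ROI id %d) shifted out of frame; dropped",
                k,
                masks.roi_ids[k - 1],
            )
            continue
        new_k += 1
        out_labels[sel] = new_k
        new_ids.append(masks.roi_ids[k - 1])
    return AcfMaskSet(labels=out_labels, roi_ids=new_ids)


def apply_galt(masks: AcfMaskSet, galt_rois: RoiSet, threshold=GALT_OVERLAP_THRESHOLD) -> AcfMaskSet:
    """Flag foci against GALT polygons.

    A focus with >= ``threshold`` of its area inside GALT gets
    ``galt_overlap`` (excluded from MDF calling downstream); a focus with
    any lesser contact — overlap below threshold, or mere 8-adjacency to
    GALT — gets ``galt_peripheral`` (retained but flagged).
    """
    h, w = masks.labels.shape
    galt_mask = np.zeros((h, w), dtype=bool)
    for roi in galt_rois.by_role("galt"):
        roi.validate()
        poly = roi.polygon()
        x0, y0, x1, y1 = poly.bounds
        r0, r1 = max(0, int(np.floor(y0))), min(h - 1, int(np.ceil(y1)))
        c0, c1 = max(0, int(np.floor(x0))), min(w - 1, int(np.ceil(x1)))
        if r1 < r0 or c1 < c0:
            continue
        yy, xx = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
        inside = shapely.covers(poly, shapely.points(xx.ravel(), yy.ravel()))
        galt_mask[r0 : r1 + 1, c0 : c1 + 1] |= inside.reshape(yy.shape)
    return apply_galt_mask(masks, galt_mask, threshold)


def apply_galt_mask(masks: AcfMaskSet, galt_mask, threshold=GALT_OVERLAP_THRESHOLD) -> AcfMaskSet:
    """Same as :func:`apply_galt` but from a rasterized GALT mask."""
    galt_mask = np.asarray(galt_mask, dtype=bool)
    near_galt = ndi.binary_dilation(galt_mask, structure=_STRUCT8)
    overlap = {}
    peripheral = {}
    for k in range(1, masks.n_foci + 1):
        sel = masks.labels == k
        area = sel.sum()
        frac = (sel & galt_mask).sum() / area if area else 0.0
        if frac >= threshold:
            overlap[k] = True
            peripheral[k] = False
        elif frac > 0 or (sel & near_galt).any():
            overlap[k] = False
            peripheral[k] = True
        else:
            overlap[k] = False
            peripheral[k] = False
    return AcfMaskSet(
        labels=masks.labels,
        roi_ids=list(masks.roi_ids),
        galt_overlap=overlap,
        galt_peripheral=peripheral,
    )
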