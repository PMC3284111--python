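"""Crypt detection/editing and the per-focus morphometric battery.

Each excised focus is measured for: area, epithelial area, perimeter
(Crofton estimate), mean Feret diameter, roundness (perimeter²/(4π·area);
1 for a circle, larger for irregular shapes), staining density, and
integrated optical density (area × density); the same battery applies to
the crypt lumens detected inside the focus, plus the crypt count.

Crypt detection mimics the interactive workflow: the focus patch is
contrast-stretched, pixels darker than a threshold (Otsu by default)
become candidate crypt pixels, components below a minimum lumen area are
discarded, and the user may replay toggle/split/join edits before
measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import draw, filters, measure

from cryptometry._util import as_uint8, luminance

_STRUCT8 = np.ones((3, 3), dtype=int)

#: Crypt roundness category bin edges: category i is [edge_i, edge_{i+1}).
#: Category 0 starts at the theoretical minimum roundness of 1.
ROUNDCAT_EDGES = (1.25, 1.75, 2.5, 4.0)

#: Number of equally spaced directions for Feret (caliper) diameters.
FERET_DIRECTIONS = 18


def roundness(perimeter: float, area: float) -> float:
    """Shape factor perimeter²/(4π·area): 1 for an ideal circle, 4/π for
    a square, larger for more polygonal or elongated shapes."""
    if area <= 0:
        raise ValueError("area must be positive")
    return perimeter**2 / (4.0 * np.pi * area)


@dataclass
class CryptParams:
    """Tunables for crypt lumen detection."""

    stretch_percentiles: tuple[float, float] = (2.0, 98.0)
    threshold: Optional[float] = None  # on the stretched 0..255 scale; None = Otsu
    min_area_um2: float = 50.0
    #: Lumens cannot plausibly cover more than this fraction of a focus;
    #: when automatic thresholding exceeds it (Otsu splitting the bright
    #: epithelium mode because lumens are a tiny minority), thresholding
    #: is repeated on the dark side only.
    max_dark_fraction: float = 0.35


def stretch_contrast(gray, mask, percentiles=(2.0, 98.0)) -> np.ndarray:
    """Percentile-stretch in-mask luminance to the full 0..255 range."""
    g = np.asarray(gray, dtype=np.float64)
    vals = g[mask]
    lo, hi = np.percentile(vals, percentiles)
    if hi <= lo:
        return np.zeros_like(g)
    return np.clip((g - lo) / (hi - lo) * 255.0, 0.0, 255.0)


class CryptLabelMap:
    """Editable crypt label map over one focus patch.

    Components carry stable internal ids so a toggled-off crypt can be
    toggled back; the public :attr:`labels` view renumbers active
    components consecutively (creation order), satisfying downstream
    consumers that expect labels 1..n.
    """

    def __init__(self, shape):
        self.shape = tuple(shape)
        self._components: dict[int, np.ndarray] = {}
        self._active: dict[int, bool] = {}
        self._order: list[int] = []
        self._next_id = 1
        self.edit_log: list[tuple] = []

    # -- construction -----------------------------------------------------
    def add(self, mask: np.ndarray) -> int:
        cid = self._next_id
        self._next_id += 1
        self._components[cid] = np.asarray(mask, dtype=bool)
        self._active[cid] = True
        self._order.append(cid)
        return cid

    def copy(self) -> "CryptLabelMap":
        out = CryptLabelMap(self.shape)
        out._components = {k: v.copy() for k, v in self._components.items()}
        out._active = dict(self._active)
        out._order = list(self._order)
        out._next_id = self._next_id
        out.edit_log = list(self.edit_log)
        return out

    # -- views ------------------------------------------------------------
    @property
    def ids(self) -> list[int]:
        return [c for c in self._order if self._active[c]]

    @property
    def count(self) -> int:
        return len(self.ids)

    @property
    def labels(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=np.int32)
        for k, cid in enumerate(self.ids, start=1):
            out[self._components[cid]] = k
        return out

    def component(self, cid: int) -> np.ndarray:
        if cid not in self._components:
            raise KeyError(f"unknown crypt id {cid}")
        return self._components[cid]

    # -- edits ------------------------------------------------------------
    def toggle(self, cid: int) -> None:
        if cid not in self._components:
            raise KeyError(f"unknown crypt id {cid}")
        self._active[cid] = not self._active[cid]
        self.edit_log.append(("toggle", cid))

    def join(self, cid_a: int, cid_b: int) -> int:
        for c in (cid_a, cid_b):
            if c not in self._components or not self._active[c]:
                raise KeyError(f"unknown or inactive crypt id {c}")
        if cid_a == cid_b:
            raise ValueError("cannot join a crypt with itself")
        merged = self._components[cid_a] | self._components[cid_b]
        self._components[cid_a] = merged
        self._active[cid_b] = False
        self._order.remove(cid_b)
        del self._components[cid_b]
        del self._active[cid_b]
        self.edit_log.append(("join", cid_a, cid_b))
        return cid_a

    def split(self, cid: int, polyline) -> tuple[int, ...]:
        """Split one component along a cut polyline; cut pixels belong to
        neither child."""
        if cid not in self._components or not self._active[cid]:
            raise KeyError(f"unknown or inactive crypt id {cid}")
        comp = self._components[cid]
        cut = np.zeros(self.shape, dtype=bool)
        pts = np.asarray(polyline, dtype=float)
        if pts.ndim != 2 or len(pts) < 2:
            raise ValueError("cut polyline needs >= 2 vertices")
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            rr, cc = draw.line(
                int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1))
            )
            keep = (rr >= 0) & (rr < self.shape[0]) & (cc >= 0) & (cc < self.shape[1])
            cut[rr[keep], cc[keep]] = True
        remain = comp & ~cut
        lab, n = ndi.label(remain, structure=_STRUCT8)
        if n < 2:
            raise ValueError("cut polyline does not separate the crypt")
        # deterministic child order: by first pixel in raster scan
        firsts = ndi.minimum_position(
            np.arange(lab.size).reshape(lab.shape), lab, range(1, n + 1)
        )
        order = sorted(range(1, n + 1), key=lambda k: firsts[k - 1])
        pos = self._order.index(cid)
        self._order.remove(cid)
        del self._components[cid]
        del self._active[cid]
        new_ids = []
        for j, k in enumerate(order):
            nid = self._next_id
            self._next_id += 1
            self._components[nid] = lab == k
            self._active[nid] = True
            self._order.insert(pos + j, nid)
            new_ids.append(nid)
        self.edit_log.append(("split", cid, tuple(new_ids)))
        return tuple(new_ids)


def detect_crypts(
    patch_gray,
    focus_mask,
    pixel_size_um: float,
    params: CryptParams | None = None,
) -> CryptLabelMap:
    """Detect crypt lumens: dark components inside the focus mask.

    The in-mask luminance is percentile-stretched; pixels darker than the
    crypt threshold (Otsu on the stretched in-mask values if not given)
    become candidates; components smaller than ``min_area_um2`` are
    discarded; the rest are labeled with 8-connectivity.
    """
    params = params or CryptParams()
    mask = np.asarray(focus_mask, dtype=bool)
    if not mask.any():
        raise ValueError("focus mask is empty")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    stretched = stretch_contrast(patch_gray, mask, params.stretch_percentiles)
    vals = stretched[mask]
    if params.threshold is not None:
        thr = float(params.threshold)
    elif np.ptp(vals) == 0:
        thr = -np.inf  # uniform patch: nothing is "darker"
    else:
        thr = float(filters.threshold_otsu(vals))
        for _ in range(4):  # re-threshold while implausibly much is "dark"
            dark = vals[vals < thr]
            if dark.size / vals.size <= params.max_dark_fraction:
                break
            if dark.size < 2 or np.ptp(dark) == 0:
                break
            thr = float(filters.threshold_otsu(dark))
    cand = (stretched < thr) & mask
    lab, n = ndi.label(cand, structure=_STRUCT8)
    min_px = params.min_area_um2 / (pixel_size_um**2)
    out = CryptLabelMap(mask.shape)
    if n:
        areas = ndi.sum_labels(np.ones_like(lab), lab, range(1, n + 1))
        for k in range(1, n + 1):
            if areas[k - 1] >= min_px:
                out.add(lab == k)
    return out


def edit_crypts(crypts: CryptLabelMap, edits) -> CryptLabelMap:
    """Replay an edit list on a copy of the map.

    Each edit is ``("toggle", id)``, ``("join", id_a, id_b)`` or
    ``("split", id, polyline)``.
    """
    out = crypts.copy()
    for edit in edits:
        op = edit[0]
        if op == "toggle":
            out.toggle(edit[1])
        elif op == "join":
            out.join(edit[1], edit[2])
        elif op == "split":
            out.split(edit[1], edit[2])
        else:
            raise ValueError(f"unknown edit operation {op!r}")
    return out


# ---------------------------------------------------------------------------
# Shape measurements


def feret_diameters(mask, n_directions=FERET_DIRECTIONS) -> np.ndarray:
    """Caliper (Feret) extents of a pixel set over equally spaced
    directions, in pixels (projection span + 1 pixel footprint)."""
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    if len(ys) == 0:
        raise ValueError("empty mask")
    angles = np.arange(n_directions) * np.pi / n_directions
    proj = xs[:, None] * np.cos(angles) + ys[:, None] * np.sin(angles)
    return proj.max(axis=0) - proj.min(axis=0) + 1.0


def _shape_metrics(mask, s):
    """area, perimeter, roundness, max/mean Feret, major axis — in µm."""
    area_px = int(mask.sum())
    perim_px = measure.perimeter_crofton(mask, directions=4)
    fer = feret_diameters(mask)
    props = measure.regionprops(mask.astype(np.uint8))[0]
    return {
        "area": area_px * s * s,
        "perimeter": perim_px * s,
        "roundness": roundness(perim_px, area_px) if area_px else np.nan,
        "feret_mean": float(fer.mean()) * s,
        "feret_max": float(fer.max()) * s,
        "major_axis": props.axis_major_length * s,
    }


@dataclass
class AcfMeasurements:
    """The full per-focus measurement vector (morphometry + mucin).

    Areas in µm², lengths in µm, density dimensionless in [0, 1], IOD in
    µm² (area × density), percents on the 0–100 scale.  Mucin fields stay
    NaN/None until the HID-AB stage fills them.
    """

    CRYPTCOUNT: int = 0
    ACF_AREA: float = np.nan
    ACF_EPIAREA: float = np.nan
    C_SUMAREA: float = 0.0
    C_AVGAREA: float = 0.0
    ACF_DIAAVG: float = np.nan
    C_AVGMAXDIA: float = 0.0
    C_AVGSIZELEN: float = 0.0
    ACF_PERIM: float = np.nan
    C_AVGPERIM: float = 0.0
    ACF_ROUND: float = np.nan
    C_AVGROUND: float = np.nan
    C_ROUNDCAT: int = 0
    ACF_DEN: float = np.nan
    ACF_IOD: float = np.nan
    P_SULFOAREA: float = np.nan
    P_SIALOAREA: float = np.nan
    P_UAREA: float = np.nan
    MDF: Optional[bool] = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


MEASUREMENT_COLUMNS = [f.name for f in fields(AcfMeasurements)]


def background_white_point(patch_rgb, focus_mask, percentile=99.0) -> float:
    """Per-slide white point: a high percentile of background luminance
    (outside the focus); falls back to 255 if no background is visible."""
    lum = luminance(patch_rgb)
    bg = lum[~np.asarray(focus_mask, dtype=bool)]
    if bg.size == 0:
        return 255.0
    wp = float(np.percentile(bg, percentile))
    return wp if wp > 0 else 255.0


def measure_acf(
    patch_rgb,
    focus_mask,
    crypts: CryptLabelMap | None,
    pixel_size_um: float,
    white_point: float | None = None,
    density_mode: str = "linear",
    roundcat_edges=ROUNDCAT_EDGES,
) -> AcfMeasurements:
    """Compute the morphometric battery for one focus.

    Density is the mean over the mask of (1 − L) with L the luminance
    normalized to [0, 1] against the slide white point (``linear``), or
    the mean optical density −log10(L) clipped at 2 and rescaled to [0, 1]
    (``od``).  IOD = area × density by definition.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um (calibration) must be positive")
    mask = np.asarray(focus_mask, dtype=bool)
    if not mask.any():
        raise ValueError("focus mask is empty")
    s = pixel_size_um
    m = _shape_metrics(mask, s)

    lum = luminance(patch_rgb)
    wp = white_point if white_point is not None else background_white_point(patch_rgb, mask)
    L = np.clip(lum[mask] / wp, 0.0, 1.0)
    if density_mode == "linear":
        den = float(np.mean(1.0 - L))
    elif density_mode == "od":
        od = -np.log10(np.maximum(L, 10.0**-2))
        den = float(np.mean(od) / 2.0)
    else:
        raise ValueError("density_mode must be 'linear' or 'od'")

    out = AcfMeasurements(
        ACF_AREA=m["area"],
        ACF_PERIM=m["perimeter"],
        ACF_ROUND=m["roundness"],
        ACF_DIAAVG=m["feret_mean"],
        ACF_DEN=den,
        ACF_IOD=m["area"] * den,
    )

    if crypts is not None and crypts.count:
        per = [_shape_metrics(crypts.component(cid), s) for cid in crypts.ids]
        out.CRYPTCOUNT = crypts.count
        out.C_SUMAREA = float(sum(p["area"] for p in per))
        out.C_AVGAREA = out.C_SUMAREA / out.CRYPTCOUNT
        out.C_AVGPERIM = float(np.mean([p["perimeter"] for p in per]))
        out.C_AVGROUND = float(np.mean([p["roundness"] for p in per]))
        out.C_AVGMAXDIA = float(np.mean([p["feret_max"] for p in per]))
        out.C_AVGSIZELEN = float(np.mean([p["major_axis"] for p in per]))
        out.C_ROUNDCAT = int(np.digitize(out.C_AVGROUND, roundcat_edges))
    out.ACF_EPIAREA = max(out.ACF_AREA - out.C_SUMAREA, 0.0)
    return out


def render_qc(patch_rgb, crypts: CryptLabelMap | None = None) -> dict:
    """Deterministic QC renderings of one focus patch.

    Returns ``height`` (float map, inverted luminance: darker staining is
    'taller'), ``pseudo_color`` (fixed viridis colormap of height, uint8
    RGB), and ``overlay`` (contrast-stretched grayscale with detected
    crypt pixels painted pure red).
    """
    patch = np.asarray(patch_rgb)
    if patch.size == 0:
        raise ValueError("empty patch")
    lum = luminance(patch)
    height = 255.0 - lum
    span = np.ptp(height)
    norm = (height - height.min()) / span if span > 0 else np.zeros_like(height)
    import matplotlib

    cmap = matplotlib.colormaps["viridis"]
    pseudo = as_uint8(np.asarray(cmap(norm))[..., :3] * 255.0)
    full = np.ones(lum.shape, dtype=bool)
    stretched = stretch_contrast(lum, full)
    overlay = as_uint8(np.stack([stretched] * 3, axis=-1))
    if crypts is not None:
        overlay[crypts.labels > 0] = (255, 0, 0)
    return {"height": height, "pseudo_color": pseudo, "overlay": overlay}
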