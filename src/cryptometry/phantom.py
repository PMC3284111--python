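"""Synthetic dual-stain whole-mount phantoms with exhaustive ground truth.

Every downstream stage (compositing, registration, ROI extraction,
morphometry, mucin scoring) is exercised against images produced here, so
the renderer favours *known* geometry and colorimetry over realism:

* The methylene-blue layer is a light blue mucosa with a faint periodic
  "normal crypt" lattice; each aberrant crypt focus (ACF) is a darker disk
  whose crypt lumens are near-black (round disks, high-aspect slits, or
  spiral ribbons).
* The HID-AB layer shares the same tissue lattice (it is the same slide,
  restained) and renders each focus as an angular-sector partition into
  three mucin classes: HID sulphomucin (dark brown), AB sialomucin
  (blue), and unstained (near-white).  Sector cuts are placed by exact
  pixel counts, so realized class fractions match the requested fractions
  to within one pixel.
* Gut-associated lymphoid tissue (GALT) polygons render pale (stain-poor)
  in both layers.
* The delivered HID-AB raster is the unshifted render translated by an
  integer (dx, dy), emulating the stage offset between the two capture
  sessions; vacated margins are filled with the HID-AB background color.

All randomness flows from the spec's single seed; identical specs produce
bit-identical rasters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from cryptometry._util import as_uint8, check_rgb, luminance

# ---------------------------------------------------------------------------
# Phantom palette (8-bit RGB).  The HID / AB / unstained colors are chosen to
# sit comfortably inside the default HSV gates of the mucin segmenter:
# HID hue ~24 deg at value ~0.36, AB hue ~221 deg at saturation ~0.8,
# unstained near-white (saturation ~0.04).
METH_BG = np.array([186.0, 198.0, 224.0])
METH_FOCUS_DARK = np.array([24.0, 34.0, 92.0])
METH_LUMEN = np.array([8.0, 12.0, 40.0])
GALT_PALE = np.array([232.0, 230.0, 218.0])
HIDAB_BG = np.array([148.0, 104.0, 66.0])
HID_BROWN = np.array([92.0, 51.0, 23.0])
AB_BLUE = np.array([40.0, 90.0, 200.0])
UNSTAINED_WHITE = np.array([244.0, 240.0, 234.0])

#: Amplitude (8-bit units) of the shared normal-crypt lattice texture.
LATTICE_AMPLITUDE = 10.0

CRYPT_SHAPES = ("round", "slit", "spiral")

_GOLDEN_ANGLE = 2.399963229728653  # radians; sunflower lumen layout


@dataclass(frozen=True)
class FocusSpec:
    """Geometry and staining of one synthetic ACF.

    ``center`` is (x, y) in pixels; radii are in microns and converted by
    the parent :class:`PhantomSpec` pixel size.  ``mucin_fractions`` is
    (f_HID, f_AB, f_unstained) and must sum to 1.
    """

    center: tuple[float, float]
    radius_um: float
    n_crypts: int
    crypt_radius_um: float
    crypt_shape: str = "round"
    darkness: float = 0.6
    mucin_fractions: tuple[float, float, float] = (0.6, 0.3, 0.1)

    def validate(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("focus radius_um must be positive")
        if self.n_crypts < 0:
            raise ValueError("n_crypts must be >= 0")
        if self.n_crypts and self.crypt_radius_um <= 0:
            raise ValueError("crypt_radius_um must be positive")
        if self.crypt_shape not in CRYPT_SHAPES:
            raise ValueError(f"crypt_shape must be one of {CRYPT_SHAPES}")
        if not 0.0 <= self.darkness <= 1.0:
            raise ValueError("darkness must lie in [0, 1]")
        f = np.asarray(self.mucin_fractions, dtype=float)
        if f.shape != (3,) or np.any(f < -1e-9) or np.any(f > 1 + 1e-9):
            raise ValueError("mucin fractions must each lie in [0, 1]")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("mucin fractions must sum to 1 (+/-1e-9)")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic dual-stain whole mount."""

    shape: tuple[int, int] = (256, 256)  # (height, width) pixels
    pixel_size_um: float = 2.0
    seed: int = 0
    foci: tuple[FocusSpec, ...] = ()
    galt: tuple[tuple[tuple[float, float], ...], ...] = ()  # polygons, (x, y)
    layer_shift: tuple[int, int] = (0, 0)  # (dx, dy) of the HID-AB capture
    crypt_spacing_um: float = 50.0  # background lattice period
    noise_sd: float = 3.0  # additive Gaussian noise, 8-bit units
    mdf_threshold: float = 85.0  # percent unstained defining truth MDF

    def __post_init__(self):
        object.__setattr__(self, "foci", tuple(self.foci))
        object.__setattr__(
            self, "galt", tuple(tuple(map(tuple, g)) for g in self.galt)
        )

    def validate(self) -> None:
        h, w = self.shape
        if h <= 0 or w <= 0:
            raise ValueError("image shape must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for f in self.foci:
            f.validate()
            r = f.radius_um / self.pixel_size_um
            x, y = f.center
            if x - r < 0 or y - r < 0 or x + r > w - 1 or y + r > h - 1:
                raise ValueError(
                    f"focus at {f.center} (radius {r:.1f} px) exceeds image bounds"
                )
        # Foci are distinct lesions: disks must not overlap (small gap so
        # polygonized outlines stay disjoint too).
        for i in range(len(self.foci)):
            for j in range(i + 1, len(self.foci)):
                a, b = self.foci[i], self.foci[j]
                d = np.hypot(
                    a.center[0] - b.center[0], a.center[1] - b.center[1]
                )
                ra = a.radius_um / self.pixel_size_um
                rb = b.radius_um / self.pixel_size_um
                if d <= ra + rb + 2.0:
                    raise ValueError(f"foci {i} and {j} overlap")
        for poly in self.galt:
            pts = np.asarray(poly, dtype=float)
            if pts.ndim != 2 or pts.shape[0] < 3:
                raise ValueError("GALT polygon needs >= 3 vertices")
            if (
                pts[:, 0].min() < 0
                or pts[:, 1].min() < 0
                or pts[:, 0].max() > w - 1
                or pts[:, 1].max() > h - 1
            ):
                raise ValueError("GALT polygon exceeds image bounds")


@dataclass
class PhantomBundle:
    """Rendered layers plus every piece of ground truth."""

    spec: PhantomSpec
    methylene: np.ndarray  # (H, W, 3) uint8
    hidab: np.ndarray  # (H, W, 3) uint8, shifted by spec.layer_shift
    acf_labels: np.ndarray  # (H, W) uint16; 0 background, k = focus k
    crypt_labels: np.ndarray  # (H, W) uint16; global crypt ids
    galt_mask: np.ndarray  # (H, W) bool
    truth: pd.DataFrame  # one row per focus

    def hidab_unshifted(self) -> np.ndarray:
        """HID-AB render aligned to the methylene layer (undo the shift)."""
        from cryptometry.overlay import apply_shift

        dx, dy = self.spec.layer_shift
        return apply_shift(self.hidab, -dx, -dy, fill=tuple(HIDAB_BG.astype(int)))


# ---------------------------------------------------------------------------
# Geometry helpers


def _disk_mask(shape, center, radius_px):
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    cx, cy = center
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2


def _polygon_mask(shape, poly):
    import shapely

    h, w = shape
    pts = np.asarray(poly, dtype=float)
    geom = shapely.Polygon(pts)
    x0, y0, x1, y1 = geom.bounds
    r0, r1 = max(0, int(np.floor(y0))), min(h - 1, int(np.ceil(y1)))
    c0, c1 = max(0, int(np.floor(x0))), min(w - 1, int(np.ceil(x1)))
    mask = np.zeros(shape, dtype=bool)
    if r1 < r0 or c1 < c0:
        return mask
    yy, xx = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    inside = shapely.covers(geom, shapely.points(xx.ravel(), yy.ravel()))
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside.reshape(xx.shape)
    return mask


def _lumen_masks(spec: PhantomSpec, focus: FocusSpec) -> list[np.ndarray]:
    """Place n_crypts lumens inside the focus on a sunflower layout."""
    s = spec.pixel_size_um
    r_focus = focus.radius_um / s
    cr = focus.crypt_radius_um / s
    extent = {"round": cr, "slit": 2.3 * cr, "spiral": cr * 1.1}[focus.crypt_shape]
    r_avail = r_focus - extent - 1.5
    if focus.n_crypts == 0:
        return []
    if r_avail <= 0:
        raise ValueError("crypt lumens do not fit inside the focus")
    n = focus.n_crypts
    min_sep = 2 * extent + 1.5  # lumens disjoint and not 8-adjacent

    def _ring(n_ring, with_center):
        pts = []
        if with_center:
            pts.append((0.0, 0.0))
        th0 = 0.5  # fixed phase; layout is deterministic
        for i in range(n_ring):
            th = th0 + 2 * np.pi * i / n_ring
            pts.append((r_avail * np.cos(th), r_avail * np.sin(th)))
        return pts

    def _ok(pts):
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if np.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1]) <= min_sep:
                    return False
        return True

    # Prefer a single ring (maximal spacing); fall back to ring + center.
    centers = None
    if n == 1:
        centers = [(0.0, 0.0)]
    else:
        for layout in (_ring(n, False), _ring(n - 1, True)):
            if _ok(layout):
                centers = layout
                break
    if centers is None:
        raise ValueError(
            f"{n} crypts of shape '{focus.crypt_shape}' do not fit "
            "without merging; enlarge the focus or shrink the lumens"
        )
    centers = [
        (focus.center[0] + px, focus.center[1] + py) for px, py in centers
    ]
    masks = []
    h, w = spec.shape
    for i, (cx, cy) in enumerate(centers):
        if focus.crypt_shape == "round":
            m = _disk_mask(spec.shape, (cx, cy), cr)
        elif focus.crypt_shape == "slit":
            ang = i * _GOLDEN_ANGLE
            a, b = 2.2 * cr, max(0.45 * cr, 0.8)
            yy, xx = np.ogrid[:h, :w]
            u = (xx - cx) * np.cos(ang) + (yy - cy) * np.sin(ang)
            v = -(xx - cx) * np.sin(ang) + (yy - cy) * np.cos(ang)
            m = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        else:  # spiral: disks stamped along an Archimedean arc
            m = np.zeros(spec.shape, dtype=bool)
            t = np.linspace(0.0, 2.5 * np.pi, 40)
            radius = cr * t / t[-1]
            stamp = max(0.35 * cr, 0.9)
            for tk, rk in zip(t, radius):
                m |= _disk_mask(
                    spec.shape,
                    (cx + rk * np.cos(tk + i), cy + rk * np.sin(tk + i)),
                    stamp,
                )
        masks.append(m)
    return masks


def _sector_classes(mask: np.ndarray, center, fractions) -> np.ndarray:
    """Partition a focus mask into HID(1)/AB(2)/unstained(3) sectors.

    Pixels are ordered by angle about the focus center and cut at exact
    pixel counts, so realized fractions equal the requested ones to within
    a single pixel.
    """
    ys, xs = np.nonzero(mask)
    n = len(ys)
    ang = np.arctan2(ys - center[1], xs - center[0])
    order = np.lexsort((xs, ys, ang))
    f = np.asarray(fractions, dtype=float)
    n_hid = int(np.floor(f[0] * n + 0.5))
    n_ab = int(np.floor(f[1] * n + 0.5))
    n_ab = min(n_ab, n - n_hid)
    out = np.zeros(mask.shape, dtype=np.uint8)
    idx = order
    out[ys[idx[:n_hid]], xs[idx[:n_hid]]] = 1
    out[ys[idx[n_hid : n_hid + n_ab]], xs[idx[n_hid : n_hid + n_ab]]] = 2
    out[ys[idx[n_hid + n_ab :]], xs[idx[n_hid + n_ab :]]] = 3
    return out


# ---------------------------------------------------------------------------
# Whole-mount rendering


def _lattice(shape, period_px):
    """Shared normal-crypt texture: product of two phase-shifted cosines."""
    h, w = shape
    yy, xx = np.mgrid[:h, :w]
    k = 2 * np.pi / max(period_px, 2.0)
    return 0.5 * (np.cos(k * xx) + np.cos(k * yy + 1.3))


def gen_wholemount(spec: PhantomSpec) -> PhantomBundle:
    """Render a dual-stain phantom whole mount with full ground truth.

    Returns a :class:`PhantomBundle` whose ``truth`` table carries, per
    focus: true area (µm², from the rasterized label map), crypt count,
    requested and realized mucin fractions, and the truth MDF flag
    (requested unstained fraction ≥ ``spec.mdf_threshold`` percent).
    """
    spec.validate()
    h, w = spec.shape
    s = spec.pixel_size_um
    rng = np.random.default_rng(spec.seed)

    acf_labels = np.zeros((h, w), dtype=np.uint16)
    crypt_labels = np.zeros((h, w), dtype=np.uint16)
    galt_mask = np.zeros((h, w), dtype=bool)
    for poly in spec.galt:
        galt_mask |= _polygon_mask((h, w), poly)

    lattice = _lattice((h, w), spec.crypt_spacing_um / s)

    meth = np.empty((h, w, 3), dtype=np.float64)
    meth[:] = METH_BG
    meth += (LATTICE_AMPLITUDE * lattice)[..., None]

    hidab = np.empty((h, w, 3), dtype=np.float64)
    hidab[:] = HIDAB_BG
    hidab += (LATTICE_AMPLITUDE * lattice)[..., None]

    meth[galt_mask] = GALT_PALE
    hidab[galt_mask] = GALT_PALE

    rows = []
    crypt_id = 0
    for k, focus in enumerate(spec.foci, start=1):
        r_px = focus.radius_um / s
        fmask = _disk_mask((h, w), focus.center, r_px)
        acf_labels[fmask] = k

        # Methylene: flat focus color scaled by darkness, lumens darker.
        t = 0.3 + 0.7 * focus.darkness
        meth[fmask] = (1 - t) * METH_BG + t * METH_FOCUS_DARK
        lumens = _lumen_masks(spec, focus)
        for lm in lumens:
            crypt_id += 1
            crypt_labels[lm] = crypt_id
            meth[lm] = METH_LUMEN

        # HID-AB: angular-sector partition into the three mucin classes.
        classes = _sector_classes(fmask, focus.center, focus.mucin_fractions)
        hidab[classes == 1] = HID_BROWN
        hidab[classes == 2] = AB_BLUE
        hidab[classes == 3] = UNSTAINED_WHITE

        npx = int(fmask.sum())
        f_hid, f_ab, f_un = focus.mucin_fractions
        rows.append(
            {
                "focus_id": k,
                "center_x": focus.center[0],
                "center_y": focus.center[1],
                "radius_um": focus.radius_um,
                "crypt_shape": focus.crypt_shape,
                "darkness": focus.darkness,
                "true_area_um2": npx * s * s,
                "true_crypt_count": focus.n_crypts,
                "f_hid": f_hid,
                "f_ab": f_ab,
                "f_unstained": f_un,
                "realized_f_hid": (classes == 1).sum() / npx,
                "realized_f_ab": (classes == 2).sum() / npx,
                "realized_f_unstained": (classes == 3).sum() / npx,
                "true_mdf": bool(100.0 * f_un >= spec.mdf_threshold),
            }
        )

    if spec.noise_sd > 0:
        meth += rng.normal(0.0, spec.noise_sd, meth.shape)
        hidab += rng.normal(0.0, spec.noise_sd, hidab.shape)

    meth8 = as_uint8(meth)
    hidab8 = as_uint8(hidab)

    from cryptometry.overlay import apply_shift

    dx, dy = spec.layer_shift
    hidab8 = apply_shift(hidab8, dx, dy, fill=tuple(HIDAB_BG.astype(int)))

    truth = pd.DataFrame(
        rows,
        columns=[
            "focus_id",
            "center_x",
            "center_y",
            "radius_um",
            "crypt_shape",
            "darkness",
            "true_area_um2",
            "true_crypt_count",
            "f_hid",
            "f_ab",
            "f_unstained",
            "realized_f_hid",
            "realized_f_ab",
            "realized_f_unstained",
            "true_mdf",
        ],
    )
    return PhantomBundle(
        spec=spec,
        methylene=meth8,
        hidab=hidab8,
        acf_labels=acf_labels,
        crypt_labels=crypt_labels,
        galt_mask=galt_mask,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Focus stacks and tile grids


def gen_focus_stack(sharp, n_planes, blur_sigmas, in_focus_map):
    """Emulate a Z stack: plane k is sharp where ``in_focus_map == k`` and
    Gaussian-blurred with ``blur_sigmas[k]`` elsewhere."""
    sharp = check_rgb(sharp, "sharp")
    if n_planes < 1:
        raise ValueError("a focus stack needs at least one plane")
    if len(blur_sigmas) != n_planes:
        raise ValueError("blur_sigmas length must equal n_planes")
    if any(sg < 0 for sg in blur_sigmas):
        raise ValueError("blur sigmas must be non-negative")
    fmap = np.asarray(in_focus_map)
    if fmap.shape != sharp.shape[:2]:
        raise ValueError("in_focus_map shape must match the image")
    if fmap.max(initial=0) >= n_planes:
        raise ValueError("in_focus_map assigns a plane index >= n_planes")
    planes = []
    src = sharp.astype(np.float64)
    for k in range(n_planes):
        sg = blur_sigmas[k]
        if sg == 0:
            blurred = src.copy()
        else:
            blurred = np.stack(
                [ndi.gaussian_filter(src[..., c], sg) for c in range(3)], axis=-1
            )
        plane = np.where((fmap == k)[..., None], src, blurred)
        planes.append(as_uint8(plane))
    return planes


def gen_tiles(image, grid, overlap_px=0):
    """Cut an image into a (rows, cols) grid of overlapping tiles.

    Returns ``[(tile, (row, col), (y, x)), ...]`` in row-major order where
    (y, x) is the tile origin on the source canvas.  The grid must divide
    the image exactly given the overlap: with tile extent ``t`` and
    overlap ``o``, ``rows*t - (rows-1)*o`` must equal the image height
    (likewise for width).
    """
    image = np.asarray(image)
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise ValueError("grid must be at least (1, 1)")
    if overlap_px < 0:
        raise ValueError("overlap_px must be >= 0")
    h, w = image.shape[:2]

    def _extent(total, n):
        num = total + (n - 1) * overlap_px
        if num % n:
            raise ValueError(
                f"grid {grid} with overlap {overlap_px} does not divide "
                f"the {h}x{w} image exactly"
            )
        return num // n

    th, tw = _extent(h, rows), _extent(w, cols)
    if overlap_px >= th or overlap_px >= tw:
        raise ValueError("overlap must be smaller than the tile extent")
    out = []
    for r in range(rows):
        y = r * (th - overlap_px)
        for c in range(cols):
            x = c * (tw - overlap_px)
            out.append((image[y : y + th, x : x + tw].copy(), (r, c), (y, x)))
    return out


def random_spec(seed: int, shape=(192, 192), max_foci: int = 2, **overrides) -> PhantomSpec:
    """Sample a small feasible phantom spec for randomized property suites.

    Foci geometry is sampled so crypt lumens always fit their focus
    (lumen radius ≥ 3 px at the 2 µm/px default), centers stay inside the
    frame, and foci keep a clearance gap; the inter-layer shift is drawn
    from ±6 px.  Fully determined by ``seed``.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    px = overrides.get("pixel_size_um", 2.0)
    n_foci = int(rng.integers(1, max_foci + 1))
    foci: list[FocusSpec] = []
    for _ in range(n_foci):
        for _attempt in range(50):
            shape_kind = rng.choice(CRYPT_SHAPES)
            if shape_kind == "slit":
                n_crypts = int(rng.integers(2, 5))
                radius_px = rng.uniform(35.0, 42.0)
                crypt_r_px = rng.uniform(3.0, 5.0)
            else:
                n_crypts = int(rng.integers(3, 8))
                radius_px = rng.uniform(28.0, 42.0)
                crypt_r_px = rng.uniform(3.0, 5.5)
            margin = radius_px + 3.0
            if 2 * margin >= min(h, w):
                continue
            cx = rng.uniform(margin, w - 1 - margin)
            cy = rng.uniform(margin, h - 1 - margin)
            clear = all(
                np.hypot(cx - f.center[0], cy - f.center[1])
                > radius_px + f.radius_um / px + 4.0
                for f in foci
            )
            if not clear:
                continue
            f_un = rng.uniform(0.0, 1.0)
            f_hid = rng.uniform(0.0, 1.0 - f_un)
            cand = FocusSpec(
                center=(cx, cy),
                radius_um=radius_px * px,
                n_crypts=n_crypts,
                crypt_radius_um=crypt_r_px * px,
                crypt_shape=str(shape_kind),
                darkness=rng.uniform(0.45, 0.9),
                mucin_fractions=(f_hid, 1.0 - f_un - f_hid, f_un),
            )
            try:
                spec_try = PhantomSpec(
                    shape=shape,
                    pixel_size_um=px,
                    foci=tuple(foci) + (cand,),
                )
                spec_try.validate()
                _lumen_masks(spec_try, cand)  # lumens must fit
            except ValueError:
                continue
            foci.append(cand)
            break
    dx, dy = int(rng.integers(-6, 7)), int(rng.integers(-6, 7))
    kw = dict(
        shape=shape,
        pixel_size_um=px,
        seed=int(rng.integers(0, 2**31 - 1)),
        foci=tuple(foci),
        layer_shift=(dx, dy),
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


def default_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """A realistic single-mount default: 320x320 px at 2 µm/px with three
    foci spanning the crypt shapes and mucin profiles, one GALT region,
    and a modest stage shift between the stain captures."""
    foci = (
        FocusSpec((80, 80), 90.0, 6, 10.0, "round", 0.65, (0.70, 0.20, 0.10)),
        FocusSpec((225, 95), 80.0, 5, 9.0, "slit", 0.55, (0.10, 0.55, 0.35)),
        FocusSpec((150, 230), 85.0, 4, 9.0, "spiral", 0.75, (0.02, 0.08, 0.90)),
    )
    galt = (((240.0, 200.0), (305.0, 205.0), (300.0, 265.0), (245.0, 270.0)),)
    spec = PhantomSpec(
        shape=(320, 320),
        pixel_size_um=2.0,
        seed=seed,
        foci=foci,
        galt=galt,
        layer_shift=(7, -3),
    )
    return replace(spec, **overrides) if overrides else spec
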