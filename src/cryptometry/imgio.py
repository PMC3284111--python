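"""I/O for rasters, ROI geometry, project manifests, and result tables.

Coordinate conventions (used package-wide):

* Rasters are row-major with origin at the top-left pixel, 0-based
  indices, pixel-center addressing: pixel (row r, col c) covers the point
  (x, y) = (c, r).
* Polygons are vertex lists in (x, y) = (col, row) pixel coordinates and
  are closed implicitly (last vertex joins the first).
* Bounding boxes are 0-based and half-open: (r0, r1, c0, c1).

ROI geometry is stored as GeoJSON-flavored polygon files (pixel units, no
CRS), one feature per region with ``role`` ("acf" or "galt") and a stable
integer ``id``.  A painted-outline raster importer is provided for parity
with pencil-tool circumscription workflows.  The project manifest is
YAML (or JSON) and replaces proprietary layered-image formats.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
import yaml
from PIL import Image

SEGMENTS = ("ascending", "transverse", "descending")
LAYER_NAMES = ("methylene", "hidab", "he")
ROI_ROLES = ("acf", "galt")

#: Column order of the per-ACF results table: identity, geometry flags,
#: then the full morphometric + mucin measurement battery.
ACF_ID_COLUMNS = ["rat_id", "segment", "focus_id", "galt_overlap", "galt_peripheral"]


# ---------------------------------------------------------------------------
# Rasters


def read_raster(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3 and arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"{path}: rasters must be 8-bit RGB or 8/16-bit gray")
    return arr


def write_raster(path, arr) -> None:
    path = Path(path)
    arr = np.asarray(arr)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


# ---------------------------------------------------------------------------
# ROI geometry


@dataclass(frozen=True)
class Roi:
    """One closed polygon region with a stable integer id."""

    id: int
    role: str
    vertices: tuple[tuple[float, float], ...]  # (x, y) pixel coordinates

    def __post_init__(self):
        object.__setattr__(self, "vertices", tuple(map(tuple, self.vertices)))

    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)

    def validate(self) -> None:
        if self.role not in ROI_ROLES:
            raise ValueError(f"ROI role must be one of {ROI_ROLES}")
        if len(self.vertices) < 3:
            raise ValueError(f"ROI {self.id}: a polygon needs >= 3 vertices")
        poly = self.polygon()
        if not poly.is_valid or not poly.is_simple:
            raise ValueError(f"ROI {self.id}: polygon is self-intersecting")


@dataclass
class RoiSet:
    rois: list[Roi] = field(default_factory=list)

    def validate(self) -> None:
        ids = [r.id for r in self.rois]
        if len(ids) != len(set(ids)):
            raise ValueError("ROI ids must be unique")
        for r in self.rois:
            r.validate()

    def by_role(self, role: str) -> "RoiSet":
        return RoiSet([r for r in self.rois if r.role == role])

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)


def write_rois(rois: RoiSet, path) -> None:
    features = []
    for r in rois:
        ring = list(map(list, r.vertices))
        if ring[0] != ring[-1]:
            ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "properties": {"id": r.id, "role": r.role},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_rois(path) -> RoiSet:
    data = json.loads(Path(path).read_text())
    rois = []
    for feat in data.get("features", []):
        geom = feat["geometry"]
        if geom["type"] != "Polygon":
            raise ValueError(f"{path}: only Polygon features are supported")
        ring = geom["coordinates"][0]
        if len(ring) > 1 and ring[0] == ring[-1]:
            ring = ring[:-1]
        props = feat.get("properties", {})
        rois.append(
            Roi(
                id=int(props["id"]),
                role=str(props["role"]),
                vertices=tuple(map(tuple, ring)),
            )
        )
    out = RoiSet(rois)
    out.validate()
    return out


def outline_raster_to_rois(
    raster, outline_color, role="acf", tolerance=40
) -> RoiSet:
    """Import a painted-outline raster (pencil-tool circumscription).

    Pixels within ``tolerance`` (Chebyshev distance per channel) of
    ``outline_color`` are treated as outline ink.  Each closed outline
    encloses one region; enclosed areas (interior plus the ink itself,
    matching the convention that the drawn border belongs to the focus)
    are polygonized.  Ids are assigned in raster scan order, starting at 1.
    """
    from skimage import measure
    from scipy import ndimage as ndi

    arr = np.asarray(raster)
    ink = np.all(
        np.abs(arr.astype(int) - np.asarray(outline_color, dtype=int)) <= tolerance,
        axis=-1,
    )
    # Everything not reachable from the border without crossing ink is
    # enclosed; enclosed + ink = the circumscribed regions.
    filled = ndi.binary_fill_holes(ink)
    labels, n = ndi.label(filled, structure=np.ones((3, 3), dtype=int))
    rois = []
    next_id = 1
    for k in range(1, n + 1):
        mask = labels == k
        if mask.sum() == ink[labels == k].sum():  # ink blob enclosing nothing
            continue
        for verts in mask_to_polygons(mask):
            rois.append(Roi(id=next_id, role=role, vertices=verts))
            next_id += 1
    out = RoiSet(rois)
    out.validate()
    return out


def mask_to_polygons(mask) -> list[tuple[tuple[float, float], ...]]:
    """Polygonize a binary mask: one polygon per connected region, traced
    along the half-pixel iso-contour so that rasterizing the polygon with
    pixel-center coverage reproduces the mask exactly (regions without
    holes)."""
    from skimage import measure

    padded = np.pad(np.asarray(mask, dtype=float), 1)
    contours = measure.find_contours(padded, 0.5)
    polys = []
    for cont in contours:
        if len(cont) < 4:
            continue
        # (row, col) -> (x, y); subtract the pad offset
        verts = [(c - 1.0, r - 1.0) for r, c in cont[:-1]]
        poly = shapely.Polygon(verts)
        if poly.area < 0.5:
            continue
        # keep outer boundaries only (holes are traced clockwise by
        # find_contours' orientation convention relative to outers)
        polys.append(tuple(verts))
    # Outer contours enclose more area; if a region has holes we keep the
    # largest contour per region.  Simple regions yield one contour each.
    return polys


# ---------------------------------------------------------------------------
# Project manifest


@dataclass
class LayerEntry:
    name: str
    path: str
    shift: tuple[int, int] = (0, 0)  # registered (dx, dy) vs methylene


@dataclass
class ProjectManifest:
    """Open description of one whole-mount project: identity, calibration,
    stain layers with registered shifts, and ROI files."""

    rat_id: str
    segment: str
    pixel_size_um: float
    layers: list[LayerEntry] = field(default_factory=list)
    roi_files: dict = field(default_factory=dict)  # role -> path
    notes: str = ""

    def validate(self) -> None:
        if self.segment not in SEGMENTS:
            raise ValueError(
                f"segment must be one of {SEGMENTS}, got {self.segment!r}"
            )
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        names = [ly.name for ly in self.layers]
        for nm in names:
            if nm not in LAYER_NAMES:
                raise ValueError(f"unknown layer name {nm!r}")
        if names.count("methylene") != 1:
            raise ValueError("exactly one methylene layer is required")
        for nm in ("hidab", "he"):
            if names.count(nm) > 1:
                raise ValueError(f"at most one {nm!r} layer is allowed")
        for role in self.roi_files:
            if role not in ROI_ROLES:
                raise ValueError(f"unknown ROI role {role!r}")

    def layer(self, name: str) -> LayerEntry:
        for ly in self.layers:
            if ly.name == name:
                return ly
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "rat_id": self.rat_id,
            "segment": self.segment,
            "pixel_size_um": float(self.pixel_size_um),
            "layers": [
                {"name": ly.name, "path": str(ly.path), "shift": list(ly.shift)}
                for ly in self.layers
            ],
            "roi_files": {k: str(v) for k, v in self.roi_files.items()},
            "notes": self.notes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectManifest":
        return cls(
            rat_id=str(d["rat_id"]),
            segment=str(d["segment"]),
            pixel_size_um=float(d["pixel_size_um"]),
            layers=[
                LayerEntry(
                    name=e["name"],
                    path=e["path"],
                    shift=tuple(e.get("shift", (0, 0))),
                )
                for e in d.get("layers", [])
            ],
            roi_files=dict(d.get("roi_files", {})),
            notes=str(d.get("notes", "")),
        )


def write_manifest(manifest: ProjectManifest, path) -> None:
    manifest.validate()
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(manifest.to_dict(), indent=1))
    else:
        path.write_text(yaml.safe_dump(manifest.to_dict(), sort_keys=False))


def read_manifest(path) -> ProjectManifest:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    m = ProjectManifest.from_dict(d)
    m.validate()
    return m


@dataclass
class ProjectBundle:
    manifest: ProjectManifest
    rasters: dict  # layer name -> np.ndarray
    rois: RoiSet


def load_project(manifest_path) -> ProjectBundle:
    """Read a manifest, its rasters, and its ROI files; validate that all
    layers share dimensions (declared shifts do not change raster size)."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    rasters = {}
    ref_shape = None
    for ly in manifest.layers:
        p = Path(ly.path)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise FileNotFoundError(f"layer {ly.name!r}: raster not found: {p}")
        arr = read_raster(p)
        if ref_shape is None:
            ref_shape = arr.shape[:2]
        elif arr.shape[:2] != ref_shape:
            raise ValueError(
                f"layer {ly.name!r} has dimensions {arr.shape[:2]}, "
                f"expected {ref_shape}"
            )
        rasters[ly.name] = arr
    rois = RoiSet()
    for role, rp in manifest.roi_files.items():
        p = Path(rp)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise FileNotFoundError(f"ROI file for role {role!r} not found: {p}")
        rois.rois.extend(read_rois(p).rois)
    rois.validate()
    return ProjectBundle(manifest=manifest, rasters=rasters, rois=rois)


# ---------------------------------------------------------------------------
# Result tables


def write_results(per_acf: pd.DataFrame, per_crypt: pd.DataFrame, out_dir) -> dict:
    """Write the per-ACF, per-crypt, and aggregate CSVs.

    ``per_acf`` has one row per focus with the identity columns
    (rat_id, segment, focus_id, GALT flags) followed by the measurement
    battery; ``per_crypt`` has one row per crypt (rat_id, segment,
    focus_id, crypt_id, area/perimeter/roundness/diameters).  The
    aggregate CSV groups per (rat, segment): focus count, MDF count, and
    measurement means.  Empty tables yield header-only CSVs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    acf_path = out_dir / "per_acf.csv"
    crypt_path = out_dir / "per_crypt.csv"
    agg_path = out_dir / "aggregate.csv"
    per_acf.to_csv(acf_path, index=False)
    per_crypt.to_csv(crypt_path, index=False)

    if len(per_acf):
        numeric = per_acf.select_dtypes("number").columns.difference(["focus_id"])
        g = per_acf.groupby(["rat_id", "segment"], sort=True)
        agg = g[list(numeric)].mean()
        agg.insert(0, "n_foci", g.size())
        if "MDF" in per_acf.columns:
            agg.insert(1, "n_mdf", g["MDF"].sum().astype(int))
        agg.reset_index().to_csv(agg_path, index=False)
    else:
        pd.DataFrame(columns=["rat_id", "segment", "n_foci", "n_mdf"]).to_csv(
            agg_path, index=False
        )
    return {"per_acf": acf_path, "per_crypt": crypt_path, "aggregate": agg_path}
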