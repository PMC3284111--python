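"""End-to-end pipeline: phantom → register → extract → morph → mucin → stats.

A single YAML/JSON config drives the run; every stage writes its
artifacts under the output directory and contributes to a run log
(parameters, seed, package version, artifact checksums) so a rerun with
an identical config is bit-identical for integer artifacts.  All
defaults that the original interactive workflow left unspecified live in
the config, so any divergence is visible and overridable.

Stage inputs: ``register``/``extract``/``morph``/``mucin`` consume the
project manifest (written by ``phantom`` or supplied via
``project: path``); ``morph`` and ``mucin`` rasterize the manifest's ACF
outlines themselves, so ``extract`` (which writes label maps and
excised-on-white TIFFs) is optional; ``stats`` consumes the per-ACF
records produced by ``morph``/``mucin`` in the same run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import cryptometry
from cryptometry import imgio, morphometry, mucin, overlay, phantom, roi, stats

STAGES = ("phantom", "register", "extract", "morph", "mucin", "stats")

FLOAT_FORMAT = "%.6g"


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _phantom_spec_from_config(cfg: dict, seed: int) -> phantom.PhantomSpec:
    spec = phantom.default_spec(seed)
    kw = {}
    for key in (
        "shape",
        "pixel_size_um",
        "layer_shift",
        "crypt_spacing_um",
        "noise_sd",
        "mdf_threshold",
    ):
        if key in cfg:
            val = cfg[key]
            kw[key] = tuple(val) if isinstance(val, list) else val
    if "foci" in cfg:
        kw["foci"] = tuple(
            phantom.FocusSpec(
                center=tuple(f["center"]),
                radius_um=f["radius_um"],
                n_crypts=f.get("n_crypts", 0),
                crypt_radius_um=f.get("crypt_radius_um", 10.0),
                crypt_shape=f.get("crypt_shape", "round"),
                darkness=f.get("darkness", 0.6),
                mucin_fractions=tuple(f.get("mucin_fractions", (0.6, 0.3, 0.1))),
            )
            for f in cfg["foci"]
        )
    if "galt" in cfg:
        kw["galt"] = tuple(tuple(map(tuple, g)) for g in cfg["galt"])
    from dataclasses import replace

    return replace(spec, seed=seed, **kw)


def save_phantom_project(
    bundle: phantom.PhantomBundle, out_dir, rat_id="phantom-rat", segment="descending"
) -> Path:
    """Write a phantom bundle as a loadable project: layer TIFFs, truth
    label maps, truth table, ROI GeoJSON (polygonized truth), manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    imgio.write_raster(out / "methylene.tif", bundle.methylene)
    imgio.write_raster(out / "hidab.tif", bundle.hidab)
    imgio.write_raster(out / "truth_acf_labels.tif", bundle.acf_labels.astype(np.uint16))
    imgio.write_raster(out / "truth_crypt_labels.tif", bundle.crypt_labels.astype(np.uint16))
    imgio.write_raster(
        out / "truth_galt_mask.tif", bundle.galt_mask.astype(np.uint8) * 255
    )
    bundle.truth.to_csv(out / "truth.csv", index=False, float_format=FLOAT_FORMAT)

    rois = []
    for k in range(1, bundle.spec.foci.__len__() + 1):
        polys = imgio.mask_to_polygons(bundle.acf_labels == k)
        if not polys:
            raise RuntimeError(f"could not polygonize focus {k}")
        rois.append(imgio.Roi(id=k, role="acf", vertices=polys[0]))
    imgio.write_rois(imgio.RoiSet(rois), out / "acf_rois.json")
    galt_rois = [
        imgio.Roi(id=1000 + i, role="galt", vertices=g)
        for i, g in enumerate(bundle.spec.galt)
    ]
    imgio.write_rois(imgio.RoiSet(galt_rois), out / "galt_rois.json")

    manifest = imgio.ProjectManifest(
        rat_id=rat_id,
        segment=segment,
        pixel_size_um=bundle.spec.pixel_size_um,
        layers=[
            imgio.LayerEntry("methylene", "methylene.tif", (0, 0)),
            imgio.LayerEntry("hidab", "hidab.tif", (0, 0)),
        ],
        roi_files={"acf": "acf_rois.json", "galt": "galt_rois.json"},
        notes="synthetic phantom project",
    )
    mpath = out / "project.yaml"
    imgio.write_manifest(manifest, mpath)
    return mpath


def _build_masks(project: imgio.ProjectBundle) -> roi.AcfMaskSet:
    shape = project.rasters["methylene"].shape[:2]
    masks = roi.outlines_to_labels(project.rois.by_role("acf"), shape)
    galt = project.rois.by_role("galt")
    if len(galt):
        masks = roi.apply_galt(masks, galt)
    return masks


def _aligned_hidab(project: imgio.ProjectBundle) -> np.ndarray:
    entry = project.manifest.layer("hidab")
    dx, dy = entry.shift
    return overlay.apply_shift(
        project.rasters["hidab"], -dx, -dy, fill=(255, 255, 255)
    )


def run_pipeline(config, out_dir, seed: int | None = None) -> dict:
    """Run the requested stages; returns a dict of artifact paths.

    ``config`` is a mapping or a path to a YAML/JSON file.  Raises
    :class:`StageError` naming the failing (or missing producing) stage.
    """
    if not isinstance(config, dict):
        p = Path(config)
        text = p.read_text()
        config = (
            json.loads(text) if p.suffix.lower() == ".json" else yaml.safe_load(text)
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(config.get("seed", 0))
    stages = list(config.get("stages", STAGES))
    for st in stages:
        if st not in STAGES:
            raise StageError(st, "unknown stage")

    log: dict = {
        "package_version": cryptometry.__version__,
        "seed": seed,
        "stages": stages,
        "config": {k: v for k, v in config.items() if k != "stages"},
        "artifacts": {},
    }
    artifacts: dict = {}
    project: imgio.ProjectBundle | None = None
    manifest_path: Path | None = None
    per_acf: pd.DataFrame | None = None
    per_crypt: pd.DataFrame | None = None

    def _register_artifact(name, path):
        artifacts[name] = Path(path)
        log["artifacts"][name] = {
            "path": str(path),
            "sha256": _sha256(Path(path)),
        }

    if "phantom" in stages:
        spec = _phantom_spec_from_config(config.get("phantom", {}), seed)
        bundle = phantom.gen_wholemount(spec)
        pdir = out / "phantom"
        manifest_path = save_phantom_project(
            bundle,
            pdir,
            rat_id=config.get("phantom", {}).get("rat_id", "phantom-rat"),
            segment=config.get("phantom", {}).get("segment", "descending"),
        )
        for f in sorted(pdir.iterdir()):
            _register_artifact(f"phantom/{f.name}", f)
    elif "project" in config:
        manifest_path = Path(config["project"])

    def _need_project(stage: str) -> imgio.ProjectBundle:
        nonlocal project
        if project is None:
            if manifest_path is None or not manifest_path.exists():
                raise StageError(
                    stage,
                    "no project manifest available (produced by stage "
                    "'phantom', or supply 'project:' in the config)",
                )
            project = imgio.load_project(manifest_path)
        return project

    if "register" in stages:
        proj = _need_project("register")
        if "hidab" not in proj.rasters:
            raise StageError("register", "project has no hidab layer")
        rcfg = config.get("register", {})
        max_shift = int(rcfg.get("max_shift", 50))
        # Cross-stain registration correlates tissue edges, not raw
        # luminance: stain polarity differs between layers.
        channel = rcfg.get("channel", "gradient")
        dx, dy, score = overlay.estimate_shift(
            proj.rasters["methylene"], proj.rasters["hidab"], max_shift, channel
        )
        proj.manifest.layer("hidab").shift = (int(dx), int(dy))
        imgio.write_manifest(proj.manifest, manifest_path)
        _register_artifact("project.yaml", manifest_path)
        log["register"] = {"dx": int(dx), "dy": int(dy), "score": float(score)}

    if "extract" in stages:
        proj = _need_project("extract")
        masks = _build_masks(proj)
        edir = out / "extract"
        edir.mkdir(exist_ok=True)
        imgio.write_raster(edir / "acf_labels.tif", masks.labels.astype(np.uint16))
        white = roi.extract_on_white(proj.rasters["methylene"], masks)
        imgio.write_raster(edir / "methylene_acf_on_white.tif", white)
        if "hidab" in proj.rasters:
            hid = roi.extract_on_white(_aligned_hidab(proj), masks)
            imgio.write_raster(edir / "hidab_acf_on_white.tif", hid)
        for f in sorted(edir.iterdir()):
            _register_artifact(f"extract/{f.name}", f)

    if "morph" in stages:
        proj = _need_project("morph")
        masks = _build_masks(proj)
        mcfg = config.get("morph", {})
        params = morphometry.CryptParams(
            min_area_um2=float(mcfg.get("min_crypt_area_um2", 50.0)),
            threshold=mcfg.get("crypt_threshold"),
        )
        s = proj.manifest.pixel_size_um
        from cryptometry._util import luminance

        meth = proj.rasters["methylene"]
        lum = luminance(meth)
        rows = []
        crypt_rows = []
        qc_dir = out / "qc" if mcfg.get("qc", False) else None
        if qc_dir:
            qc_dir.mkdir(exist_ok=True)
        for k in range(1, masks.n_foci + 1):
            mask = masks.mask(k)
            crypts = morphometry.detect_crypts(lum, mask, s, params)
            meas = morphometry.measure_acf(meth, mask, crypts, s)
            g_ov, g_pe = masks.flags(k)
            rows.append(
                {
                    "rat_id": proj.manifest.rat_id,
                    "segment": proj.manifest.segment,
                    "focus_id": masks.roi_ids[k - 1],
                    "galt_overlap": g_ov,
                    "galt_peripheral": g_pe,
                    **meas.as_dict(),
                }
            )
            for j, cid in enumerate(crypts.ids, start=1):
                cm = morphometry._shape_metrics(crypts.component(cid), s)
                crypt_rows.append(
                    {
                        "rat_id": proj.manifest.rat_id,
                        "segment": proj.manifest.segment,
                        "focus_id": masks.roi_ids[k - 1],
                        "crypt_id": j,
                        "area_um2": cm["area"],
                        "perimeter_um": cm["perimeter"],
                        "roundness": cm["roundness"],
                        "max_diameter_um": cm["feret_max"],
                        "major_axis_um": cm["major_axis"],
                    }
                )
            if qc_dir:
                renders = morphometry.render_qc(meth * mask[..., None], crypts)
                imgio.write_raster(qc_dir / f"focus_{k:03d}_overlay.png", renders["overlay"])
                imgio.write_raster(
                    qc_dir / f"focus_{k:03d}_pseudo.png", renders["pseudo_color"]
                )
        per_acf = pd.DataFrame(rows)
        per_crypt = pd.DataFrame(
            crypt_rows,
            columns=[
                "rat_id",
                "segment",
                "focus_id",
                "crypt_id",
                "area_um2",
                "perimeter_um",
                "roundness",
                "max_diameter_um",
                "major_axis_um",
            ],
        )

    if "mucin" in stages:
        proj = _need_project("mucin")
        if "hidab" not in proj.rasters:
            raise StageError("mucin", "project has no hidab layer")
        masks = _build_masks(proj)
        mcfg = config.get("mucin", {})
        thr = mucin.MucinThresholds(**mcfg.get("thresholds", {}))
        mdf_thr = float(mcfg.get("mdf_threshold", mucin.MDF_THRESHOLD))
        aligned = _aligned_hidab(proj)
        mrows = []
        for k in range(1, masks.n_foci + 1):
            mask = masks.mask(k)
            cmap = mucin.segment_classes(aligned, mask, thr)
            percents = mucin.percent_areas(cmap)
            g_ov, _ = masks.flags(k)
            mrows.append(
                {
                    "focus_id": masks.roi_ids[k - 1],
                    "P_SULFOAREA": percents[0],
                    "P_SIALOAREA": percents[1],
                    "P_UAREA": percents[2],
                    "MDF": mucin.call_mdf(percents, g_ov, mdf_thr),
                    "stain_category": mucin.stain_category(percents).value,
                }
            )
        mdf = pd.DataFrame(mrows)
        if per_acf is None:
            proj2 = proj
            per_acf = pd.DataFrame(
                {
                    "rat_id": proj2.manifest.rat_id,
                    "segment": proj2.manifest.segment,
                    "focus_id": mdf["focus_id"],
                }
            )
            for col in morphometry.MEASUREMENT_COLUMNS:
                if col not in ("P_SULFOAREA", "P_SIALOAREA", "P_UAREA", "MDF"):
                    per_acf[col] = np.nan
        for col in ("P_SULFOAREA", "P_SIALOAREA", "P_UAREA", "MDF", "stain_category"):
            per_acf = per_acf.drop(columns=[col], errors="ignore")
        per_acf = per_acf.merge(mdf, on="focus_id", how="left")

    if per_acf is not None:
        if "MDF" not in per_acf.columns:
            per_acf["MDF"] = np.nan  # mucin stage skipped: empty-marked
        if per_crypt is None:
            per_crypt = pd.DataFrame(
                columns=[
                    "rat_id",
                    "segment",
                    "focus_id",
                    "crypt_id",
                    "area_um2",
                    "perimeter_um",
                    "roundness",
                    "max_diameter_um",
                    "major_axis_um",
                ]
            )
        rdir = out / "results"
        rdir.mkdir(exist_ok=True)
        per_acf_out = per_acf.copy()
        for c in per_acf_out.select_dtypes("float").columns:
            per_acf_out[c] = per_acf_out[c].map(
                lambda v: float(FLOAT_FORMAT % v) if pd.notna(v) else v
            )
        paths = imgio.write_results(per_acf_out, per_crypt, rdir)
        for name, pth in paths.items():
            _register_artifact(f"results/{name}", pth)

    if "stats" in stages:
        if per_acf is None or "MDF" not in per_acf.columns or per_acf["MDF"].isna().all():
            raise StageError(
                "stats",
                "no per-ACF records with MDF calls available (produced by "
                "stages 'morph' + 'mucin')",
            )
        scfg = config.get("stats", {})
        n_rats = int(scfg.get("n_rats", per_acf["rat_id"].nunique()))
        table = stats.StudyTable(per_acf)
        summary = stats.aggregate_by_segment(table, n_rats)
        sdir = out / "results"
        sdir.mkdir(exist_ok=True)
        summary.df.reset_index().to_csv(
            sdir / "segment_summary.csv", index=False, float_format=FLOAT_FORMAT
        )
        idx, ordered = stats.mdf_index(summary)
        idx.rename_axis("segment").reset_index().to_csv(
            sdir / "mdf_index.csv", index=False, float_format=FLOAT_FORMAT
        )
        log["stats"] = {"mdf_index_ordered": ordered}
        if per_acf["CRYPTCOUNT"].notna().any():
            try:
                cmp_df = stats.compare_mdf(
                    table, int(scfg.get("min_crypts", stats.MIN_CRYPTS_DEFAULT))
                )
                cmp_df.reset_index().to_csv(
                    sdir / "mdf_comparison.csv", index=False, float_format=FLOAT_FORMAT
                )
                _register_artifact("results/mdf_comparison", sdir / "mdf_comparison.csv")
            except ValueError:
                pass
        _register_artifact("results/segment_summary", sdir / "segment_summary.csv")
        _register_artifact("results/mdf_index", sdir / "mdf_index.csv")

    (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    artifacts["run_log"] = out / "run_log.json"
    return artifacts
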