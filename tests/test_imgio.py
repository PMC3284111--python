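"""Manifest, ROI, raster, and results I/O round-trips and validation."""

import numpy as np
import pandas as pd
import pytest

from cryptometry import imgio, phantom
from cryptometry.pipeline import save_phantom_project


@pytest.fixture(scope="module")
def project_dir(tmp_path_factory, bundle):
    out = tmp_path_factory.mktemp("proj")
    save_phantom_project(bundle, out, rat_id="r1", segment="transverse")
    return out


class TestManifest:
    def test_round_trip_lossless(self, tmp_path):
        m = imgio.ProjectManifest(
            rat_id="r7",
            segment="ascending",
            pixel_size_um=2.5,
            layers=[
                imgio.LayerEntry("methylene", "m.tif", (0, 0)),
                imgio.LayerEntry("hidab", "h.tif", (7, -3)),
            ],
            roi_files={"acf": "acf.json"},
            notes="x",
        )
        p = tmp_path / "p.yaml"
        imgio.write_manifest(m, p)
        back = imgio.read_manifest(p)
        assert back.to_dict() == m.to_dict()

    def test_nonpositive_pixel_size_names_field(self):
        m = imgio.ProjectManifest(
            rat_id="r",
            segment="ascending",
            pixel_size_um=0.0,
            layers=[imgio.LayerEntry("methylene", "m.tif")],
        )
        with pytest.raises(ValueError, match="pixel_size_um"):
            m.validate()

    def test_unknown_segment_and_layer_rejected(self):
        with pytest.raises(ValueError, match="segment"):
            imgio.ProjectManifest(
                "r", "sigmoid", 1.0, [imgio.LayerEntry("methylene", "m.tif")]
            ).validate()
        with pytest.raises(ValueError, match="layer"):
            imgio.ProjectManifest(
                "r", "ascending", 1.0, [imgio.LayerEntry("methylene", "m"),
                                        imgio.LayerEntry("giemsa", "g")]
            ).validate()

    def test_exactly_one_methylene_layer(self):
        with pytest.raises(ValueError, match="methylene"):
            imgio.ProjectManifest("r", "ascending", 1.0, []).validate()


class TestLoadProject:
    def test_phantom_project_loads_cleanly(self, project_dir):
        proj = imgio.load_project(project_dir / "project.yaml")
        assert set(proj.rasters) == {"methylene", "hidab"}
        assert len(proj.rois.by_role("acf")) == 3
        assert len(proj.rois.by_role("galt")) == 1

    def test_missing_raster_reported(self, project_dir, tmp_path):
        m = imgio.read_manifest(project_dir / "project.yaml")
        m.layers[0].path = "nope.tif"
        p = tmp_path / "bad.yaml"
        imgio.write_manifest(m, p)
        with pytest.raises(FileNotFoundError, match="nope.tif"):
            imgio.load_project(p)

    def test_dimension_mismatch_reported(self, project_dir, tmp_path):
        m = imgio.read_manifest(project_dir / "project.yaml")
        narrow = imgio.read_raster(project_dir / "hidab.tif")[:, :-10]
        imgio.write_raster(tmp_path / "hidab.tif", narrow)
        imgio.write_raster(
            tmp_path / "methylene.tif",
            imgio.read_raster(project_dir / "methylene.tif"),
        )
        for roi_file in ("acf_rois.json", "galt_rois.json"):
            (tmp_path / roi_file).write_text((project_dir / roi_file).read_text())
        p = tmp_path / "p.yaml"
        imgio.write_manifest(m, p)
        with pytest.raises(ValueError, match="dimensions"):
            imgio.load_project(p)


class TestRois:
    def test_geojson_round_trip(self, tmp_path):
        rs = imgio.RoiSet(
            [
                imgio.Roi(1, "acf", ((0, 0), (10, 0), (10, 10), (0, 10))),
                imgio.Roi(2, "galt", ((20, 20), (30, 22), (25, 30))),
            ]
        )
        p = tmp_path / "rois.json"
        imgio.write_rois(rs, p)
        back = imgio.read_rois(p)
        assert [(r.id, r.role, r.vertices) for r in back] == [
            (r.id, r.role, tuple((float(x), float(y)) for x, y in r.vertices))
            for r in rs
        ]

    def test_duplicate_ids_rejected(self):
        rs = imgio.RoiSet(
            [
                imgio.Roi(1, "acf", ((0, 0), (5, 0), (5, 5))),
                imgio.Roi(1, "acf", ((10, 10), (15, 10), (15, 15))),
            ]
        )
        with pytest.raises(ValueError, match="unique"):
            rs.validate()

    def test_self_intersecting_polygon_rejected(self):
        bowtie = imgio.Roi(1, "acf", ((0, 0), (10, 10), (10, 0), (0, 10)))
        with pytest.raises(ValueError, match="self-intersect"):
            bowtie.validate()

    def test_outline_raster_importer_recovers_region(self, bundle):
        # paint the truth outline of focus 1 in pure red on the methylene layer
        from skimage.segmentation import find_boundaries

        img = bundle.methylene.copy()
        outline = find_boundaries(bundle.acf_labels == 1, mode="thick")
        img[outline] = (255, 0, 0)
        rs = imgio.outline_raster_to_rois(img, (255, 0, 0), tolerance=10)
        assert len(rs) == 1
        from cryptometry.roi import outlines_to_labels

        masks = outlines_to_labels(rs, img.shape[:2])
        got = masks.labels > 0
        truth = bundle.acf_labels == 1
        iou = (got & truth).sum() / (got | truth).sum()
        assert iou > 0.9


class TestResults:
    def _study(self, n_foci=1, n_crypts=3):
        from cryptometry.morphometry import MEASUREMENT_COLUMNS

        rows = []
        for i in range(n_foci):
            row = {
                "rat_id": "r1",
                "segment": "ascending",
                "focus_id": i + 1,
                "galt_overlap": False,
                "galt_peripheral": False,
            }
            row.update({c: float(i + 1) for c in MEASUREMENT_COLUMNS})
            row["CRYPTCOUNT"] = n_crypts
            row["MDF"] = False
            rows.append(row)
        from cryptometry.morphometry import MEASUREMENT_COLUMNS

        acf_cols = [
            "rat_id", "segment", "focus_id", "galt_overlap", "galt_peripheral",
        ] + MEASUREMENT_COLUMNS
        per_acf = pd.DataFrame(rows, columns=acf_cols)
        per_crypt = pd.DataFrame(
            [
                {
                    "rat_id": "r1",
                    "segment": "ascending",
                    "focus_id": 1,
                    "crypt_id": j + 1,
                    "area_um2": 100.0,
                    "perimeter_um": 40.0,
                    "roundness": 1.1,
                    "max_diameter_um": 12.0,
                    "major_axis_um": 11.0,
                }
                for j in range(n_crypts)
            ]
        )
        return per_acf, per_crypt

    def test_row_counts(self, tmp_path):
        per_acf, per_crypt = self._study(1, 3)
        paths = imgio.write_results(per_acf, per_crypt, tmp_path)
        assert len(pd.read_csv(paths["per_acf"])) == 1
        assert len(pd.read_csv(paths["per_crypt"])) == 3

    def test_empty_study_header_only(self, tmp_path):
        per_acf, per_crypt = self._study(0, 0)
        per_crypt = per_crypt.iloc[:0]
        paths = imgio.write_results(per_acf, per_crypt, tmp_path)
        assert len(pd.read_csv(paths["per_acf"])) == 0
        assert len(pd.read_csv(paths["aggregate"])) == 0

    def test_per_acf_round_trip_full_precision(self, tmp_path):
        per_acf, per_crypt = self._study(2)
        per_acf.loc[0, "ACF_AREA"] = 12345.678901234567
        paths = imgio.write_results(per_acf, per_crypt, tmp_path)
        back = pd.read_csv(paths["per_acf"])
        assert back.loc[0, "ACF_AREA"] == per_acf.loc[0, "ACF_AREA"]
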