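"""Crypt detection/editing, QC renders, and the measurement battery."""

import numpy as np
import pytest

from cryptometry import morphometry as mm
from cryptometry import phantom
from cryptometry._util import luminance


def analytic_disk(r, pad=8):
    n = 2 * (r + pad) + 1
    yy, xx = np.ogrid[:n, :n]
    return (xx - (r + pad)) ** 2 + (yy - (r + pad)) ** 2 <= r * r


class TestRoundnessFormula:
    def test_ideal_circle_is_exactly_one(self):
        r = 37.0
        assert mm.roundness(2 * np.pi * r, np.pi * r * r) == pytest.approx(1.0, abs=1e-12)

    def test_ideal_square_is_four_over_pi(self):
        s = 12.0
        assert mm.roundness(4 * s, s * s) == pytest.approx(4 / np.pi, abs=1e-12)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            mm.roundness(10.0, 0.0)


class TestDetectCrypts:
    def test_uniform_patch_finds_nothing(self):
        mask = analytic_disk(20)
        gray = np.full(mask.shape, 90.0)
        crypts = mm.detect_crypts(gray, mask, 2.0)
        assert crypts.count == 0

    def test_phantom_disk_lumens_counted(self, bundle):
        lum = luminance(bundle.methylene)
        for k, f in enumerate(bundle.spec.foci, start=1):
            crypts = mm.detect_crypts(lum, bundle.acf_labels == k, 2.0)
            assert crypts.count == f.n_crypts, f.crypt_shape

    def test_min_area_filter_drops_small_lumen(self):
        mask = analytic_disk(40)
        gray = np.full(mask.shape, 180.0)
        yy, xx = np.ogrid[: mask.shape[0], : mask.shape[1]]
        big = (xx - 30) ** 2 + (yy - 48) ** 2 <= 6**2
        small = (xx - 62) ** 2 + (yy - 48) ** 2 <= 1.5**2  # ~7 px < 12.5 px min
        gray[big | small] = 20.0
        params = mm.CryptParams(min_area_um2=50.0)
        crypts = mm.detect_crypts(gray, mask, 2.0, params)  # 50 um2 = 12.5 px
        assert crypts.count == 1
        assert not (crypts.labels[small]).any()

    def test_raising_min_area_never_increases_count(self, bundle):
        lum = luminance(bundle.methylene)
        mask = bundle.acf_labels == 1
        counts = [
            mm.detect_crypts(lum, mask, 2.0, mm.CryptParams(min_area_um2=a)).count
            for a in (10.0, 50.0, 200.0, 400.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mm.detect_crypts(np.zeros((10, 10)), np.zeros((10, 10), bool), 2.0)


class TestEditCrypts:
    @pytest.fixture()
    def two_disks(self):
        m = mm.CryptLabelMap((40, 60))
        yy, xx = np.ogrid[:40, :60]
        m.add((xx - 15) ** 2 + (yy - 20) ** 2 <= 36)
        m.add((xx - 40) ** 2 + (yy - 20) ** 2 <= 36)
        return m

    def test_toggle_is_involution_and_logged(self, two_disks):
        before = two_disks.labels.copy()
        out = mm.edit_crypts(two_disks, [("toggle", 1), ("toggle", 1)])
        assert np.array_equal(out.labels, before)
        assert len(out.edit_log) == 2

    def test_toggle_removes_component(self, two_disks):
        out = mm.edit_crypts(two_disks, [("toggle", 2)])
        assert out.count == 1

    def test_join_decrements_count(self, two_disks):
        out = mm.edit_crypts(two_disks, [("join", 1, 2)])
        assert out.count == 1
        assert (out.labels > 0).sum() == (two_disks.labels > 0).sum()

    def test_split_along_diameter_accounts_pixels(self, two_disks):
        parent = (two_disks.labels == 1).sum()
        out = mm.edit_crypts(two_disks, [("split", 1, [(15, 10), (15, 30)])])
        assert out.count == 3
        labs = out.labels
        cut = (two_disks.labels == 1) & (labs == 0)
        children = [(labs == k).sum() for k in np.unique(labs[labs > 0])]
        # original disk 2 is still present; its pixels unchanged
        assert sum(children) + cut.sum() == parent + (two_disks.labels == 2).sum()

    def test_unknown_id_and_non_separating_cut_rejected(self, two_disks):
        with pytest.raises(KeyError):
            mm.edit_crypts(two_disks, [("toggle", 99)])
        with pytest.raises(ValueError, match="separate"):
            mm.edit_crypts(two_disks, [("split", 1, [(0, 0), (1, 0)])])


class TestMeasureAcf:
    def test_rasterized_disk_matches_analytics(self):
        mask = analytic_disk(100)
        patch = np.full(mask.shape + (3,), 240, np.uint8)
        patch[mask] = (60, 60, 60)
        meas = mm.measure_acf(patch, mask, None, 1.0, white_point=255.0)
        assert meas.ACF_AREA == pytest.approx(np.pi * 100**2, rel=0.02)
        assert meas.ACF_ROUND == pytest.approx(1.0, abs=0.02)
        assert meas.ACF_DIAAVG == pytest.approx(200.0, rel=0.02)
        assert meas.ACF_PERIM == pytest.approx(2 * np.pi * 100, rel=0.02)
        assert meas.ACF_IOD / meas.ACF_AREA == pytest.approx(meas.ACF_DEN, abs=1e-12)

    def test_roundness_converges_under_refinement(self):
        r1 = mm.measure_acf(
            np.zeros(analytic_disk(60).shape + (3,), np.uint8),
            analytic_disk(60), None, 1.0, white_point=255.0,
        ).ACF_ROUND
        r2 = mm.measure_acf(
            np.zeros(analytic_disk(120).shape + (3,), np.uint8),
            analytic_disk(120), None, 1.0, white_point=255.0,
        ).ACF_ROUND
        assert abs(r2 - r1) / r1 < 0.01

    def test_measurement_identities_on_phantom(self, bundle):
        lum = luminance(bundle.methylene)
        s = bundle.spec.pixel_size_um
        for k in range(1, 4):
            mask = bundle.acf_labels == k
            crypts = mm.detect_crypts(lum, mask, s)
            meas = mm.measure_acf(bundle.methylene, mask, crypts, s)
            assert meas.ACF_EPIAREA == pytest.approx(meas.ACF_AREA - meas.C_SUMAREA)
            assert meas.ACF_IOD == pytest.approx(meas.ACF_AREA * meas.ACF_DEN)
            assert meas.C_AVGAREA * meas.CRYPTCOUNT == pytest.approx(meas.C_SUMAREA)
            assert meas.ACF_EPIAREA >= 0
            assert 0.0 <= meas.ACF_DEN <= 1.0

    def test_darker_focus_has_higher_density(self):
        mask = analytic_disk(30)
        light = np.full(mask.shape + (3,), 250, np.uint8)
        dark = light.copy()
        light[mask] = (150, 150, 150)
        dark[mask] = (40, 40, 40)
        dl = mm.measure_acf(light, mask, None, 1.0).ACF_DEN
        dd = mm.measure_acf(dark, mask, None, 1.0).ACF_DEN
        assert dd > dl

    def test_roundcat_bins(self):
        assert int(np.digitize(1.0, mm.ROUNDCAT_EDGES)) == 0
        assert int(np.digitize(1.5, mm.ROUNDCAT_EDGES)) == 1
        assert int(np.digitize(2.2, mm.ROUNDCAT_EDGES)) == 2
        assert int(np.digitize(3.0, mm.ROUNDCAT_EDGES)) == 3
        assert int(np.digitize(5.0, mm.ROUNDCAT_EDGES)) == 4

    def test_bad_calibration_rejected(self):
        mask = analytic_disk(10)
        with pytest.raises(ValueError, match="calibration|pixel_size"):
            mm.measure_acf(np.zeros(mask.shape + (3,), np.uint8), mask, None, 0.0)


class TestRenderQc:
    def test_constant_patch_flat_surface(self):
        patch = np.full((20, 20, 3), 99, np.uint8)
        out = mm.render_qc(patch)
        assert np.ptp(out["height"]) == 0

    def test_darker_pixel_strictly_taller(self):
        patch = np.full((4, 4, 3), 200, np.uint8)
        patch[1, 1] = (20, 20, 20)
        h = mm.render_qc(patch)["height"]
        assert h[1, 1] > h[0, 0]

    def test_overlay_red_equals_crypt_support(self, bundle):
        lum = luminance(bundle.methylene)
        mask = bundle.acf_labels == 1
        crypts = mm.detect_crypts(lum, mask, 2.0)
        out = mm.render_qc(bundle.methylene, crypts)["overlay"]
        red = np.all(out == (255, 0, 0), axis=-1)
        assert np.array_equal(red, crypts.labels > 0)
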