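"""Phantom generator: determinism, geometry truth, stacks, and tiles."""

import numpy as np
import pytest

from cryptometry import phantom
from cryptometry.phantom import FocusSpec, PhantomSpec


def focus(center=(60, 60), radius=80.0, n=4, f=(0.6, 0.3, 0.1), **kw):
    return FocusSpec(
        center=center,
        radius_um=radius,
        n_crypts=n,
        crypt_radius_um=kw.pop("crypt_radius_um", 9.0),
        mucin_fractions=f,
        **kw,
    )


class TestSpecValidation:
    def test_mucin_fractions_must_sum_to_one(self):
        spec = PhantomSpec(foci=(focus(f=(0.5, 0.3, 0.1)),))
        with pytest.raises(ValueError, match="sum to 1"):
            spec.validate()

    def test_geometry_outside_bounds_rejected(self):
        spec = PhantomSpec(shape=(128, 128), foci=(focus(center=(10, 64)),))
        with pytest.raises(ValueError, match="bounds"):
            spec.validate()

    def test_overlapping_foci_rejected(self):
        spec = PhantomSpec(
            shape=(256, 256),
            foci=(focus(center=(100, 100)), focus(center=(140, 100))),
        )
        with pytest.raises(ValueError, match="overlap"):
            spec.validate()


class TestWholemount:
    def test_zero_foci_gives_background_only(self):
        b = phantom.gen_wholemount(PhantomSpec(shape=(96, 96), foci=()))
        assert b.acf_labels.max() == 0
        assert b.crypt_labels.max() == 0
        assert len(b.truth) == 0

    def test_truth_label_count_matches_spec(self, bundle):
        assert bundle.acf_labels.max() == len(bundle.spec.foci)
        assert set(np.unique(bundle.acf_labels)) == {0, 1, 2, 3}

    def test_mdf_flag_from_unstained_fraction(self):
        spec = PhantomSpec(
            shape=(160, 160), foci=(focus(center=(80, 80), f=(0.05, 0.05, 0.90)),)
        )
        b = phantom.gen_wholemount(spec)
        assert bool(b.truth.loc[0, "true_mdf"]) is True
        spec2 = PhantomSpec(
            shape=(160, 160), foci=(focus(center=(80, 80), f=(0.1, 0.1, 0.80)),)
        )
        assert bool(phantom.gen_wholemount(spec2).truth.loc[0, "true_mdf"]) is False

    def test_seeded_determinism_bit_identical(self):
        a = phantom.gen_wholemount(phantom.default_spec(7))
        b = phantom.gen_wholemount(phantom.default_spec(7))
        assert np.array_equal(a.methylene, b.methylene)
        assert np.array_equal(a.hidab, b.hidab)
        assert np.array_equal(a.acf_labels, b.acf_labels)

    def test_foci_darker_than_background(self, bundle):
        from cryptometry._util import luminance

        lum = luminance(bundle.methylene)
        fg = lum[bundle.acf_labels > 0].mean()
        bg = lum[(bundle.acf_labels == 0) & ~bundle.galt_mask].mean()
        assert fg < bg - 30

    def test_truth_area_matches_analytic_disk(self, bundle):
        spec = bundle.spec
        for k, f in enumerate(spec.foci, start=1):
            r_px = f.radius_um / spec.pixel_size_um
            assert r_px >= 20
            analytic = np.pi * r_px**2 * spec.pixel_size_um**2
            got = bundle.truth.loc[k - 1, "true_area_um2"]
            assert abs(got - analytic) / analytic < 0.02

    def test_realized_mucin_fractions_match_spec(self, bundle):
        t = bundle.truth
        for col_r, col_s in [
            ("realized_f_hid", "f_hid"),
            ("realized_f_ab", "f_ab"),
            ("realized_f_unstained", "f_unstained"),
        ]:
            assert np.allclose(t[col_r], t[col_s], atol=0.005)

    def test_hidab_is_shifted_render(self, bundle):
        aligned = bundle.hidab_unshifted()
        # away from the margins, the re-aligned HID-AB focus colors must
        # land on the truth labels: the MDF focus is near-white there
        mdf_mask = bundle.acf_labels == 3
        assert aligned[mdf_mask].mean() > 180


class TestFocusStack:
    def test_single_plane_sigma_zero_is_identity(self, bundle):
        (plane,) = phantom.gen_focus_stack(
            bundle.methylene, 1, [0.0], np.zeros(bundle.methylene.shape[:2], int)
        )
        assert np.array_equal(plane, bundle.methylene)

    def test_in_focus_side_is_sharper(self, bundle):
        from cryptometry.composite import local_variance
        from cryptometry._util import luminance

        img = bundle.methylene
        h, w = img.shape[:2]
        fmap = np.zeros((h, w), int)
        fmap[:, w // 2 :] = 1
        planes = phantom.gen_focus_stack(img, 2, [3.0, 3.0], fmap)
        v0 = local_variance(luminance(planes[0]), 9)
        left, right = v0[:, : w // 2 - 9], v0[:, w // 2 + 9 :]
        assert left.mean() > right.mean()
        # plane 0 equals the sharp source on its in-focus half
        assert np.array_equal(planes[0][:, : w // 2], img[:, : w // 2])

    def test_fully_blurred_plane(self, bundle):
        img = bundle.methylene
        planes = phantom.gen_focus_stack(
            img, 2, [0.0, 5.0], np.zeros(img.shape[:2], int)
        )
        assert np.array_equal(planes[0], img)
        assert not np.array_equal(planes[1], img)

    def test_empty_stack_rejected(self, bundle):
        with pytest.raises(ValueError):
            phantom.gen_focus_stack(
                bundle.methylene, 0, [], np.zeros(bundle.methylene.shape[:2], int)
            )


class TestTiles:
    def test_single_tile_identity(self, bundle):
        tiles = phantom.gen_tiles(bundle.methylene, (1, 1), 0)
        assert len(tiles) == 1
        tile, rc, origin = tiles[0]
        assert rc == (0, 0) and origin == (0, 0)
        assert np.array_equal(tile, bundle.methylene)

    def test_disjoint_quadrants_partition(self, bundle):
        img = bundle.methylene
        tiles = phantom.gen_tiles(img, (2, 2), 0)
        canvas = np.zeros_like(img)
        for tile, _, (y, x) in tiles:
            canvas[y : y + tile.shape[0], x : x + tile.shape[1]] = tile
        assert np.array_equal(canvas, img)

    def test_overlapping_tiles_agree_on_shared_pixels(self, bundle):
        img = bundle.methylene
        tiles = phantom.gen_tiles(img, (2, 1), 10)
        (t0, _, (y0, _)), (t1, _, (y1, _)) = tiles
        shared0 = t0[y1 - y0 :]
        shared1 = t1[: t0.shape[0] - (y1 - y0)]
        assert np.array_equal(shared0, shared1)

    def test_each_tile_is_exact_crop(self, bundle):
        img = bundle.methylene
        for tile, _, (y, x) in phantom.gen_tiles(img, (2, 2), 10):
            assert np.array_equal(tile, img[y : y + tile.shape[0], x : x + tile.shape[1]])

    def test_bad_overlap_rejected(self, bundle):
        with pytest.raises(ValueError):
            phantom.gen_tiles(bundle.methylene, (2, 2), 320)
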