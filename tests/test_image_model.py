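import numpy as np
import pytest
import tifffile

from lipoquant.image_model import (
    BinaryMask,
    CellROI,
    ChannelCountMismatchError,
    MultiChannelImage,
    dilate_mask,
    mask_difference,
    mask_union,
    otsu_mask,
    rasterize_polygon_csv,
    read_image,
    subtract_background,
    write_image,
)

from conftest import disk_pixels, exhaustive_otsu_threshold


class TestReadImage:
    def test_two_page_roundtrip(self, tmp_path, rng):
        data = rng.integers(0, 4096, size=(2, 64, 64)).astype(np.uint16)
        path = tmp_path / "img.tif"
        tifffile.imwrite(path, data)
        img = read_image(path, ["bodipy", "spartin"], pixel_size_um=0.107)
        assert set(img.channels) == {"bodipy", "spartin"}
        assert img.shape == (64, 64)
        assert np.array_equal(img.channel("bodipy"), data[0])
        assert np.array_equal(img.channel("spartin"), data[1])
        assert img.bit_depth == 16

    def test_single_page(self, tmp_path):
        path = tmp_path / "img.tif"
        tifffile.imwrite(path, np.ones((32, 32), dtype=np.uint8))
        img = read_image(path, ["a"])
        assert img.channel("a").shape == (32, 32)

    def test_channel_count_mismatch(self, tmp_path):
        path = tmp_path / "img.tif"
        tifffile.imwrite(path, np.ones((32, 32), dtype=np.uint8))
        with pytest.raises(ChannelCountMismatchError):
            read_image(path, ["a", "b"])

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_image(tmp_path / "nope.tif", ["a"])

    def test_write_read_bit_exact(self, tmp_path, rng):
        data = rng.integers(0, 65535, size=(3, 40, 40)).astype(np.uint16)
        img = MultiChannelImage(
            channels={f"c{i}": data[i] for i in range(3)}, pixel_size_um=0.065
        )
        path = tmp_path / "rt.tif"
        write_image(img, path, channel_order=["c0", "c1", "c2"])
        back = read_image(path, ["c0", "c1", "c2"])
        for i in range(3):
            assert np.array_equal(back.channel(f"c{i}"), data[i])


class TestMultiChannelImage:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="inconsistent shapes"):
            MultiChannelImage(channels={"a": np.zeros((4, 4)), "b": np.zeros((5, 4))})

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            MultiChannelImage(channels={"a": np.full((4, 4), -1.0)})

    def test_nonfinite_rejected(self):
        bad = np.zeros((4, 4))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            MultiChannelImage(channels={"a": bad})

    def test_pixel_size_positive(self):
        with pytest.raises(ValueError, match="pixel_size_um"):
            MultiChannelImage(channels={"a": np.zeros((4, 4))}, pixel_size_um=0.0)


class TestCellROI:
    def test_nucleus_must_be_inside_cell(self):
        cell = np.zeros((10, 10), dtype=bool)
        cell[2:5, 2:5] = True
        nuc = np.zeros((10, 10), dtype=bool)
        nuc[7, 7] = True
        with pytest.raises(ValueError, match="nucleus"):
            CellROI(BinaryMask(cell), BinaryMask(nuc))

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            CellROI(BinaryMask.empty((5, 5)), BinaryMask.empty((5, 5)))


class TestSubtractBackground:
    def test_constant_maps_to_zero(self):
        out = subtract_background(np.full((80, 80), 50.0), ball_radius_px=20)
        assert np.allclose(out, 0.0, atol=1e-6)

    def test_small_feature_preserved(self):
        img = np.full((100, 100), 50.0)
        for r, c in disk_pixels((100, 100), (50, 50), 5):
            img[r, c] += 500.0
        out = subtract_background(img, ball_radius_px=20)
        assert abs(out[50, 50] - 500.0) <= 0.05 * 500
        off = np.ones((100, 100), dtype=bool)
        for r, c in disk_pixels((100, 100), (50, 50), 8):
            off[r, c] = False
        assert out[off].max() < 1.0

    def test_zero_image(self):
        out = subtract_background(np.zeros((30, 30)), ball_radius_px=5)
        assert np.all(out == 0)

    def test_bounded_by_input(self, rng):
        img = rng.uniform(0, 1000, size=(60, 60))
        out = subtract_background(img, ball_radius_px=7)
        assert np.all(out >= 0)
        assert np.all(out <= img + 1e-9)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros((10, 10)), ball_radius_px=0)

    def test_matches_bruteforce_opening_oracle(self, rng):
        # independent oracle: erosion (disk min) then dilation (disk max)
        img = rng.uniform(0, 100, size=(24, 24))
        radius = 3
        offsets = [
            (dr, dc)
            for dr in range(-radius, radius + 1)
            for dc in range(-radius, radius + 1)
            if np.hypot(dr, dc) <= radius + 1e-9
        ]
        h, w = img.shape

        def erode(a):
            out = np.empty_like(a)
            for r in range(h):
                for c in range(w):
                    vals = [
                        a[r + dr, c + dc]
                        for dr, dc in offsets
                        if 0 <= r + dr < h and 0 <= c + dc < w
                    ]
                    out[r, c] = min(vals)
            return out

        def dilate(a):
            out = np.empty_like(a)
            for r in range(h):
                for c in range(w):
                    vals = [
                        a[r + dr, c + dc]
                        for dr, dc in offsets
                        if 0 <= r + dr < h and 0 <= c + dc < w
                    ]
                    out[r, c] = max(vals)
            return out

        expected = img - dilate(erode(img))
        got = subtract_background(img, ball_radius_px=radius)
        assert np.allclose(got, np.clip(expected, 0, None), atol=1e-9)


class TestOtsuMask:
    def test_two_level_exact(self, rng):
        img = np.full(1000, 10.0)
        high = rng.choice(1000, size=100, replace=False)
        img[high] = 200.0
        mask = otsu_mask(img.reshape(25, 40))
        assert mask.area() == 100
        assert set(map(tuple, np.argwhere(mask.grid))) == {
            (i // 40, i % 40) for i in high
        }

    def test_constant_returns_empty_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = otsu_mask(np.full((20, 20), 7.0))
        assert mask.area() == 0

    def test_gaussian_mixture_recovery(self, rng):
        n = 5000
        fg = rng.normal(180, 5, size=n)
        bg = rng.normal(20, 5, size=n)
        img = np.concatenate([bg, fg]).reshape(100, 100)
        mask = otsu_mask(img)
        assert abs(mask.area() - n) <= 0.02 * n

    def test_threshold_matches_exhaustive_search(self, rng):
        from skimage.filters import threshold_otsu

        from conftest import assert_threshold_is_otsu_maximizer

        for _ in range(10):
            img = rng.uniform(0, 255, size=(32, 32))
            img[: rng.integers(4, 28)] += rng.uniform(100, 300)
            thr = threshold_otsu(img, nbins=256)
            assert_threshold_is_otsu_maximizer(img, thr)
            assert np.isclose(thr, exhaustive_otsu_threshold(img), atol=2.0)


class TestDilateMask:
    def test_single_pixel_radius3_is_29px(self):
        mask = BinaryMask.empty((200, 200))
        mask.grid[100, 100] = True
        out = dilate_mask(mask, 3)
        assert out.area() == 29
        assert set(map(tuple, np.argwhere(out.grid))) == disk_pixels(
            (200, 200), (100, 100), 3
        )

    def test_radius_zero_identity(self, rng):
        mask = BinaryMask(rng.random((30, 30)) > 0.7)
        assert np.array_equal(dilate_mask(mask, 0).grid, mask.grid)

    def test_empty_in_empty_out(self):
        assert dilate_mask(BinaryMask.empty((20, 20)), 10).area() == 0

    def test_negative_radius(self):
        with pytest.raises(ValueError):
            dilate_mask(BinaryMask.empty((5, 5)), -1)

    def test_extensive_and_monotone(self, rng):
        a_grid = rng.random((40, 40)) > 0.9
        b_grid = a_grid | (rng.random((40, 40)) > 0.9)
        a, b = BinaryMask(a_grid), BinaryMask(b_grid)
        da, db = dilate_mask(a, 4), dilate_mask(b, 4)
        assert np.all(da.grid | ~a.grid)  # extensive: a subset dilate(a)
        assert not np.any(da.grid & ~db.grid)  # monotone

    def test_bruteforce_distance_oracle(self, rng):
        grid = rng.random((25, 25)) > 0.95
        grid[12, 12] = True
        mask = BinaryMask(grid)
        out = dilate_mask(mask, 2.5)
        trues = np.argwhere(grid)
        expected = np.zeros_like(grid)
        for r in range(25):
            for c in range(25):
                if np.hypot(trues[:, 0] - r, trues[:, 1] - c).min() <= 2.5 + 1e-9:
                    expected[r, c] = True
        assert np.array_equal(out.grid, expected)


class TestMaskAlgebra:
    def test_disjoint_union_and_difference(self):
        a = BinaryMask.empty((10, 10))
        a.grid[:1] = True  # area 10
        b = BinaryMask.empty((10, 10))
        b.grid[5, :5] = True
        b.grid[6] = True  # area 15
        assert mask_union(a, b).area() == 25
        assert mask_difference(a, b).area() == 10

    def test_self_difference_empty(self, rng):
        a = BinaryMask(rng.random((16, 16)) > 0.5)
        assert mask_difference(a, a).area() == 0

    def test_set_oracle(self, rng):
        ga = rng.random((256, 256)) > 0.5
        gb = rng.random((256, 256)) > 0.5
        sa = set(map(tuple, np.argwhere(ga)))
        sb = set(map(tuple, np.argwhere(gb)))
        assert mask_union(BinaryMask(ga), BinaryMask(gb)).area() == len(sa | sb)
        assert mask_difference(BinaryMask(ga), BinaryMask(gb)).area() == len(sa - sb)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mask_union(BinaryMask.empty((4, 4)), BinaryMask.empty((5, 5)))


class TestPolygonCSV:
    def test_square_polygon(self, tmp_path):
        csv = tmp_path / "poly.csv"
        rows = ["cell_id,vertex_index,row,col"]
        for i, (r, c) in enumerate([(2, 2), (2, 8), (8, 8), (8, 2)]):
            rows.append(f"cellA,{i},{r},{c}")
        csv.write_text("\n".join(rows) + "\n")
        masks = rasterize_polygon_csv(csv, (12, 12))
        assert set(masks) == {"cellA"}
        area = masks["cellA"].area()
        assert 25 <= area <= 49  # filled ~6x6 square up to edge convention
        assert masks["cellA"].grid[5, 5]
        assert not masks["cellA"].grid[0, 0]
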