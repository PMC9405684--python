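import json
import struct

import numpy as np
import pytest

from vasculomorph.imaging_io import (
    BinaryMask,
    PolygonROI,
    RasterImage,
    ZStack,
    auto_contrast,
    binarize,
    extract_polygon_roi,
    max_project,
    otsu_threshold,
    read_image,
    read_roi,
    reduce_haze,
    sharpen,
    write_image,
)


def img(values, px=1.0):
    return RasterImage(np.asarray(values, dtype=np.uint8), px)


class TestTypes:
    def test_raster_requires_2d(self):
        with pytest.raises(ValueError):
            RasterImage(np.zeros((2, 2, 2), dtype=np.uint8))

    def test_pixel_size_positive(self):
        with pytest.raises(ValueError):
            RasterImage(np.zeros((2, 2), dtype=np.uint8), pixel_size_um=0)

    def test_16bit_rescales_to_8bit(self):
        im = RasterImage(np.array([[0, 1000], [2000, 4000]], dtype=np.uint16))
        out = im.as_uint8()
        assert out.values.dtype == np.uint8
        assert out.values[0, 0] == 0 and out.values[1, 1] == 255

    def test_zstack_rejects_mismatched_slices(self):
        with pytest.raises(ValueError):
            ZStack([img(np.zeros((2, 2))), img(np.zeros((3, 3)))])

    def test_polygon_needs_three_vertices(self):
        with pytest.raises(ValueError):
            PolygonROI([[0, 0], [1, 1]])

    def test_polygon_rejects_bowtie(self):
        with pytest.raises(ValueError):
            PolygonROI([[0, 0], [10, 10], [10, 0], [0, 10]])


class TestMaxProject:
    def test_per_pixel_max(self):
        st = ZStack([img([[0, 5]]), img([[3, 2]])])
        assert max_project(st).values.tolist() == [[3, 5]]

    def test_single_slice_identity(self):
        a = img([[1, 2], [3, 4]])
        assert np.array_equal(max_project(ZStack([a])).values, a.values)

    def test_matches_loop_oracle(self, rng):
        slices = [img(rng.integers(0, 256, (16, 16))) for _ in range(3)]
        out = max_project(ZStack(slices)).values
        # independent brute-force oracle
        expect = np.zeros((16, 16), dtype=np.uint8)
        for y in range(16):
            for x in range(16):
                expect[y, x] = max(s.values[y, x] for s in slices)
        assert np.array_equal(out, expect)

    def test_slice_order_commutes(self, rng):
        slices = [img(rng.integers(0, 256, (8, 8))) for _ in range(4)]
        a = max_project(ZStack(slices)).values
        b = max_project(ZStack(slices[::-1])).values
        assert np.array_equal(a, b)

    def test_empty_stack_errors(self):
        with pytest.raises(ValueError):
            ZStack([])


class TestAutoContrast:
    def test_constant_unchanged(self):
        a = img(np.full((5, 5), 77))
        assert np.array_equal(auto_contrast(a, 0.0).values, a.values)

    def test_ramp_rescaled(self):
        vals = np.arange(0, 101, dtype=np.uint8)[None, :]
        out = auto_contrast(RasterImage(vals), 0.0).values
        expect = np.round(vals.astype(float) / 100 * 255).astype(np.uint8)
        assert np.array_equal(out, expect)

    def test_full_range_identity(self):
        vals = np.linspace(0, 255, 256).astype(np.uint8)[None, :]
        out = auto_contrast(RasterImage(vals), 0.0).values
        assert np.array_equal(out, vals)

    def test_preserves_shape_and_calibration(self, rng):
        a = RasterImage(rng.integers(0, 256, (7, 9)).astype(np.uint8), pixel_size_um=2.5)
        out = auto_contrast(a)
        assert out.values.shape == (7, 9) and out.pixel_size_um == 2.5

    def test_saturation_domain(self):
        with pytest.raises(ValueError):
            auto_contrast(img(np.zeros((2, 2))), 0.5)


class TestSharpen:
    def test_constant_unchanged_including_borders(self):
        a = img(np.full((6, 6), 100))
        assert np.array_equal(sharpen(a).values, a.values)

    def test_single_pixel_hand_convolution(self):
        a = np.zeros((5, 5), dtype=np.uint8)
        a[2, 2] = 4
        out = sharpen(RasterImage(a)).values
        assert out[2, 2] == 12  # 4*12/4
        assert out[1, 1] == 0  # -4/4 clips to 0
        assert out[0, 0] == 0

    def test_preserves_shape(self, rng):
        a = RasterImage(rng.integers(0, 256, (4, 11)).astype(np.uint8))
        assert sharpen(a).values.shape == (4, 11)


class TestReduceHaze:
    def test_zero_image_unchanged(self):
        a = img(np.zeros((30, 30)))
        assert np.array_equal(reduce_haze(a, 3).values, a.values)

    def test_constant_becomes_zero(self):
        from scipy.ndimage import grey_opening
        from skimage.morphology import disk

        a = np.full((40, 40), 90, dtype=np.uint8)
        out = reduce_haze(RasterImage(a), 5).values
        oracle = a.astype(int) - grey_opening(a, footprint=disk(5), mode="nearest")
        assert np.array_equal(out, np.clip(oracle, 0, 255).astype(np.uint8))
        assert (out == 0).all()

    def test_line_survives_background_removed(self):
        a = np.full((60, 60), 50, dtype=np.uint8)
        a[29:32, 5:55] = 200  # 3-px-wide bright line
        out = reduce_haze(RasterImage(a), 10).values
        assert out[5, 5] == 0  # background gone
        assert (out[30, 10:50] > 100).all()  # line preserved above zero

    def test_radius_too_large_errors(self):
        with pytest.raises(ValueError):
            reduce_haze(img(np.zeros((10, 10))), 20)


def _winding_inside(poly, x, y):
    """Independent even-odd ray-cast point-in-polygon oracle."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xin = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < xin:
                inside = not inside
    return inside


class TestExtractPolygonROI:
    def test_whole_image_rectangle_identity(self, rng):
        a = RasterImage(rng.integers(1, 255, (10, 10)).astype(np.uint8))
        roi = PolygonROI([[-0.5, -0.5], [9.5, -0.5], [9.5, 9.5], [-0.5, 9.5]])
        assert np.array_equal(extract_polygon_roi(a, roi).values, a.values)

    def test_left_half_crop(self):
        a = img(np.full((10, 10), 255))
        roi = PolygonROI([[-0.5, -0.5], [4.5, -0.5], [4.5, 9.5], [-0.5, 9.5]])
        out = extract_polygon_roi(a, roi).values
        assert out.shape == (10, 5)
        assert (out == 255).all()

    def test_triangle_matches_winding_oracle(self):
        a = img(np.full((20, 20), 10))
        tri = [[2.13, 2.31], [17.42, 3.27], [8.71, 16.63]]  # no pixel centers on edges
        out = extract_polygon_roi(a, PolygonROI(tri)).values
        got = int((out > 0).sum())
        expect = sum(
            _winding_inside(tri, x, y) for x in range(20) for y in range(20)
        )
        assert got == expect

    def test_polygon_outside_errors(self):
        a = img(np.zeros((5, 5)))
        with pytest.raises(ValueError):
            extract_polygon_roi(a, PolygonROI([[50, 50], [60, 50], [55, 60]]))


class TestBinarize:
    def test_constant_zero_otsu_warns_empty(self):
        with pytest.warns(UserWarning):
            m = binarize(img(np.zeros((4, 4))), "otsu")
        assert not m.data.any()

    def test_bimodal_otsu(self):
        vals = np.concatenate([np.full(100, 10), np.full(100, 200)]).astype(np.uint8)
        a = RasterImage(vals.reshape(10, 20))
        m = binarize(a, "otsu")
        t = otsu_threshold(a.values)
        assert 10 < t <= 200
        assert np.array_equal(m.data, a.values == 200)

    def test_otsu_equals_bruteforce_search(self, rng):
        for _ in range(10):
            vals = rng.integers(0, 256, (16, 16)).astype(np.uint8)
            t = otsu_threshold(vals)
            # exhaustive between-class-variance search oracle
            flat = vals.ravel().astype(float)
            best_t, best_v = None, -1.0
            for cand in range(1, 256):
                lo, hi = flat[flat < cand], flat[flat >= cand]
                if len(lo) == 0 or len(hi) == 0:
                    continue
                v = len(lo) * len(hi) * (lo.mean() - hi.mean()) ** 2
                if v > best_v:
                    best_v, best_t = v, cand
            assert t == best_t

    def test_fixed_full_mask(self):
        m = binarize(img(np.full((3, 3), 255)), "fixed", threshold=128)
        assert m.data.all()


class TestIO:
    def test_tiff_roundtrip(self, tmp_path):
        a = img(np.arange(36).reshape(6, 6))
        write_image(tmp_path / "a.tif", a)
        back = read_image(tmp_path / "a.tif", pixel_size_um=3.0)
        assert np.array_equal(back.values, a.values)
        assert back.pixel_size_um == 3.0

    def test_png_roundtrip(self, tmp_path):
        a = img(np.arange(36).reshape(6, 6))
        write_image(tmp_path / "a.png", a)
        assert np.array_equal(read_image(tmp_path / "a.png").values, a.values)

    def test_mask_write(self, tmp_path):
        m = BinaryMask(np.eye(4, dtype=bool))
        write_image(tmp_path / "m.tif", m)
        back = read_image(tmp_path / "m.tif")
        assert np.array_equal(back.values > 0, m.data)

    def test_json_roi(self, tmp_path):
        p = tmp_path / "roi.json"
        p.write_text(json.dumps([[0, 0], [10, 0], [5, 8]]))
        roi = read_roi(p)
        assert roi.vertices.shape == (3, 2)

    def test_imagej_roi(self, tmp_path):
        # minimal polygon .roi: header (64 bytes) + n x-coords + n y-coords
        xs, ys = [1, 11, 6], [2, 2, 12]
        top, left = 5, 3
        buf = bytearray(64)
        buf[0:4] = b"Iout"
        struct.pack_into(">h", buf, 4, 227)  # version
        buf[6] = 0  # polygon
        struct.pack_into(">hhhh", buf, 8, top, left, 20, 20)
        struct.pack_into(">h", buf, 16, len(xs))
        for x in xs:
            buf += struct.pack(">h", x)
        for y in ys:
            buf += struct.pack(">h", y)
        p = tmp_path / "poly.roi"
        p.write_bytes(bytes(buf))
        roi = read_roi(p)
        assert roi.vertices.tolist() == [[4.0, 7.0], [14.0, 7.0], [9.0, 17.0]]
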