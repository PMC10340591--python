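import numpy as np
import pytest
from scipy import ndimage

from berryprint.preprocess import (
    GRAY_COEFFS,
    GRAY_COEFFS_LEGACY,
    CropBox,
    NoObjectFoundError,
    binarize,
    clean_mask,
    crop_bounds,
    otsu_threshold,
    preprocess_image,
    sobel_edges,
    to_grayscale,
    unify_background,
)
from berryprint.synthetic import ClassRecipe, generate_image


def otsu_brute_force(img, levels=256):
    """Independent exhaustive scan of the between-class variance."""
    vals = np.clip(np.floor(np.asarray(img, float) / 256.0 * levels), 0, levels - 1).ravel()
    best_k, best_s = 0, -1.0
    for k in range(levels):
        c1, c2 = vals[vals <= k], vals[vals > k]
        if c1.size == 0 or c2.size == 0:
            s = 0.0
        else:
            p1 = c1.size / vals.size
            s = p1 * (1 - p1) * (c1.mean() - c2.mean()) ** 2
        if s > best_s:
            best_s, best_k = s, k
    return best_k


class TestGrayscale:
    @pytest.mark.parametrize(
        "pixel, coeffs, expected",
        [
            ((0, 0, 0), GRAY_COEFFS_LEGACY, 0.0),
            ((255, 255, 255), GRAY_COEFFS_LEGACY, 252.705),  # 255 × 0.991
            ((100, 50, 200), GRAY_COEFFS, 82.05),
        ],
    )
    def test_single_pixel(self, pixel, coeffs, expected):
        img = np.array(pixel, dtype=float).reshape(1, 1, 3)
        assert to_grayscale(img, coeffs)[0, 0] == pytest.approx(expected, abs=1e-9)

    def test_rejects_non_rgb(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4, 4)))

    def test_not_clipped(self):
        img = np.full((2, 2, 3), 255.0)
        out = to_grayscale(img, (1.0, 1.0, 1.0))
        assert np.all(out == 765.0)


class TestOtsu:
    def test_perfectly_separable_has_unit_separability(self):
        img = np.concatenate([np.zeros(50), np.full(50, 255.0)]).reshape(10, 10)
        k, eta = otsu_threshold(img)
        assert eta == pytest.approx(1.0)
        assert 0 <= k < 255

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            img = rng.integers(0, 256, size=(24, 24))
            k, eta = otsu_threshold(img)
            assert k == otsu_brute_force(img)
            assert 0.0 <= eta <= 1.0

    def test_agrees_with_skimage(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(11)
        for _ in range(10):
            img = rng.integers(0, 256, size=(20, 20))
            k, _ = otsu_threshold(img)
            assert k == threshold_otsu(img, nbins=256)

    def test_small_level_set_split(self):
        img = np.array([[10.0, 10.0], [10.0, 200.0]])
        k, _ = otsu_threshold(img)
        assert 10 <= k <= 199  # any k in this band separates {10} from {200}

    def test_constant_image_raises(self):
        with pytest.raises(ValueError, match="no threshold"):
            otsu_threshold(np.full((8, 8), 42.0))


class TestBinarize:
    def test_zero_image(self):
        assert binarize(np.zeros((4, 4)), 0).sum() == 0

    def test_strict_greater_convention(self):
        img = np.array([[0.0, 128.0, 255.0]])
        np.testing.assert_array_equal(binarize(img, 128), [[0, 0, 1]])

    def test_threshold_range_checked(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), 300)

    def test_blob_foreground_area(self):
        recipe = ClassRecipe("x", ridge_contrast=0.0, noise_sd=0.0)
        img, gt = generate_image(recipe, seed=9)
        gray = to_grayscale(img)
        k, _ = otsu_threshold(gray)
        # threshold the quantized gray, as the pipeline does
        bw = binarize(np.floor(gray), k)
        fruit_pixels = int((bw == 0).sum())  # fruit is the dark class
        assert fruit_pixels == pytest.approx(gt.area, rel=0.02)


class TestSobel:
    def test_constant_image_is_zero(self):
        assert np.all(sobel_edges(np.full((10, 10), 7.0)) == 0)

    def test_offset_invariance(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 255, (12, 12))
        np.testing.assert_allclose(sobel_edges(img), sobel_edges(img + 40.0), atol=1e-9)

    def test_vertical_step_response(self):
        img = np.zeros((8, 8))
        img[:, 4:] = 1.0
        edges = sobel_edges(img)
        assert edges.max() == pytest.approx(4.0)
        # response confined to the two columns flanking the step
        nz_cols = np.flatnonzero(edges.sum(axis=0))
        np.testing.assert_array_equal(nz_cols, [3, 4])

    def test_square_boundary_localization(self):
        img = np.zeros((20, 20))
        img[6:14, 6:14] = 1.0
        edges = sobel_edges(img)
        ys, xs = np.nonzero(edges)
        assert ys.min() >= 5 and ys.max() <= 14
        assert xs.min() >= 5 and xs.max() <= 14
        assert np.all(edges[9:11, 9:11] == 0)  # interior silent


class TestCropBounds:
    @staticmethod
    def edge_image_with_columns(cols, rows=(5, 6)):
        img = np.zeros((20, 60))
        for c in cols:
            img[rows[0] : rows[1], c] = 1.0
        return img

    def test_contiguous_run(self):
        box = crop_bounds(self.edge_image_with_columns(range(5, 21)))
        assert (box.xmin, box.xmax) == (5, 20)

    def test_isolated_noise_rejected(self):
        box = crop_bounds(self.edge_image_with_columns(list(range(5, 21)) + [45]))
        assert (box.xmin, box.xmax) == (5, 20)  # gap 45-20=25 > 10

    def test_nearby_run_merged(self):
        cols = list(range(5, 21)) + list(range(25, 31))
        box = crop_bounds(self.edge_image_with_columns(cols))
        assert (box.xmin, box.xmax) == (5, 30)  # gap 25-20=5 <= 10

    def test_crop_is_idempotent(self):
        img = self.edge_image_with_columns(range(5, 21))
        box = crop_bounds(img)
        again = crop_bounds(box.crop(img))
        assert (again.xmin, again.xmax) == (0, box.xmax - box.xmin)
        assert (again.ymin, again.ymax) == (0, box.ymax - box.ymin)

    def test_empty_edges_raise(self):
        with pytest.raises(NoObjectFoundError):
            crop_bounds(np.zeros((10, 10)))


def brute_dilate(mask, se):
    """Reference dilation: OR of shifted copies (edge-padded)."""
    r = se.shape[0] // 2
    p = np.pad(mask.astype(bool), r, mode="edge")
    out = np.zeros_like(mask, dtype=bool)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if se[dy + r, dx + r]:
                out |= p[r + dy : r + dy + mask.shape[0], r + dx : r + dx + mask.shape[1]]
    return out


def brute_erode(mask, se):
    r = se.shape[0] // 2
    p = np.pad(mask.astype(bool), r, mode="edge")
    out = np.ones_like(mask, dtype=bool)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if se[dy + r, dx + r]:
                out &= p[r + dy : r + dy + mask.shape[0], r + dx : r + dx + mask.shape[1]]
    return out


class TestUnifyBackground:
    def test_all_ones_mask_keeps_image(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, (10, 10, 3)).astype(np.uint8)
        np.testing.assert_array_equal(unify_background(img, np.ones((10, 10)), 2), img)

    def test_all_zero_mask_blackens(self):
        img = np.full((6, 6, 3), 200, dtype=np.uint8)
        assert unify_background(img, np.zeros((6, 6)), 2).sum() == 0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            unify_background(np.zeros((6, 6, 3)), np.zeros((5, 5)), 1)

    def test_cleanup_matches_brute_force_morphology(self):
        rng = np.random.default_rng(5)
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[5:15, 5:15] = 1
        mask[8, 8] = 0  # interior hole
        mask[1, 1] = 1  # salt noise in background
        radius = 2
        y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1]
        se = (x * x + y * y) <= radius * radius
        expected = brute_erode(brute_dilate(mask, se), se)  # closing
        expected = brute_dilate(brute_erode(expected, se), se)  # then opening
        np.testing.assert_array_equal(clean_mask(mask, radius), expected.astype(np.uint8))
        assert expected[1, 1] == 0 and expected[8, 8] == 1

    def test_background_exactly_black(self):
        rng = np.random.default_rng(8)
        img = rng.integers(50, 256, (20, 20, 3)).astype(np.uint8)
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[4:16, 4:16] = 1
        out = unify_background(img, mask, 1)
        cleaned = clean_mask(mask, 1)
        nonblack = (out.sum(axis=2) > 0).sum()
        assert nonblack <= cleaned.sum()
        assert np.all(out[cleaned == 0] == 0)


class TestPreprocessPipeline:
    def test_recovers_disk_bounding_box(self):
        # dark disk spanning rows/cols 100..300 on a white canvas
        yy, xx = np.mgrid[0:400, 0:400].astype(float)
        mask = ((xx - 200) ** 2 + (yy - 200) ** 2) <= 100**2
        img = np.full((400, 400, 3), 250, dtype=np.uint8)
        img[mask] = (150, 60, 40)
        out = preprocess_image(img)
        assert out.shape[0] == pytest.approx(201, abs=2)
        assert out.shape[1] == pytest.approx(201, abs=2)

    def test_synthetic_blob_bbox_within_2px(self):
        img, gt = generate_image(ClassRecipe("x", ridge_contrast=0.0, noise_sd=0.0), seed=21)
        res = preprocess_image(img, return_info=True)
        for got, want in [
            (res.crop_box.xmin, gt.bbox.xmin),
            (res.crop_box.xmax, gt.bbox.xmax),
            (res.crop_box.ymin, gt.bbox.ymin),
            (res.crop_box.ymax, gt.bbox.ymax),
        ]:
            assert abs(got - want) <= 2

    def test_background_is_exactly_black(self):
        img, _ = generate_image(ClassRecipe("x"), seed=4)
        out = preprocess_image(img)
        corners = np.concatenate([out[0, :2].ravel(), out[-1, -2:].ravel()])
        assert np.all(corners == 0)

    def test_rerun_on_preprocessed_is_stable(self):
        img, _ = generate_image(ClassRecipe("x"), seed=13)
        once = preprocess_image(img)
        twice = preprocess_image(once)
        area_once = once.shape[0] * once.shape[1]
        area_twice = twice.shape[0] * twice.shape[1]
        assert area_twice >= 0.95 * area_once

    def test_white_image_has_no_object(self):
        with pytest.raises(NoObjectFoundError):
            preprocess_image(np.full((64, 64, 3), 255, dtype=np.uint8))
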