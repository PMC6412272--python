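import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msxfruit import (
    BinaryMask,
    GrayImage,
    MsxImage,
    RunConfig,
    ValidationError,
    label_regions,
    morph_open_disk,
    otsu_threshold,
    preprocess_pipeline,
    remove_small_regions,
    restore_color,
    to_red_gray,
)
from msxfruit.preprocess import binarize

from oracles import flood_fill_components, open_bf, otsu_exhaustive


class TestRedGray:
    def test_projects_red_channel(self):
        px = np.zeros((2, 2, 3), dtype=np.uint8)
        px[0, 0] = (200, 50, 10)
        gray = to_red_gray(MsxImage(px))
        assert gray.pixels[0, 0] == 200
        assert gray.pixels[1, 1] == 0

    def test_structured_red_pattern(self):
        h, w = 7, 5
        px = np.zeros((h, w, 3), dtype=np.uint8)
        pattern = (np.arange(h) % 256).astype(np.uint8)[:, None] * np.ones(w, dtype=np.uint8)
        px[..., 0] = pattern
        px[..., 1] = 99
        assert np.array_equal(to_red_gray(MsxImage(px)).pixels, pattern)


class TestOtsu:
    def test_perfect_bimodal_split(self):
        px = np.concatenate([np.zeros(32, np.uint8), np.full(32, 255, np.uint8)])
        gray = GrayImage(px.reshape(8, 8))
        t, degenerate = otsu_threshold(gray)
        assert not degenerate
        mask = binarize(gray, t)
        assert np.array_equal(mask.pixels, gray.pixels == 255)

    def test_constant_image_is_degenerate(self):
        gray = GrayImage(np.full((4, 4), 7, dtype=np.uint8))
        t, degenerate = otsu_threshold(gray)
        assert (t, degenerate) == (7, True)
        assert binarize(gray, t).area == 0

    def test_matches_exhaustive_search(self, rng):
        """Threshold equals the argmax of between-class variance over all 256."""
        for _ in range(20):
            gray = GrayImage(rng.integers(0, 256, (64, 64), dtype=np.uint8))
            t, _ = otsu_threshold(gray)
            assert t == otsu_exhaustive(gray.pixels)

    def test_dark_foreground_polarity(self):
        px = np.concatenate([np.zeros(32, np.uint8), np.full(32, 255, np.uint8)])
        gray = GrayImage(px.reshape(8, 8))
        t, _ = otsu_threshold(gray)
        mask = binarize(gray, t, bright_foreground=False)
        assert np.array_equal(mask.pixels, gray.pixels == 0)


class TestOpening:
    def test_radius_zero_is_identity(self, rng):
        mask = BinaryMask(rng.random((16, 16)) > 0.5)
        assert np.array_equal(morph_open_disk(mask, 0).pixels, mask.pixels)

    def test_isolated_pixel_removed(self):
        px = np.zeros((9, 9), dtype=bool)
        px[4, 4] = True
        assert morph_open_disk(BinaryMask(px), 1).area == 0

    def test_large_disk_opening_matches_bruteforce_composition(self):
        # a filled radius-5 disk opened by the radius-3 disk: equals the
        # brute-force erode-then-dilate result and keeps nearly all pixels
        # (only extremal boundary pixels of the digital disk may be shaved)
        px = np.zeros((21, 21), dtype=bool)
        rr, cc = np.mgrid[0:21, 0:21]
        px[(rr - 10) ** 2 + (cc - 10) ** 2 <= 25] = True
        opened = morph_open_disk(BinaryMask(px), 3)
        assert np.array_equal(opened.pixels, open_bf(px, 3))
        assert not (opened.pixels & ~px).any()
        assert opened.area >= 0.9 * px.sum()

    def test_matches_bruteforce_erosion_dilation(self, rng):
        """Interior objects open exactly as erode-then-dilate by the disk."""
        px = np.zeros((30, 30), dtype=bool)
        px[5:17, 6:20] = True
        px[18:26, 10:14] = True
        px[rng.random((30, 30)) > 0.97] = True
        px[0, :] = px[-1, :] = px[:, 0] = px[:, -1] = False
        assert np.array_equal(morph_open_disk(BinaryMask(px), 2).pixels, open_bf(px, 2))

    def test_negative_radius_rejected(self):
        with pytest.raises(ValidationError):
            morph_open_disk(BinaryMask(np.zeros((3, 3), bool)), -1)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), radius=st.integers(1, 3))
    def test_idempotent_and_anti_extensive(self, seed, radius):
        mask = BinaryMask(np.random.default_rng(seed).random((24, 24)) > 0.45)
        once = morph_open_disk(mask, radius)
        twice = morph_open_disk(once, radius)
        assert np.array_equal(once.pixels, twice.pixels)
        assert not (once.pixels & ~mask.pixels).any()


def _stamp(areas, shape=(40, 120)):
    """Disjoint rectangles of the given areas (width 5, separated)."""
    px = np.zeros(shape, dtype=bool)
    c = 2
    for area in areas:
        h = 5
        w = area // h
        assert h * w == area
        px[2:2 + h, c:c + w] = True
        c += w + 3
    return BinaryMask(px)


class TestSmallAreaRemoval:
    def test_strict_threshold_at_one_tenth(self):
        mask = _stamp([100, 10, 25])
        out = remove_small_regions(mask, 0.1)
        _, areas = flood_fill_components(out.pixels)
        assert sorted(areas) == [25, 100]  # 10 is not "larger than" 10

    def test_component_just_above_cutoff_survives(self):
        mask = _stamp([100, 15])
        out = remove_small_regions(mask, 0.1)
        _, areas = flood_fill_components(out.pixels)
        assert sorted(areas) == [15, 100]

    def test_empty_mask(self):
        out = remove_small_regions(BinaryMask(np.zeros((5, 5), bool)), 0.1)
        assert out.area == 0

    def test_matches_flood_fill_oracle(self, rng):
        px = np.zeros((256, 256), dtype=bool)
        for _ in range(200):
            r, c = rng.integers(0, 246, 2)
            h, w = rng.integers(2, 10, 2)
            px[r:r + h, c:c + w] = True
        mask = BinaryMask(px)
        out = remove_small_regions(mask, 0.1, connectivity=8)
        labels, areas = flood_fill_components(px, 8)
        amax = max(areas)
        keep = {i + 1 for i, a in enumerate(areas) if a > 0.1 * amax}
        expected = np.isin(labels, list(keep))
        assert np.array_equal(out.pixels, expected)


class TestLabelRegions:
    def test_empty(self):
        assert label_regions(BinaryMask(np.zeros((4, 4), bool))).n_regions == 0

    def test_diagonal_connectivity(self):
        px = np.zeros((4, 4), dtype=bool)
        px[1, 1] = px[2, 2] = True
        assert label_regions(BinaryMask(px), connectivity=8).n_regions == 1
        assert label_regions(BinaryMask(px), connectivity=4).n_regions == 2

    def test_raster_scan_label_order(self):
        px = np.zeros((6, 12), dtype=bool)
        px[4, 1] = True          # lowest row, but leftmost column
        px[0, 10] = True         # encountered first in raster order
        px[2, 4:6] = True
        labels = label_regions(BinaryMask(px))
        assert labels.pixels[0, 10] == 1
        assert labels.pixels[2, 4] == 2
        assert labels.pixels[4, 1] == 3

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        px = rng.random((48, 48)) > 0.65
        labels = label_regions(BinaryMask(px), connectivity)
        oracle_labels, areas = flood_fill_components(px, connectivity)
        assert labels.n_regions == len(areas)
        # raster-scan order labeling makes the two label maps identical
        assert np.array_equal(labels.pixels, oracle_labels)


class TestRestoreColor:
    def test_full_mask_is_identity(self, rng):
        img = MsxImage(rng.integers(0, 256, (6, 6, 3), dtype=np.uint8))
        out = restore_color(img, BinaryMask(np.ones((6, 6), bool)))
        assert np.array_equal(out.pixels, img.pixels)

    def test_empty_mask_blacks_out(self, rng):
        img = MsxImage(rng.integers(0, 256, (6, 6, 3), dtype=np.uint8))
        assert restore_color(img, BinaryMask(np.zeros((6, 6), bool))).pixels.sum() == 0

    def test_checkerboard_pointwise_rule(self):
        img = MsxImage(np.tile(np.array([10, 20, 30], np.uint8), (4, 4, 1)))
        board = np.indices((4, 4)).sum(axis=0) % 2 == 0
        out = restore_color(img, BinaryMask(board))
        assert np.array_equal(out.pixels[board], np.tile([10, 20, 30], (board.sum(), 1)))
        assert (out.pixels[~board] == 0).all()

    def test_shape_mismatch_rejected(self):
        img = MsxImage(np.zeros((4, 4, 3), dtype=np.uint8))
        with pytest.raises(ValidationError):
            restore_color(img, BinaryMask(np.zeros((5, 5), bool)))


def _blob_image(blobs, shape=(80, 80), bg=25, fg=210, salt=None, rng=None):
    """Dark image with bright rectangles and optional isolated salt pixels."""
    px = np.full(shape + (3,), bg, dtype=np.uint8)
    for r, c, h, w in blobs:
        px[r:r + h, c:c + w, 0] = fg
        px[r:r + h, c:c + w, 1] = fg // 2
    if salt:
        for _ in range(salt):
            r, c = rng.integers(0, shape[0], 2)
            px[r, c, 0] = 255
    return MsxImage(px)


class TestPipeline:
    def test_recovers_known_blob_count(self, rng):
        img = _blob_image(
            [(5, 5, 20, 20), (40, 10, 18, 22), (50, 50, 22, 18)], salt=40, rng=rng
        )
        result = preprocess_pipeline(img, RunConfig())
        assert result.labels.n_regions == 3

    def test_all_black_image(self):
        img = MsxImage(np.zeros((20, 20, 3), dtype=np.uint8))
        result = preprocess_pipeline(img)
        assert result.labels.n_regions == 0
        assert result.restored.pixels.sum() == 0

    def test_small_area_rule_fires_after_opening(self):
        # speck of 12 px survives a radius-1 opening but not the 1/10-of-max rule
        img = _blob_image([(5, 5, 20, 20), (40, 40, 3, 4)])
        result = preprocess_pipeline(img, RunConfig(disk_radius=1))
        assert result.labels.n_regions == 1

    def test_restored_respects_clean_mask(self, rng):
        img = _blob_image([(5, 5, 20, 20)])
        result = preprocess_pipeline(img)
        clean = result.binary_clean.pixels
        assert np.array_equal(
            result.restored.pixels[clean], img.pixels[clean]
        )
        assert (result.restored.pixels[~clean] == 0).all()
        assert np.array_equal(result.labels.pixels > 0, clean)

    def test_deterministic(self, scene, cfg):
        a = preprocess_pipeline(scene.image, cfg)
        b = preprocess_pipeline(scene.image, cfg)
        assert np.array_equal(a.labels.pixels, b.labels.pixels)
        assert np.array_equal(a.restored.pixels, b.restored.pixels)
        assert a.otsu_threshold == b.otsu_threshold

    def test_component_count_never_increases_along_chain(self, rng):
        from scipy import ndimage as ndi

        for seed in range(10):
            g = np.random.default_rng(seed)
            img = MsxImage(g.integers(0, 256, (60, 60, 3), dtype=np.uint8))
            gray = to_red_gray(img)
            t, _ = otsu_threshold(gray)
            raw = binarize(gray, t)
            opened = morph_open_disk(raw, 3)
            cleaned = remove_small_regions(opened, 0.1, 8)
            s = ndi.generate_binary_structure(2, 2)
            n_raw = ndi.label(raw.pixels, s)[1]
            n_open = ndi.label(opened.pixels, s)[1]
            n_clean = ndi.label(cleaned.pixels, s)[1]
            assert n_raw >= n_open >= n_clean
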