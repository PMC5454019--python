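"""Thresholding, watershed splitting and mask combination."""

import numpy as np
import pytest

import fretcoloc as fc


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def exhaustive_between_class_threshold(image):
    """Oracle: sweep every gray level, maximize between-class variance."""
    vals = np.asarray(image, dtype=float).ravel()
    best_t, best_sep = None, -1.0
    for t in np.unique(vals)[:-1]:
        lo, hi = vals[vals <= t], vals[vals > t]
        w0, w1 = lo.size / vals.size, hi.size / vals.size
        sep = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if sep > best_sep:
            best_sep, best_t = sep, t
    return best_t


class TestAutoThreshold:
    @pytest.mark.parametrize("method", ["moments", "otsu", "mean", "triangle"])
    def test_two_level_image_recovers_exact_foreground(self, method):
        img = np.full((60, 60), 10, dtype=np.uint16)
        fg = disc_mask(img.shape, (30, 30), 12)
        img[fg] = 1000
        mask = fc.auto_threshold(fc.ChannelImage(img, 12), method=method)
        assert np.array_equal(mask.pixels, fg)
        # threshold separates the classes like the exhaustive-sweep oracle
        oracle_t = exhaustive_between_class_threshold(img)
        assert 10 <= oracle_t < 1000 and 10 <= mask.threshold_value < 1000

    def test_manual_zero_keeps_all_positive_pixels(self, rng):
        img = rng.integers(0, 100, (20, 20), dtype=np.uint16)
        mask = fc.auto_threshold(fc.ChannelImage(img, 12), method="manual", manual_value=0)
        assert np.array_equal(mask.pixels, img > 0)

    def test_constant_image_yields_empty_mask_with_warning(self):
        img = fc.ChannelImage(np.zeros((10, 10), dtype=np.uint16), 12)
        with pytest.warns(UserWarning, match="constant"):
            mask = fc.auto_threshold(img, method="otsu")
        assert not mask.pixels.any()

    def test_unknown_method_raises_config_error(self):
        img = fc.ChannelImage(np.zeros((4, 4), dtype=np.uint16), 12)
        with pytest.raises(fc.ConfigError):
            fc.auto_threshold(img, method="isodata")

    def test_manual_requires_value(self):
        img = fc.ChannelImage(np.zeros((4, 4), dtype=np.uint16), 12)
        with pytest.raises(fc.ConfigError):
            fc.auto_threshold(img, method="manual")


def count_distance_map_maxima(mask):
    """Oracle for the expected number of watershed fragments: regional maxima
    of the distance map after merging plateaus/near-ties (<= 2 px apart)."""
    from scipy import ndimage as ndi
    from skimage.morphology import local_maxima

    dist = ndi.distance_transform_edt(mask)
    maxima = local_maxima(dist, connectivity=2) & mask
    merged = ndi.binary_dilation(maxima, structure=np.ones((3, 3)))
    _, n = ndi.label(merged & mask, structure=np.ones((3, 3)))
    return n


def no_4adjacent_distinct_labels(labels):
    h = (labels[:, :-1] > 0) & (labels[:, 1:] > 0) & (labels[:, :-1] != labels[:, 1:])
    v = (labels[:-1, :] > 0) & (labels[1:, :] > 0) & (labels[:-1, :] != labels[1:, :])
    return not (h.any() or v.any())


class TestWatershedSplit:
    def test_two_overlapping_discs_split_with_one_pixel_separation(self):
        mask = disc_mask((60, 60), (30, 21), 10) | disc_mask((60, 60), (30, 39), 10)
        result = fc.watershed_split(mask)
        assert result.n_objects == 2 == count_distance_map_maxima(mask)
        assert no_4adjacent_distinct_labels(result.labels)
        # conservation: no new foreground; the separation line is inside the mask
        assert not ((result.labels > 0) & ~mask).any()
        assert ((result.labels == 0) & mask).sum() > 0

    def test_single_disc_is_one_label_and_mask_preserved(self):
        mask = disc_mask((40, 40), (20, 20), 10)
        result = fc.watershed_split(mask)
        assert result.n_objects == 1
        assert np.array_equal(result.labels > 0, mask)

    def test_empty_mask_gives_zero_labels(self):
        result = fc.watershed_split(np.zeros((16, 16), dtype=bool))
        assert result.n_objects == 0 and not result.labels.any()

    def test_deterministic_across_runs(self, rng):
        mask = np.zeros((80, 80), dtype=bool)
        for _ in range(6):
            c = rng.integers(12, 68, 2)
            mask |= disc_mask(mask.shape, c, int(rng.integers(5, 11)))
        a = fc.watershed_split(mask.copy())
        b = fc.watershed_split(mask.copy())
        assert np.array_equal(a.labels, b.labels)


class TestCombine:
    @staticmethod
    def _mask(px):
        return fc.BinaryMask(px, "manual", 0.0)

    def test_disjoint_masks_union_adds_and_intersection_empty(self):
        a = np.zeros((20, 20), dtype=bool)
        b = np.zeros((20, 20), dtype=bool)
        a[:3, :10] = True   # 30 px
        b[10:14, :10] = True  # 40 px
        union = fc.combine_union(self._mask(a), self._mask(b))
        inter = fc.combine_intersection(self._mask(a), self._mask(b))
        assert union.area == 70 and inter.area == 0

    def test_identical_masks_are_idempotent(self, rng):
        a = rng.random((15, 15)) > 0.5
        assert np.array_equal(fc.combine_union(self._mask(a), self._mask(a)).pixels, a)
        assert np.array_equal(fc.combine_intersection(self._mask(a), self._mask(a)).pixels, a)

    def test_empty_mask_is_union_identity(self, rng):
        a = rng.random((15, 15)) > 0.5
        empty = np.zeros((15, 15), dtype=bool)
        assert np.array_equal(fc.combine_union(self._mask(a), self._mask(empty)).pixels, a)

    def test_known_overlap_count(self):
        a = np.zeros((10, 10), dtype=bool)
        b = np.zeros((10, 10), dtype=bool)
        a[2:6, 2:8] = True
        b[4:8, 2:8] = True  # overlap rows 4..5 x cols 2..7 = 12 px
        assert fc.combine_intersection(self._mask(a), self._mask(b)).area == 12

    def test_shape_mismatch_raises(self):
        with pytest.raises(fc.ShapeError):
            fc.combine_union(self._mask(np.zeros((4, 4), dtype=bool)),
                             self._mask(np.zeros((5, 5), dtype=bool)))

    def test_inclusion_exclusion_on_random_pairs(self, rng):
        for _ in range(100):
            a = rng.random((32, 32)) > rng.uniform(0.2, 0.8)
            b = rng.random((32, 32)) > rng.uniform(0.2, 0.8)
            union = fc.combine_union(self._mask(a), self._mask(b))
            inter = fc.combine_intersection(self._mask(a), self._mask(b))
            assert union.area + inter.area == int(a.sum()) + int(b.sum())


class TestLabelObjects:
    def test_min_size_filters_small_components(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[0, :5] = True          # 5 px
        mask[10:14, 10:15] = True   # 20 px
        mask[20:30, 20:30] = True   # 100 px
        assert fc.label_objects(mask, min_size=10).n_objects == 2
        assert fc.label_objects(mask, min_size=0).n_objects == 3

    def test_checkerboard_pixels_below_min_size_all_removed(self):
        mask = np.indices((8, 8)).sum(axis=0) % 2 == 0
        # 8-connected checkerboard is one big component; use isolated pixels
        mask = np.zeros((9, 9), dtype=bool)
        mask[::3, ::3] = True
        assert fc.label_objects(mask, min_size=2).n_objects == 0

    def test_labels_are_consecutive_in_raster_order(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[8:10, 0:2] = True   # appears later in raster order
        mask[0:2, 8:10] = True   # appears first
        objs = fc.label_objects(mask, min_size=0)
        assert objs.n_objects == 2
        assert objs.labels[0, 8] == 1 and objs.labels[8, 0] == 2
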