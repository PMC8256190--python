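import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from hydropore.segment import (
    SegmentParams,
    adaptive_gaussian_threshold,
    adaptive_threshold_sigma,
    binary_open,
    clear_border,
    erode,
    fill_holes,
    invert_foreground,
    otsu_threshold,
    reconstruct,
    watershed_split,
)

from _oracles import (
    adaptive_mask_oracle,
    clear_border_oracle,
    erode_oracle,
    fill_holes_oracle,
    open_oracle,
    otsu_oracle,
    reconstruct_oracle,
)

small_masks = hnp.arrays(
    np.bool_, hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=14)
)


def _disk(shape, row, col, r):
    rr = np.arange(shape[0])[:, None] - row
    cc = np.arange(shape[1])[None, :] - col
    return rr**2 + cc**2 <= r**2


class TestAdaptiveThreshold:
    def test_constant_image_offset_convention(self):
        # the offset is subtracted from the local mean, so on a constant
        # image a positive offset admits everything and a negative one
        # nothing — the flat-field behaviour is governed entirely by c
        img = np.full((30, 30), 120.0)
        assert adaptive_gaussian_threshold(img, 5, 2.0).all()
        assert not adaptive_gaussian_threshold(img, 5, -2.0).any()

    def test_bright_block_detected(self):
        img = np.full((9, 9), 50.0)
        img[3:6, 3:6] = 200.0
        mask = adaptive_gaussian_threshold(img, 5, 2.0)
        oracle = adaptive_mask_oracle(img, 5, 2.0, adaptive_threshold_sigma(5))
        np.testing.assert_array_equal(mask, oracle)
        assert mask[3:6, 3:6].all()

    def test_adaptive_beats_otsu_under_illumination_ramp(self):
        # two identical bright blobs at both ends of a strong ramp: a
        # global cut misses one, the local cut finds both
        img = np.tile(np.linspace(20, 210, 60), (40, 1))
        img[6:12, 6:12] += 40
        img[30:36, 50:56] += 40
        adaptive = adaptive_gaussian_threshold(img, 11, 5.0)
        assert adaptive[8, 8] and adaptive[33, 53]
        global_mask = otsu_threshold(img)
        covers_both = (
            global_mask[6:12, 6:12].all() and global_mask[30:36, 50:56].all()
            and global_mask.sum() < 2 * 36 * 4
        )
        assert not covers_both

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            adaptive_gaussian_threshold(np.zeros((10, 10)), 25, 2.0)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            adaptive_gaussian_threshold(np.zeros((30, 30)), 4, 2.0)


class TestOtsu:
    def test_separable_bimodal_half_split(self):
        img = np.zeros((10, 10)) + 10.0
        img[5:] = 240.0
        mask, t = otsu_threshold(img, return_threshold=True)
        assert 10 <= t < 240
        assert mask.sum() == 50
        np.testing.assert_array_equal(mask, img > 128)

    def test_matches_brute_force_on_mixture(self, rng):
        img = np.concatenate(
            [rng.normal(80, 12, 500), rng.normal(190, 10, 300)]
        ).reshape(20, 40)
        img = np.clip(img, 0, 255)
        mask = otsu_threshold(img)
        oracle_mask, _ = otsu_oracle(img)
        np.testing.assert_array_equal(mask, oracle_mask)

    def test_matches_skimage_mask(self, rng):
        from skimage.filters import threshold_otsu

        img = np.clip(rng.normal(120, 40, (32, 32)), 0, 255)
        q = np.round(img).astype(np.uint8)
        np.testing.assert_array_equal(otsu_threshold(img), img > threshold_otsu(q))

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full((5, 5), 7.0))


class TestInvert:
    def test_all_true_to_all_false(self):
        assert not invert_foreground(np.ones((3, 3), bool)).any()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(small_masks)
    def test_involution(self, mask):
        np.testing.assert_array_equal(invert_foreground(invert_foreground(mask)), mask)

    def test_pore_wall_complementarity(self):
        mask = np.zeros((12, 12), bool)
        mask[3:7, 3:7] = True
        assert invert_foreground(mask).sum() + mask.sum() == mask.size


class TestClearBorder:
    def test_interior_blob_unchanged(self):
        mask = np.zeros((10, 10), bool)
        mask[4:7, 4:7] = True
        np.testing.assert_array_equal(clear_border(mask), mask)

    def test_edge_touching_blob_removed(self):
        mask = np.zeros((10, 10), bool)
        mask[0:4, 2:5] = True
        assert not clear_border(mask).any()

    def test_mixed_blobs_flood_fill_oracle(self):
        mask = np.zeros((12, 12), bool)
        mask[0:3, 0:3] = True  # corner blob
        mask[6:9, 6:9] = True  # interior blob
        out = clear_border(mask, 8)
        np.testing.assert_array_equal(out, clear_border_oracle(mask, 8))
        assert out.sum() == 9


class TestMorphology:
    def test_isolated_pixel_eroded_away(self):
        mask = np.zeros((7, 7), bool)
        mask[3, 3] = True
        assert not erode(mask, 1).any()

    def test_square_erosion_matches_set_oracle(self):
        mask = np.zeros((9, 9), bool)
        mask[2:7, 2:7] = True
        out = erode(mask, 1)
        np.testing.assert_array_equal(out, erode_oracle(mask, 1))
        assert out.sum() == 9  # the 3×3-supported interior of the square

    def test_opening_antiextensive_and_idempotent(self, rng):
        mask = rng.random((20, 20)) < 0.45
        opened = binary_open(mask, 1)
        assert not (opened & ~mask).any()
        np.testing.assert_array_equal(binary_open(opened, 1), opened)

    def test_opening_iterated_as_unit_equals_once(self, rng):
        mask = rng.random((24, 24)) < 0.5
        np.testing.assert_array_equal(binary_open(mask, 5), binary_open(mask, 1))

    def test_zero_iterations_identity(self, rng):
        mask = rng.random((8, 8)) < 0.5
        np.testing.assert_array_equal(erode(mask, 0), mask)
        np.testing.assert_array_equal(binary_open(mask, 0), mask)


class TestFillHoles:
    def test_ring_becomes_disk(self):
        ring = _disk((15, 15), 7, 7, 5) & ~_disk((15, 15), 7, 7, 3.5)
        filled = fill_holes(ring)
        np.testing.assert_array_equal(filled, fill_holes_oracle(ring))
        assert filled[7, 7]

    def test_no_holes_idempotent(self):
        mask = _disk((11, 11), 5, 5, 3)
        np.testing.assert_array_equal(fill_holes(mask), mask)

    def test_nested_rings_fully_solid(self):
        outer = _disk((21, 21), 10, 10, 9) & ~_disk((21, 21), 10, 10, 7)
        inner = _disk((21, 21), 10, 10, 5) & ~_disk((21, 21), 10, 10, 3)
        mask = outer | inner
        out = fill_holes(mask)
        np.testing.assert_array_equal(out, fill_holes_oracle(mask))
        assert out[10, 10] and out.sum() == _disk((21, 21), 10, 10, 9).sum()


class TestReconstruct:
    def test_marker_equals_reference_fixpoint(self):
        ref = _disk((9, 9), 4, 4, 3)
        np.testing.assert_array_equal(reconstruct(ref, ref), ref)

    def test_empty_marker_empty_result(self):
        ref = _disk((9, 9), 4, 4, 3)
        assert not reconstruct(np.zeros_like(ref), ref).any()

    def test_single_pixel_recovers_exactly_one_blob(self):
        ref = _disk((20, 20), 5, 5, 3) | _disk((20, 20), 14, 14, 3)
        marker = np.zeros_like(ref)
        marker[5, 5] = True
        out = reconstruct(marker, ref)
        np.testing.assert_array_equal(out, reconstruct_oracle(marker, ref))
        np.testing.assert_array_equal(out, _disk((20, 20), 5, 5, 3))


class TestWatershed:
    def test_single_disk_single_label(self):
        mask = _disk((30, 30), 15, 15, 8)
        labels = watershed_split(mask, 0.05)
        assert labels.max() == 1
        np.testing.assert_array_equal(labels > 0, mask)

    def test_fused_pair_split_through_neck(self):
        # two r=8 disks, centers 20 px apart, joined by a 3-px neck
        shape = (40, 60)
        d1 = _disk(shape, 20, 20, 8)
        d2 = _disk(shape, 20, 40, 8)
        rr = np.abs(np.arange(shape[0])[:, None] - 20)
        cc = np.arange(shape[1])[None, :]
        neck = (rr <= 1.5) & (cc >= 20) & (cc <= 40)
        mask = d1 | d2 | neck
        labels = watershed_split(mask, 0.05)
        assert labels.max() == 2
        assert labels[20, 20] != labels[20, 40]
        assert labels[20, 20] > 0 and labels[20, 40] > 0

    def test_labels_partition_foreground(self, rng):
        mask = rng.random((40, 40)) < 0.4
        labels = watershed_split(mask, 0.05)
        np.testing.assert_array_equal(labels > 0, mask)
        vals = np.unique(labels)
        assert vals[0] == 0 or labels.min() > 0
        nz = vals[vals > 0]
        np.testing.assert_array_equal(nz, np.arange(1, nz.size + 1))

    def test_empty_mask_zero_labels(self):
        labels = watershed_split(np.zeros((10, 10), bool), 0.05)
        assert labels.max() == 0

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            watershed_split(np.ones((5, 5), bool), 1.5)

    def test_label_count_equals_interior_disks_on_phantom(self, benchmark_phantoms):
        _, _, gt = benchmark_phantoms[0]
        labels = watershed_split(gt.labels > 0, 0.05)
        assert labels.max() == len(gt.interior_pores)


class TestPipelineMonotonicity:
    def test_cleaning_shrinks_filling_grows(self, rng):
        mask = rng.random((48, 48)) < 0.5
        cleared = clear_border(mask)
        assert cleared.sum() <= mask.sum()
        eroded = erode(cleared, 1)
        assert eroded.sum() <= cleared.sum()
        opened = binary_open(eroded, 5)
        assert opened.sum() <= eroded.sum()
        filled = fill_holes(opened)
        assert filled.sum() >= opened.sum()


def test_params_validation():
    SegmentParams().validate()
    for bad in [
        dict(threshold_method="mean"),
        dict(window=24),
        dict(watershed_max_threshold=0.0),
        dict(connectivity=6),
        dict(erosion_iters=-1),
    ]:
        with pytest.raises(ValueError):
            SegmentParams(**bad).validate()
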