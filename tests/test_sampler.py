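import numpy as np
import pytest

from paleoseg.annotation import AnnotationPlan
from paleoseg.exceptions import GeometryError, SamplingError, ScheduleError
from paleoseg.sampler import (
    CropPair,
    assemble_input,
    augment,
    build_epoch,
    sample_negative_crop,
    sample_positive_crop,
)
from paleoseg.stack_io import SliceStack


def _plan(n_train: int, neg=((0, 10),)) -> AnnotationPlan:
    idx = [10 * (i + 1) for i in range(n_train + 1)]
    return AnnotationPlan(
        idx, step=10, validation_index=idx[-1], negative_ranges=list(neg)
    )


class TestPositiveCrop:
    def test_single_pixel_always_captured(self, rng):
        """Positive-crop guarantee with the hardest mask: one fossil pixel."""
        img = rng.uniform(size=(48, 48))
        mask = np.zeros((48, 48), dtype=np.uint8)
        mask[37, 5] = 1
        for _ in range(1000):
            pair = sample_positive_crop(img, mask, 16, rng)
            assert pair.mask_crop.sum() >= 1
            r0, c0 = pair.origin
            assert 0 <= r0 <= 32 and 0 <= c0 <= 32

    def test_crop_matches_source_window(self, rng):
        img = rng.uniform(size=(32, 32))
        mask = (rng.uniform(size=(32, 32)) > 0.9).astype(np.uint8)
        pair = sample_positive_crop(img, mask, 8, rng)
        r0, c0 = pair.origin
        np.testing.assert_array_equal(pair.image_crop, img[r0:r0+8, c0:c0+8])
        np.testing.assert_array_equal(pair.mask_crop, mask[r0:r0+8, c0:c0+8])

    def test_degenerate_geometry_forces_origin(self, rng):
        img = rng.uniform(size=(64, 64))
        mask = np.ones((64, 64), dtype=np.uint8)
        pair = sample_positive_crop(img, mask, 64, rng)
        assert pair.origin == (0, 0)

    def test_empty_mask_falls_back_to_unconstrained(self, rng):
        pair = sample_positive_crop(
            np.zeros((32, 32)), np.zeros((32, 32), dtype=np.uint8), 8, rng
        )
        assert pair.mask_crop.sum() == 0

    def test_oversized_crop_rejected(self, rng):
        with pytest.raises(GeometryError):
            sample_positive_crop(
                np.zeros((16, 16)), np.ones((16, 16), dtype=np.uint8), 32, rng
            )


class TestNegativeCrop:
    def test_sources_contained_in_ranges(self, rng):
        stack = SliceStack(rng.uniform(size=(20, 16, 16)))
        for _ in range(100):
            pair = sample_negative_crop(stack, [(0, 10)], 8, rng)
            assert 0 <= pair.source_index < 10
            assert pair.mask_crop.sum() == 0

    def test_two_ranges_hit_uniformly(self, rng):
        """Both fossil-free ranges of equal size drawn with frequency ~1/2."""
        stack = SliceStack(np.zeros((100, 8, 8)))
        ranges = [(0, 10), (90, 100)]
        hits = sum(
            sample_negative_crop(stack, ranges, 4, rng).source_index < 10
            for _ in range(10_000)
        )
        assert abs(hits / 10_000 - 0.5) < 0.05

    def test_constant_slice_gives_constant_crop(self, rng):
        stack = SliceStack(np.full((2, 8, 8), 0.25))
        pair = sample_negative_crop(stack, [(0, 1)], 4, rng)
        assert (pair.image_crop == 0.25).all()

    def test_empty_ranges_rejected(self, rng):
        with pytest.raises(SamplingError):
            sample_negative_crop(SliceStack(np.zeros((2, 8, 8))), [], 4, rng)


class TestBuildEpoch:
    @pytest.mark.parametrize("n_train,expected", [(8, 10), (17, 19)])
    def test_epoch_composition(self, n_train, expected, rng):
        schedule = build_epoch(_plan(n_train), 2, rng)
        assert len(schedule) == expected
        assert schedule.n_positive == n_train
        assert schedule.n_negative == 2

    def test_zero_ratio(self, rng):
        schedule = build_epoch(_plan(1), 0, rng)
        assert len(schedule) == 1

    def test_reproducible_given_seed(self):
        a = build_epoch(_plan(8), 2, np.random.default_rng(7)).items
        b = build_epoch(_plan(8), 2, np.random.default_rng(7)).items
        assert a == b

    def test_no_training_slices_rejected(self, rng):
        plan = AnnotationPlan([5], step=1, validation_index=5)
        with pytest.raises(ScheduleError):
            build_epoch(plan, 2, rng)


class TestAssembleInput:
    def test_1ch_is_the_slice(self, rng):
        stack = SliceStack(rng.uniform(size=(5, 8, 8)))
        np.testing.assert_array_equal(assemble_input(stack, 2, "1ch"), stack[2])

    def test_25d_middle_channel_matches_1ch(self, rng):
        stack = SliceStack(rng.uniform(size=(5, 8, 8)))
        x = assemble_input(stack, 2, "2.5d")
        assert x.shape == (3, 8, 8)
        np.testing.assert_array_equal(x[1], stack[2])
        np.testing.assert_array_equal(x[0], stack[1])
        np.testing.assert_array_equal(x[2], stack[3])

    def test_25d_edge_replication(self, rng):
        stack = SliceStack(rng.uniform(size=(5, 8, 8)))
        first = assemble_input(stack, 0, "2.5d")
        np.testing.assert_array_equal(first[0], stack[0])
        np.testing.assert_array_equal(first[2], stack[1])
        last = assemble_input(stack, 4, "2.5d")
        np.testing.assert_array_equal(last[2], stack[4])

    def test_out_of_bounds_rejected(self, rng):
        with pytest.raises(IndexError):
            assemble_input(SliceStack(np.zeros((3, 4, 4))), 3, "1ch")


class _FixedRng:
    """Stand-in rng producing a prescribed (angle, flip_h, flip_v) draw."""

    def __init__(self, angle, flip_h, flip_v):
        self._angle = angle
        self._flips = iter([flip_h, flip_v])

    def uniform(self, lo=0.0, hi=1.0):
        return self._angle

    def integers(self, *a, **k):
        return next(self._flips)


class TestAugment:
    def test_identity_draw_returns_input(self, rng):
        img = rng.uniform(size=(16, 16))
        mask = (rng.uniform(size=(16, 16)) > 0.8).astype(np.uint8)
        pair = CropPair(img, mask, 0, (0, 0))
        out = augment(pair, _FixedRng(0.0, 0, 0))
        np.testing.assert_array_equal(out.image_crop, img)
        np.testing.assert_array_equal(out.mask_crop, mask)

    def test_quarter_turn_is_exact_permutation(self, rng):
        img = rng.uniform(size=(8, 8))
        mask = (rng.uniform(size=(8, 8)) > 0.5).astype(np.uint8)
        out = augment(CropPair(img, mask, 0, (0, 0)), _FixedRng(90.0, 0, 0))
        np.testing.assert_array_equal(out.image_crop, np.rot90(img))
        np.testing.assert_array_equal(out.mask_crop, np.rot90(mask))

    def test_flips_preserve_positive_count(self, rng):
        mask = (rng.uniform(size=(12, 12)) > 0.7).astype(np.uint8)
        img = rng.uniform(size=(12, 12))
        for draw in [(0.0, 1, 0), (0.0, 0, 1), (180.0, 1, 1)]:
            out = augment(CropPair(img, mask, 0, (0, 0)), _FixedRng(*draw))
            assert out.mask_crop.sum() == mask.sum()

    def test_same_transform_applied_to_image_and_mask(self, rng):
        """A delta pattern: the mask pixel must carry its image neighbourhood."""
        img = np.zeros((33, 33))
        img[10, 20] = 1.0
        mask = np.zeros((33, 33), dtype=np.uint8)
        mask[10, 20] = 1
        for _ in range(20):
            out = augment(CropPair(img, mask, 0, (0, 0)), rng, fill_value=0.0)
            if out.mask_crop.sum() == 0:
                continue  # rotated out of frame
            r, c = np.argwhere(out.mask_crop)[0]
            r0, r1 = max(0, r - 2), r + 3
            c0, c1 = max(0, c - 2), c + 3
            assert out.image_crop[r0:r1, c0:c1].max() > 0.1

    def test_mask_stays_binary_under_arbitrary_rotation(self, rng):
        mask = (rng.uniform(size=(16, 16)) > 0.6).astype(np.uint8)
        out = augment(
            CropPair(rng.uniform(size=(16, 16)), mask, 0, (0, 0)),
            _FixedRng(37.3, 0, 0),
        )
        assert set(np.unique(out.mask_crop)) <= {0, 1}

    def test_25d_channels_transform_together(self, rng):
        img = rng.uniform(size=(3, 8, 8))
        mask = (rng.uniform(size=(8, 8)) > 0.5).astype(np.uint8)
        out = augment(CropPair(img, mask, 0, (0, 0)), _FixedRng(270.0, 0, 0))
        for ch in range(3):
            np.testing.assert_array_equal(out.image_crop[ch], np.rot90(img[ch], 3))
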