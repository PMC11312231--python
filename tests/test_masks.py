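"""Mask primitives: components, retention, relabel, dilation, overlay."""

import numpy as np
import pytest

from perioloc import (
    StructElem,
    connected_components,
    dilate,
    extract_main_instance,
    overlay,
    relabel,
    retain_largest,
)
from perioloc.errors import (
    EmptyMaskError,
    InvalidParameterError,
    ShapeMismatchError,
)

from ._oracles import count_components_floodfill, dilate_square_bruteforce


def random_mask(rng, shape=(10, 10), p=0.35):
    return (rng.random(shape) < p).astype(np.int32)


class TestConnectedComponents:
    def test_empty_mask_stays_empty(self):
        out = connected_components(np.zeros((5, 5), np.int32))
        assert out.max() == 0

    def test_diagonal_touch_depends_on_connectivity(self):
        m = np.zeros((3, 3), np.int32)
        m[0, 0] = m[1, 1] = 1
        assert connected_components(m, 8).max() == 1
        assert connected_components(m, 4).max() == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_count_matches_floodfill_oracle(self, rng, connectivity):
        for _ in range(50):
            m = random_mask(rng)
            got = connected_components(m, connectivity).max()
            assert got == count_components_floodfill(m, connectivity)

    def test_labels_in_raster_discovery_order(self):
        m = np.zeros((5, 9), np.int32)
        m[0, 7] = 1   # first in raster order
        m[2, 0] = 1
        m[4, 4] = 1
        out = connected_components(m)
        assert out[0, 7] == 1 and out[2, 0] == 2 and out[4, 4] == 3


class TestRetainLargest:
    def test_single_label_binarized(self):
        m = np.zeros((4, 4), np.int32)
        m[1:3, 1:3] = 7
        out = retain_largest(m)
        assert set(np.unique(out)) == {0, 1}
        np.testing.assert_array_equal(out > 0, m > 0)

    def test_larger_area_wins(self):
        m = np.zeros((4, 8), np.int32)
        m[0, :5] = 1
        m[2, :3] = 2
        np.testing.assert_array_equal(retain_largest(m), (m == 1).astype(np.int32))

    def test_tie_broken_to_smallest_label(self):
        m = np.zeros((2, 4), np.int32)
        m[0, :2] = 3
        m[1, :2] = 2
        np.testing.assert_array_equal(retain_largest(m), (m == 2).astype(np.int32))

    def test_matches_histogram_argmax_oracle(self, rng):
        for _ in range(50):
            m = rng.integers(0, 5, (10, 10)).astype(np.int32)
            if m.max() == 0:
                continue
            counts = {lab: int(np.sum(m == lab)) for lab in range(1, m.max() + 1) if np.any(m == lab)}
            best = min(counts, key=lambda lab: (-counts[lab], lab))
            np.testing.assert_array_equal(retain_largest(m), (m == best).astype(np.int32))

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            retain_largest(np.zeros((3, 3), np.int32))

    def test_extract_main_instance_splits_binary_input(self):
        m = np.zeros((6, 10), np.int32)
        m[1:5, 1:6] = 1   # 20 px blob
        m[1:3, 8:10] = 1  # 4 px fragment
        out = extract_main_instance(m)
        assert out.sum() == 20 and not out[:, 8:].any()


class TestRelabel:
    def test_identity_with_value_one(self, rng):
        m = random_mask(rng)
        np.testing.assert_array_equal(relabel(m, 1), m)

    def test_roundtrip_binarization(self, rng):
        for _ in range(50):
            m = random_mask(rng)
            np.testing.assert_array_equal((relabel(m, 7) > 0).astype(np.int32), m)

    def test_zero_value_rejected(self):
        with pytest.raises(InvalidParameterError):
            relabel(np.ones((2, 2), np.int32), 0)


class TestDilate:
    def test_single_pixel_becomes_block(self):
        m = np.zeros((7, 7), np.int32)
        m[3, 3] = 1
        out = dilate(m, StructElem("square", 1))
        expect = np.zeros((7, 7), np.int32)
        expect[2:5, 2:5] = 1
        np.testing.assert_array_equal(out, expect)

    def test_empty_mask_stays_empty(self):
        m = np.zeros((5, 5), np.int32)
        np.testing.assert_array_equal(dilate(m, StructElem("square", 1)), m)

    def test_matches_neighborhood_union_oracle(self, rng):
        for _ in range(50):
            m = random_mask(rng, (12, 12))
            np.testing.assert_array_equal(
                dilate(m, StructElem("square", 1)), dilate_square_bruteforce(m, 1)
            )

    def test_two_iterations_equal_radius_two(self, rng):
        m = random_mask(rng, (12, 12))
        np.testing.assert_array_equal(
            dilate(m, StructElem("square", 1), iterations=2),
            dilate(m, StructElem("square", 2), iterations=1),
        )

    def test_monotone_and_distributes_over_union(self, rng):
        a = random_mask(rng, (12, 12), 0.2)
        b = random_mask(rng, (12, 12), 0.2)
        da, db = dilate(a, StructElem("disk", 2)), dilate(b, StructElem("disk", 2))
        assert np.all(da >= a)
        np.testing.assert_array_equal(dilate(a | b, StructElem("disk", 2)), da | db)

    def test_cross_element_is_manhattan_ball(self):
        m = np.zeros((5, 5), np.int32)
        m[2, 2] = 1
        out = dilate(m, StructElem("cross", 2))
        yy, xx = np.mgrid[0:5, 0:5]
        np.testing.assert_array_equal(out, ((np.abs(yy - 2) + np.abs(xx - 2)) <= 2).astype(np.int32))


class TestOverlay:
    def test_identical_masks_yield_overlap_codes_only(self, rng):
        m = random_mask(rng)
        out = overlay(m, m)
        assert set(np.unique(out)) <= {0, 3}

    def test_disjoint_masks_have_no_overlap_code(self):
        a = np.zeros((4, 4), np.int32)
        b = np.zeros((4, 4), np.int32)
        a[0, 0] = 1
        b[3, 3] = 1
        out = overlay(a, b)
        assert set(np.unique(out)) == {0, 1, 2}

    def test_overlap_count_and_conservation(self, rng):
        for _ in range(50):
            a, b = random_mask(rng), random_mask(rng)
            out = overlay(a, b)
            assert int(np.sum(out == 3)) == int(np.sum((a > 0) & (b > 0)))
            np.testing.assert_array_equal(((out == 1) | (out == 3)), a.astype(bool))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ShapeMismatchError):
            overlay(np.zeros((3, 3), np.int32), np.zeros((4, 4), np.int32))
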