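"""Detection, overlap and landmark metrics against direct arithmetic and oracles."""

import math

import numpy as np
import pytest

from perioloc import (
    ConfusionCounts,
    LandmarkSet,
    accuracy,
    average_precision,
    dice,
    jaccard,
    landmark_rmse,
    mean_ap,
    precision_recall,
)
from perioloc.errors import InvalidInputError

from ._oracles import (
    ap_grid_bruteforce,
    dice_bruteforce,
    jaccard_bruteforce,
    rmse_bruteforce,
)


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((10, 0, 0, 0), (1.0, 1.0)),
            ((3, 1, 0, 2), (0.75, 0.6)),
        ],
    )
    def test_precision_recall_direct(self, counts, expected):
        tp, fp, tn, fn = counts
        assert precision_recall(ConfusionCounts(tp, fp, tn, fn)) == pytest.approx(expected)

    def test_precision_recall_matches_ratio_oracle(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 20, 4))
            p, r = precision_recall(ConfusionCounts(tp, fp, tn, fn))
            assert p == (tp / (tp + fp) if tp + fp else None)
            assert r == (tp / (tp + fn) if tp + fn else None)

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((5, 0, 5, 0), 1.0),
            ((0, 3, 0, 7), 0.0),
            ((4, 2, 3, 1), 0.7),
        ],
    )
    def test_accuracy_direct(self, counts, expected):
        tp, fp, tn, fn = counts
        assert accuracy(ConfusionCounts(tp, fp, tn, fn)) == pytest.approx(expected)

    def test_zero_denominators_reported_absent(self):
        assert precision_recall(ConfusionCounts(0, 0, 5, 0))[0] is None
        assert accuracy(ConfusionCounts(0, 0, 0, 0)) is None


class TestOverlapMetrics:
    def test_identical_and_disjoint_extremes(self):
        a = np.zeros((4, 4), np.int32)
        a[1:3, 1:3] = 1
        b = np.zeros((4, 4), np.int32)
        b[0, 0] = 1
        assert dice(a, a) == 1.0 and jaccard(a, a) == 1.0
        assert dice(a, b) == 0.0 and jaccard(a, b) == 0.0

    def test_half_overlap_value(self):
        a = np.zeros((2, 4), np.int32)
        b = np.zeros((2, 4), np.int32)
        a[0, :] = 1          # |a| = 4
        b[0, 2:] = b[1, 2:] = 1  # |b| = 4, overlap 2
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_is_undefined(self):
        z = np.zeros((3, 3), np.int32)
        assert dice(z, z) is None and jaccard(z, z) is None

    def test_dice_jaccard_identity_and_oracles(self, rng):
        for _ in range(50):
            a = (rng.random((8, 8)) < 0.4).astype(np.int32)
            b = (rng.random((8, 8)) < 0.4).astype(np.int32)
            if not (a.any() or b.any()):
                continue
            d, j = dice(a, b), jaccard(a, b)
            assert abs(d - 2 * j / (1 + j)) < 1e-12
            assert d == pytest.approx(dice_bruteforce(a, b))
            assert j == pytest.approx(jaccard_bruteforce(a, b))

    def test_symmetry(self, rng):
        a = (rng.random((8, 8)) < 0.4).astype(np.int32)
        b = (rng.random((8, 8)) < 0.4).astype(np.int32)
        assert dice(a, b) == dice(b, a) and jaccard(a, b) == jaccard(b, a)


class TestAveragePrecision:
    def test_perfect_curve(self):
        assert average_precision([(0.0, 1.0), (1.0, 1.0)]) == pytest.approx(1.0)

    def test_single_point_step(self):
        assert average_precision([(1.0, 0.5)]) == pytest.approx(0.5)

    def test_two_point_curve_against_grid_oracle(self):
        curve = [(0.5, 1.0), (1.0, 0.5)]
        ap = average_precision(curve)
        assert ap == pytest.approx(0.75)
        assert ap == pytest.approx(ap_grid_bruteforce(curve), abs=1e-4)

    def test_invariant_to_duplicate_points(self):
        curve = [(0.5, 1.0), (1.0, 0.5)]
        dup = [(0.5, 1.0), (0.5, 1.0), (1.0, 0.5), (1.0, 0.5)]
        assert average_precision(dup) == average_precision(curve)

    def test_unsorted_recalls_rejected(self):
        with pytest.raises(InvalidInputError):
            average_precision([(0.8, 0.5), (0.2, 1.0)])

    def test_mean_ap(self):
        one = [(1.0, 1.0)]
        half = [(1.0, 0.5)]
        assert mean_ap([one]) == pytest.approx(1.0)
        assert mean_ap([one, half]) == pytest.approx(0.75)
        assert mean_ap([half, one]) == mean_ap([one, half])


def lm(h, w, **pts):
    return LandmarkSet(image_height=h, image_width=w, **pts)


class TestLandmarkRmse:
    def test_identical_sets_zero_error_full_agreement(self):
        s = lm(100, 100, cej_left=(10, 20), cej_right=(10, 80))
        rep = landmark_rmse(s, s)
        assert rep.rmse == 0.0 and rep.n == 2
        assert all(pe.agreement_pct == 100.0 for pe in rep.per_point.values())

    def test_single_pair_pixel_rmse(self):
        a = lm(100, 100, alc_left=(10, 10))
        b = lm(100, 100, alc_left=(13, 14))
        rep = landmark_rmse(a, b, normalize=False)
        assert rep.rmse == pytest.approx(math.sqrt((9 + 16) / 2))
        assert rep.per_point["alc_left"].euclidean_px == pytest.approx(5.0)

    def test_matches_loop_oracle_normalized_and_not(self, rng):
        for _ in range(50):
            h, w = 120, 90
            pts_a, pts_b, pairs = {}, {}, []
            for name in ("cej_left", "cej_right", "alc_left", "alc_right"):
                pa = (int(rng.integers(0, h)), int(rng.integers(0, w // 2)))
                pb = (int(rng.integers(0, h)), int(rng.integers(0, w // 2)))
                side_off = 0 if name.endswith("left") else w // 2
                pa = (pa[0], pa[1] + side_off)
                pb = (pb[0], pb[1] + side_off)
                pts_a[name], pts_b[name] = pa, pb
                pairs.append((pa, pb))
            for normalize in (True, False):
                rep = landmark_rmse(lm(h, w, **pts_a), lm(h, w, **pts_b), normalize)
                assert rep.rmse == pytest.approx(rmse_bruteforce(pairs, h, w, normalize))

    def test_normalized_rmse_scale_invariant(self):
        a = lm(100, 200, cej_left=(10, 20), alc_right=(60, 150))
        b = lm(100, 200, cej_left=(14, 26), alc_right=(50, 140))
        a2 = lm(300, 600, cej_left=(30, 60), alc_right=(180, 450))
        b2 = lm(300, 600, cej_left=(42, 78), alc_right=(150, 420))
        assert landmark_rmse(a, b).rmse == pytest.approx(landmark_rmse(a2, b2).rmse)

    def test_no_common_landmarks_undefined(self):
        a = lm(50, 50, cej_left=(1, 1))
        b = lm(50, 50, alc_right=(2, 40))
        assert landmark_rmse(a, b) is None
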