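"""Heatmap-to-box extraction and the IoBB / Lacc / FPN scoring protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camloc.dataset_io import BoundingBox
from camloc.localization import (cam_to_boxes, false_positive_number, iobb,
                                 localization_accuracy, roc_auc)


def flood_fill_boxes(mask):
    """Brute-force 8-connected component boxes (independent oracle)."""
    mask = mask.copy()
    h, w = mask.shape
    boxes = set()
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx]:
                continue
            stack, ys, xs = [(sy, sx)], [], []
            mask[sy, sx] = False
            while stack:
                y, x = stack.pop()
                ys.append(y)
                xs.append(x)
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx]:
                            mask[ny, nx] = False
                            stack.append((ny, nx))
            boxes.add((min(xs), min(ys), max(ys) - min(ys) + 1,
                       max(xs) - min(xs) + 1))
    return boxes


class TestCamToBoxes:
    def test_single_bright_rectangle(self):
        hm = np.zeros((16, 16), dtype=np.uint8)
        hm[4:8, 5:10] = 255
        (box,) = cam_to_boxes(hm, q=0.7)
        assert (box.x, box.y, box.h, box.w) == (5, 4, 4, 5)

    def test_all_zero_heatmap_gives_no_boxes(self):
        assert cam_to_boxes(np.zeros((8, 8), dtype=np.uint8)) == []

    def test_two_disjoint_squares(self):
        hm = np.zeros((20, 20), dtype=np.uint8)
        hm[2:5, 2:5] = 255
        hm[10:14, 12:17] = 200
        got = {(b.x, b.y, b.h, b.w) for b in cam_to_boxes(hm, q=0.7)}
        assert got == {(2, 2, 3, 3), (12, 10, 4, 5)}

    def test_matches_flood_fill_oracle_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            mask = rng.uniform(size=(12, 12)) < 0.25
            hm = np.where(mask, 255, 0).astype(np.uint8)
            got = {(b.x, b.y, b.h, b.w) for b in cam_to_boxes(hm, q=0.7)}
            assert got == flood_fill_boxes(mask)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            cam_to_boxes(np.zeros((4, 4), dtype=np.uint8), q=1.5)


class TestIobb:
    def test_identity_is_one(self):
        b = BoundingBox(3, 4, 10, 12)
        assert iobb(b, b) == 1.0

    def test_hand_geometry_quarter_overlap(self):
        assert iobb(BoundingBox(0, 0, 10, 10), BoundingBox(5, 5, 10, 10)) == 0.25

    def test_disjoint_is_zero(self):
        assert iobb(BoundingBox(0, 0, 5, 5), BoundingBox(50, 50, 5, 5)) == 0.0

    def test_containment_characterization(self, rng):
        for _ in range(50):
            x, y = rng.integers(0, 20, 2)
            h, w = rng.integers(1, 10, 2)
            pred = BoundingBox(float(x), float(y), float(h), float(w))
            gt_contains = BoundingBox(float(x - 1), float(y - 1),
                                      float(h + 2), float(w + 2))
            assert iobb(pred, gt_contains) == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(1, 8))
    def test_integer_scaling_invariance(self, factor):
        rng = np.random.default_rng(factor)
        p = BoundingBox(*rng.integers(0, 10, 2).astype(float),
                        *rng.integers(1, 10, 2).astype(float))
        g = BoundingBox(*rng.integers(0, 10, 2).astype(float),
                        *rng.integers(1, 10, 2).astype(float))
        assert iobb(p.scaled(factor), g.scaled(factor)) == pytest.approx(iobb(p, g))


class TestLaccFpn:
    GT = {
        "a": {0: [BoundingBox(10, 10, 20, 20)]},
        "b": {0: [BoundingBox(40, 40, 10, 10)]},
        "c": {0: [BoundingBox(5, 5, 10, 10)], 1: [BoundingBox(0, 0, 4, 4)]},
    }

    def test_perfect_predictor(self):
        lacc = localization_accuracy(self.GT, self.GT)
        fpn = false_positive_number(self.GT, self.GT)
        assert lacc == {0: 1.0, 1: 1.0}
        assert fpn == {0: 0.0, 1: 0.0}

    def test_empty_predictor(self):
        assert localization_accuracy({}, self.GT) == {0: 0.0, 1: 0.0}

    def test_two_of_three_hits(self):
        preds = {"a": {0: [BoundingBox(10, 10, 20, 20)]},
                 "b": {0: [BoundingBox(41, 41, 9, 9)]},
                 "c": {0: [BoundingBox(50, 50, 5, 5)]}}
        lacc = localization_accuracy(preds, self.GT, t_iobb=0.1)
        assert lacc[0] == pytest.approx(2 / 3)

    def test_fpn_counting_oracle(self):
        # 3 predicted boxes across the 3 evaluated images, none overlapping
        preds = {"a": {0: [BoundingBox(50, 50, 4, 4), BoundingBox(55, 55, 4, 4)]},
                 "b": {0: [BoundingBox(0, 0, 4, 4)]}}
        fpn = false_positive_number(preds, self.GT, t_iobb=0.1)
        assert fpn[0] == pytest.approx(1.0)      # 3 misses / 3 images

    def test_predictions_without_gt_for_class_excluded(self):
        preds = {"a": {1: [BoundingBox(0, 0, 4, 4)]}}   # image a has no class-1 GT
        fpn = false_positive_number(preds, self.GT, t_iobb=0.1)
        assert fpn[1] == 0.0      # only image c is evaluated for class 1

    def test_lacc_monotone_in_threshold(self, rng):
        preds = {name: {0: [BoundingBox(float(rng.integers(0, 30)),
                                        float(rng.integers(0, 30)), 15, 15)]}
                 for name in self.GT}
        prev = 1.1
        for t in (0.05, 0.1, 0.3, 0.6, 0.9):
            cur = localization_accuracy(preds, self.GT, t_iobb=t)[0]
            assert cur <= prev + 1e-12
            prev = cur


class TestRocAuc:
    def test_perfect_separation(self):
        y = np.array([[1], [1], [0], [0]])
        s = np.array([[0.9], [0.8], [0.2], [0.1]])
        per, mean = roc_auc(s, y)
        assert per[0] == 1.0 and mean == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        y = (rng.uniform(size=(4000, 1)) < 0.5).astype(int)
        s = rng.uniform(size=(4000, 1))
        per, _ = roc_auc(s, y)
        assert abs(per[0] - 0.5) < 0.03

    def test_equals_normalized_mann_whitney_u(self, rng):
        from scipy.stats import mannwhitneyu
        for _ in range(10):
            y = (rng.uniform(size=(60, 1)) < 0.4).astype(int)
            if y.sum() in (0, 60):
                continue
            s = rng.normal(size=(60, 1)) + y
            per, _ = roc_auc(s, y)
            u = mannwhitneyu(s[y[:, 0] == 1, 0], s[y[:, 0] == 0, 0],
                             alternative="two-sided").statistic
            expect = u / (y.sum() * (60 - y.sum()))
            assert per[0] == pytest.approx(expect)

    def test_single_class_reported_absent(self):
        y = np.ones((5, 2), dtype=int)
        y[:, 1] = [0, 1, 0, 1, 0]
        per, mean = roc_auc(np.random.default_rng(1).uniform(size=(5, 2)), y)
        assert 0 not in per and 1 in per
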