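import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from boxnoise.annotations import AnnotationError, BoundingBox
from boxnoise.detector import Detection
from boxnoise.evaluation import (
    average_precision,
    evaluate_dataset,
    iou,
    mann_whitney_u,
    match_detections,
)
from conftest import random_box
from test_noise import _raster_iou


def _det(box, conf=0.9):
    return Detection(box=box, confidence=conf)


class TestIoU:
    def test_identical_and_disjoint(self):
        a = BoundingBox(10, 10, 4, 4)
        assert iou(a, a) == 1.0
        assert iou(a, BoundingBox(50, 50, 4, 4)) == 0.0

    @pytest.mark.parametrize("alpha,expected", [(2, 0.5), (10, 0.1)])
    def test_concentric_area_ratio(self, alpha, expected):
        a = BoundingBox(50, 50, 10, 8)
        b = BoundingBox(50, 50, 10 * alpha**0.5, 8 * alpha**0.5)
        assert iou(a, b) == pytest.approx(expected, abs=1e-12)

    def test_hand_computed_overlap(self):
        a = BoundingBox.from_corners(0, 0, 2, 2)
        b = BoundingBox.from_corners(1, 1, 3, 3)
        assert iou(a, b) == pytest.approx(1 / 7)

    def test_symmetry(self, rng):
        for _ in range(200):
            a, b = random_box(rng), random_box(rng)
            assert iou(a, b) == iou(b, a)
            assert 0.0 <= iou(a, b) <= 1.0


class TestMatching:
    def test_single_pair_above_and_below_threshold(self):
        truth = [BoundingBox(10, 10, 4, 4)]
        hit = _det(BoundingBox(10.5, 10, 4, 4))  # IoU ~ 0.68
        miss = _det(BoundingBox(13, 13, 4, 4))   # IoU ~ 0.03
        m = match_detections([hit], truth, 0.5)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)
        m = match_detections([miss], truth, 0.5)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_double_detection_on_one_truth(self):
        truth = [BoundingBox(10, 10, 4, 4)]
        first = _det(BoundingBox(10, 10, 4, 4), conf=0.9)
        second = _det(BoundingBox(10.5, 10, 4, 4), conf=0.8)
        m = match_detections([second, first], truth, 0.5)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)
        assert m.flags == (True, False)  # higher confidence wins the truth

    def test_greedy_rule_on_enumerated_layouts(self):
        """Exhaustively verify the greedy matcher against brute-force optimal
        assignment search on tiny layouts: greedy consumes truths in
        confidence order, taking the best available IoU >= threshold."""
        truths = [BoundingBox(10, 10, 4, 4), BoundingBox(20, 10, 4, 4)]
        candidates = [BoundingBox(10, 10, 4, 4), BoundingBox(20, 10, 4, 4),
                      BoundingBox(10.8, 10, 4, 4), BoundingBox(40, 40, 4, 4)]
        for picks in itertools.permutations(range(4), 2):
            dets = [_det(candidates[picks[0]], 0.9), _det(candidates[picks[1]], 0.8)]
            m = match_detections(dets, truths, 0.5)
            # independent re-derivation of the greedy outcome
            taken = set()
            expected_flags = []
            for d in dets:
                ious = [(iou(d.box, t), -j) for j, t in enumerate(truths)
                        if j not in taken]
                best = max(ious) if ious else (0.0, 0)
                ok = best[0] >= 0.5
                expected_flags.append(ok)
                if ok:
                    taken.add(-best[1])
            assert list(m.flags) == expected_flags

    def test_counts_are_consistent(self, rng):
        truths = [random_box(rng) for _ in range(5)]
        dets = [_det(random_box(rng), c) for c in np.linspace(0.9, 0.5, 7)]
        m = match_detections(dets, truths, 0.5)
        assert m.tp + m.fn == len(truths)
        assert m.tp + m.fp == len(dets)
        assert m.tp <= min(len(dets), len(truths))

    def test_bad_threshold(self):
        with pytest.raises(AnnotationError):
            match_detections([], [], 0.0)


def _ap_oracle(flags, n_truth, n_grid=200_000):
    """Brute-force oracle: midpoint integration over a fine recall grid of
    the best precision achieved at or beyond each recall level."""
    flags = np.asarray(flags, dtype=bool)
    if not flags.size:
        return 0.0
    tp = np.cumsum(flags)
    prec = tp / np.arange(1, flags.size + 1)
    rec = tp / n_truth
    env = np.array([prec[j:].max() for j in range(flags.size)])
    r = (np.arange(n_grid) + 0.5) / n_grid
    idx = np.searchsorted(rec, r, side="left")
    vals = np.where(idx < rec.size, env[np.minimum(idx, rec.size - 1)], 0.0)
    return float(vals.mean())


class TestAveragePrecision:
    def test_perfect_and_empty(self):
        assert average_precision([True, True], 2) == 1.0
        assert average_precision([], 3) == 0.0

    def test_undefined_without_truth(self):
        with pytest.raises(AnnotationError):
            average_precision([True], 0)

    def test_worked_example(self):
        # ranks: P = 1, 1/2, 2/3; R = 1/2, 1/2, 1; envelope 1 then 2/3
        assert average_precision([True, False, True], 2) == pytest.approx(5 / 6)

    def test_exhaustive_against_numeric_oracle(self):
        """All flag sequences of length <= 8 match brute-force envelope
        integration."""
        for n in range(1, 9):
            for bits in itertools.product([False, True], repeat=n):
                n_truth = max(sum(bits), 1) + 1
                ap = average_precision(bits, n_truth)
                assert ap == pytest.approx(_ap_oracle(bits, n_truth), abs=2e-4)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=12))
    def test_flipping_tp_to_fp_never_raises_ap(self, flags):
        n_truth = max(sum(flags), 1)
        ap = average_precision(flags, n_truth)
        for i, f in enumerate(flags):
            if f:
                worse = list(flags)
                worse[i] = False
                assert average_precision(worse, n_truth) <= ap + 1e-12


class TestEvaluateDataset:
    def _perfect(self, images):
        preds = {im.image_id: [_det(b, 0.9) for b in im.boxes] for im in images}
        truths = {im.image_id: list(im.boxes) for im in images}
        return preds, truths

    def test_perfect_predictions_at_any_threshold(self, small_dataset):
        preds, truths = self._perfect(small_dataset.images[:10])
        for thr in (0.3, 0.5, 0.9, 0.99):
            assert evaluate_dataset(preds, truths, thr).map50 == 1.0

    def test_concentric_quadruple_area_scores_zero(self, small_dataset):
        images = small_dataset.images[:10]
        truths = {im.image_id: list(im.boxes) for im in images}
        preds = {im.image_id: [_det(BoundingBox(b.x, b.y, 2 * b.w, 2 * b.h))
                               for b in im.boxes] for im in images}
        assert evaluate_dataset(preds, truths, 0.5).map50 == 0.0

    def test_iou_boundary_counts_as_detected(self):
        """Concentric boxes at area ratio 2 sit at IoU exactly 0.5; the >=
        rule counts them as true positives."""
        t = BoundingBox(50, 50, 10, 10)
        p = BoundingBox(50, 50, 10 * 2**0.5, 10 * 2**0.5)
        assert iou(p, t) == pytest.approx(0.5, abs=1e-12)
        res = evaluate_dataset({"i": [_det(p)]}, {"i": [t]}, 0.5)
        assert res.map50 == 1.0

    def test_images_without_detections_contribute_fn(self, small_dataset):
        images = small_dataset.images[:4]
        preds, truths = self._perfect(images[:2])
        preds.update({im.image_id: [] for im in images[2:]})
        truths.update({im.image_id: list(im.boxes) for im in images[2:]})
        res = evaluate_dataset(preds, truths)
        n_missed = sum(len(im.boxes) for im in images[2:])
        assert res.fn == n_missed
        assert res.map50 == pytest.approx(res.tp / (res.tp + res.fn))

    def test_mismatched_ids_listed(self):
        with pytest.raises(AnnotationError, match="only-truths"):
            evaluate_dataset({"a": []}, {"a": [], "b": []})


class TestMannWhitney:
    def test_textbook_separation(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_symmetry(self, rng):
        for _ in range(20):
            a = rng.normal(size=4).round(1)
            b = rng.normal(size=6).round(1)
            assert mann_whitney_u(a, b)[1] == pytest.approx(
                mann_whitney_u(b, a)[1], abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(AnnotationError):
            mann_whitney_u([], [1.0])

    def test_matches_scipy_exact_on_tie_free_data(self, rng):
        for _ in range(25):
            n1, n2 = rng.integers(2, 8, size=2)
            pool = rng.permutation(np.arange(n1 + n2, dtype=float))
            a, b = pool[:n1], pool[n1:]
            u, p = mann_whitney_u(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert u == ref.statistic
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_matches_full_enumeration_with_ties(self, rng):
        """Exact agreement with a complete rank-assignment enumeration oracle
        for every sample-size pair up to 7, tied data included."""
        for n1 in range(1, 8):
            for n2 in range(1, 8):
                vals = rng.integers(0, 4, size=n1 + n2).astype(float)
                a, b = vals[:n1], vals[n1:]
                u, p = mann_whitney_u(a, b)
                assert p == pytest.approx(_enumeration_p(a, b), abs=1e-12)


def _enumeration_p(a, b):
    """Oracle: two-sided exact p by enumerating group assignments, computing
    U by direct pairwise comparison each time."""
    pooled = np.concatenate([a, b])
    n1 = len(a)

    def u_of(sel):
        aa = pooled[list(sel)]
        bb = np.delete(pooled, list(sel))
        return sum((x > y) + 0.5 * (x == y) for x in aa for y in bb)

    u_obs = u_of(range(n1))
    us = [u_of(sel) for sel in itertools.combinations(range(len(pooled)), n1)]
    n = len(us)
    p_le = sum(u <= u_obs + 1e-9 for u in us) / n
    p_ge = sum(u >= u_obs - 1e-9 for u in us) / n
    return min(1.0, 2 * min(p_le, p_ge))
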