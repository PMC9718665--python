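"""IoU matching and average precision against brute-force oracles."""

import itertools

import numpy as np
import pytest

from cellseg.evaluation import (
    DEFAULT_THRESHOLDS,
    average_precision,
    dataset_average_precision,
    iou_matrix,
    match_masks,
    within_annotator_bound,
)


def random_instance_map(rng, shape=(24, 24), max_rois=6):
    """Small random instance map made of non-overlapping rectangles."""
    labels = np.zeros(shape, np.int32)
    n = int(rng.integers(0, max_rois + 1))
    for i in range(n):
        r, c = rng.integers(0, shape[0] - 4, 2)
        h, w = rng.integers(2, 5, 2)
        labels[r : r + h, c : c + w] = i + 1
    # rectangles may overwrite each other; keep whatever ids survive
    return labels


def brute_force_ap(pred, truth, threshold):
    """AP by exhaustive search over all injective matchings."""
    ious, pids, tids = iou_matrix(pred, truth)
    n_p, n_t = len(pids), len(tids)
    best_tp = 0
    best_total = -1.0
    k = min(n_p, n_t)
    for size in range(k, -1, -1):
        for rows in itertools.combinations(range(n_p), size):
            for cols in itertools.permutations(range(n_t), size):
                pairs = [
                    (r, c) for r, c in zip(rows, cols) if ious[r, c] >= threshold
                ]
                tp = len(pairs)
                total = sum(ious[r, c] for r, c in pairs)
                if tp > best_tp or (tp == best_tp and total > best_total):
                    best_tp, best_total = tp, total
    denom = best_tp + (n_p - best_tp) + (n_t - best_tp)
    return 1.0 if denom == 0 else best_tp / denom


class TestIouMatrix:
    def test_identical_maps_identity_diagonal(self):
        labels = np.zeros((10, 10), np.int32)
        labels[0:3, 0:3] = 1
        labels[5:8, 5:8] = 2
        ious, pi, ti = iou_matrix(labels, labels)
        assert np.allclose(ious, np.eye(2))

    def test_known_fraction(self):
        a = np.zeros((10, 10), np.int32)
        b = np.zeros((10, 10), np.int32)
        a[0:5, 0:10] = 1  # 50 px
        b[0:5, 5:15 - 5] = 1  # 25 px, overlap 25, union 50
        ious, _, _ = iou_matrix(a, b)
        assert ious[0, 0] == pytest.approx(25 / 50)

    def test_matches_dense_bruteforce(self, rng):
        for _ in range(10):
            p = random_instance_map(rng, max_rois=20)
            t = random_instance_map(rng, max_rois=20)
            ious, pids, tids = iou_matrix(p, t)
            for i, pid in enumerate(pids):
                for j, tid in enumerate(tids):
                    inter = np.sum((p == pid) & (t == tid))
                    union = np.sum((p == pid) | (t == tid))
                    assert ious[i, j] == pytest.approx(inter / union)


class TestMatchMasks:
    def test_perfect_predictions(self):
        ious = np.eye(3)
        m = match_masks(ious, 0.5)
        assert (m.tp, m.fp, m.fn) == (3, 0, 0)

    def test_two_predictions_one_truth(self):
        # both predictions overlap the same truth ROI; only one can match
        ious = np.array([[0.8], [0.6]])
        m = match_masks(ious, 0.5)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)
        assert m.pairs[0][2] == pytest.approx(0.8)

    def test_empty_prediction_set(self):
        m = match_masks(np.zeros((0, 4)), 0.5)
        assert (m.tp, m.fp, m.fn) == (0, 0, 4)

    def test_optimal_beats_greedy_on_contested_instance(self):
        # greedy grabs 0.9 and blocks both others; optimal keeps two pairs
        ious = np.array([[0.9, 0.85], [0.86, 0.0]])
        opt = match_masks(ious, 0.5)
        greedy = match_masks(ious, 0.5, greedy=True)
        assert opt.tp == 2
        assert greedy.tp == 1
        # on uncontested instances both agree
        ious = np.array([[0.9, 0.1], [0.2, 0.8]])
        assert match_masks(ious, 0.5).pairs == match_masks(ious, 0.5, greedy=True).pairs


class TestAveragePrecision:
    def test_formula_half(self):
        truth = np.zeros((12, 12), np.int32)
        truth[0:3, 0:3] = 1
        truth[6:9, 6:9] = 2
        pred = np.zeros_like(truth)
        pred[0:3, 0:3] = 1  # one exact match, one missed
        ap = average_precision(pred, truth, thresholds=[0.5])
        assert ap[0] == pytest.approx(1 / (1 + 0 + 1))

    def test_identical_maps_ap_one_everywhere(self, rng):
        t = random_instance_map(rng)
        assert np.all(average_precision(t, t) == 1.0)

    def test_empty_conventions(self):
        empty = np.zeros((6, 6), np.int32)
        one = empty.copy()
        one[2:4, 2:4] = 1
        assert average_precision(empty, empty, thresholds=[0.5])[0] == 1.0
        assert average_precision(one, empty, thresholds=[0.5])[0] == 0.0
        assert average_precision(empty, one, thresholds=[0.5])[0] == 0.0

    def test_nonincreasing_in_threshold_and_symmetric(self, rng):
        for _ in range(20):
            p = random_instance_map(rng)
            t = random_instance_map(rng)
            ap = average_precision(p, t)
            assert np.all(np.diff(ap) <= 1e-12)
            assert np.allclose(ap, average_precision(t, p))

    def test_equals_bruteforce_on_random_instances(self, rng):
        """Optimal assignment AP == exhaustive matching, exactly."""
        for _ in range(60):
            p = random_instance_map(rng)
            t = random_instance_map(rng)
            for th in (0.5, 0.75):
                assert average_precision(p, t, thresholds=[th])[0] == pytest.approx(
                    brute_force_ap(p, t, th), abs=1e-12
                )

    def test_dataset_mean_is_unweighted(self):
        t1 = np.zeros((8, 8), np.int32)
        t1[0:2, 0:2] = 1
        rep = dataset_average_precision([t1, np.zeros_like(t1)], [t1, t1], [0.5])
        assert rep.mean_ap[0] == pytest.approx((1.0 + 0.0) / 2)


class TestWithinAnnotatorBound:
    def test_mirror_then_unmirror_is_perfect(self, rng):
        t = random_instance_map(rng)
        assert within_annotator_bound(t, t[::-1, ::-1]) == 1.0

    def test_one_dropped_roi_of_n(self):
        t = np.zeros((20, 20), np.int32)
        for i in range(4):
            t[5 * i : 5 * i + 3, 0:3] = i + 1
        b = t.copy()
        b[b == 4] = 0
        assert within_annotator_bound(t, b[::-1, ::-1]) == pytest.approx(3 / 4)

    def test_canvas_mismatch_raises(self):
        with pytest.raises(ValueError):
            within_annotator_bound(
                np.zeros((4, 4), np.int32), np.zeros((5, 4), np.int32)
            )

    def test_boundary_jitter_scores_below_one_and_reproducible(self, rng):
        from scipy import ndimage

        t = np.zeros((40, 40), np.int32)
        for i, (r, c) in enumerate([(5, 5), (5, 25), (25, 5), (25, 25)]):
            t[r : r + 8, c : c + 8] = i + 1
        # annotator-noise model: erode some ROI by 1 px on the second pass
        b = t.copy()
        for i in (1, 3):
            m = ndimage.binary_erosion(b == i, iterations=1)
            b[b == i] = 0
            b[m] = i
        ap = within_annotator_bound(t, b[::-1, ::-1], threshold=0.9)
        assert ap < 1.0
        assert ap == within_annotator_bound(t, b[::-1, ::-1], threshold=0.9)
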