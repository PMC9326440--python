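"""Matching, precision/recall, AP against a threshold-enumeration oracle, MIoU."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from soyphen.annotations_io import BoundingBox, ImageAnnotation
from soyphen.detection_eval import (
    Detection,
    MatchResult,
    average_precision,
    box_iou,
    detections_csv,
    match_detections,
    mean_average_precision,
    mean_iou_segmentation,
    precision_recall,
    read_detections_csv,
)
from soyphen.errors import DataValidationError


def _box(x0, y0, x1, y1, label="flower"):
    return BoundingBox(x0, y0, x1, y1, label=label)


def _det(image_id, box, conf):
    return Detection(image_id=image_id, box=box, label=box.label, confidence=conf)


class TestBoxIou:
    def test_identical(self):
        assert box_iou(_box(0, 0, 10, 10), _box(0, 0, 10, 10)) == 1.0

    def test_corner_touch_is_zero(self):
        assert box_iou(_box(0, 0, 10, 10), _box(10, 10, 20, 20)) == 0.0

    def test_half_shift_gives_one_third(self):
        assert box_iou(_box(0, 0, 10, 10), _box(5, 0, 15, 10)) == pytest.approx(1 / 3)


class TestMatching:
    def test_single_true_positive(self):
        gt = [ImageAnnotation("a", 100, 100, (_box(0, 0, 10, 10),))]
        dets = [_det("a", _box(0, 0, 10, 8), 0.9)]  # IOU 0.8
        mr = match_detections(gt, dets, "flower")
        assert (mr.tp, mr.fp, mr.fn) == (1, 0, 0)

    def test_duplicate_detection_is_fp(self):
        gt = [ImageAnnotation("a", 100, 100, (_box(0, 0, 10, 10),))]
        dets = [
            _det("a", _box(0, 0, 10, 10), 0.9),
            _det("a", _box(0, 0, 10, 9), 0.8),
        ]
        mr = match_detections(gt, dets, "flower")
        assert (mr.tp, mr.fp, mr.fn) == (1, 1, 0)
        assert mr.flags == (True, False)  # the 0.9 detection wins the GT

    def test_all_missed(self):
        gt = [ImageAnnotation("a", 100, 100, tuple(_box(i * 20, 0, i * 20 + 10, 10) for i in range(3)))]
        mr = match_detections(gt, [], "flower")
        assert (mr.tp, mr.fp, mr.fn) == (0, 0, 3)

    def test_unknown_image_id_rejected(self):
        gt = [ImageAnnotation("a", 100, 100, (_box(0, 0, 10, 10),))]
        with pytest.raises(DataValidationError, match="unknown image_id"):
            match_detections(gt, [_det("b", _box(0, 0, 10, 10), 0.5)], "flower")

    @given(st.lists(st.booleans(), max_size=12), st.integers(0, 5))
    def test_conservation(self, emitted, extra_fn):
        # synthesize a scene where each True flag is a perfect detection
        n_gt = sum(emitted) + extra_fn
        boxes = tuple(_box(i * 30, 0, i * 30 + 10, 10) for i in range(n_gt))
        gt = [ImageAnnotation("a", 2000, 50, boxes)]
        dets = [
            _det("a", boxes[i], 0.5 + 0.4 / (i + 1)) for i in range(sum(emitted))
        ]
        mr = match_detections(gt, dets, "flower")
        assert mr.tp + mr.fn == n_gt
        assert mr.tp + mr.fp == len(dets)


class TestPrecisionRecall:
    def test_eq_arithmetic(self):
        mr = MatchResult("flower", tp=8, fp=2, fn=2, flags=(), confidences=())
        assert precision_recall(mr) == (0.8, 0.8)

    def test_perfect(self):
        mr = MatchResult("flower", tp=4, fp=0, fn=0, flags=(), confidences=())
        assert precision_recall(mr) == (1.0, 1.0)

    def test_degenerate_zero_with_warning(self):
        mr = MatchResult("flower", tp=0, fp=5, fn=0, flags=(), confidences=())
        with pytest.warns(UserWarning):
            p, _ = precision_recall(mr)
        assert p == 0.0


def _mr_from_flags(flags, n_gt):
    tp = sum(flags)
    confs = tuple(np.linspace(0.95, 0.05, len(flags)))
    return MatchResult(
        "flower", tp=tp, fp=len(flags) - tp, fn=n_gt - tp,
        flags=tuple(flags), confidences=confs,
    )


def _ap_threshold_oracle(flags, confidences, n_gt):
    """Enumerate every confidence threshold; sum precision * recall increment."""
    order = np.argsort(-np.asarray(confidences), kind="stable")
    flags = np.asarray(flags)[order]
    confs = np.asarray(confidences)[order]
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(confs), reverse=True):
        keep = confs >= t
        tp = int(flags[keep].sum())
        precision = tp / int(keep.sum())
        recall = tp / n_gt
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return ap


class TestAveragePrecision:
    def test_perfect_ranking(self):
        mr = _mr_from_flags([True, True, True], n_gt=3)
        assert average_precision(mr).ap == pytest.approx(1.0)

    def test_hand_walked_ranks(self):
        # (TP, FP, TP) over 2 GT: 1*0.5 + 0.5*0 + (2/3)*0.5
        mr = _mr_from_flags([True, False, True], n_gt=2)
        assert average_precision(mr).ap == pytest.approx(5 / 6)

    def test_matches_threshold_oracle_on_random_sequences(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 21))
            flags = rng.random(n) < 0.6
            n_gt = int(flags.sum() + rng.integers(0, 4))
            if n_gt == 0:
                continue
            confs = rng.permutation(np.linspace(0.02, 0.98, n))  # distinct
            mr = MatchResult(
                "flower", tp=int(flags.sum()), fp=int(n - flags.sum()),
                fn=n_gt - int(flags.sum()),
                flags=tuple(bool(f) for f in flags), confidences=tuple(confs),
            )
            # MatchResult flags are already rank-ordered; order confs to match
            oracle = _ap_threshold_oracle(mr.flags, np.sort(confs)[::-1], n_gt)
            assert average_precision(mr).ap == pytest.approx(oracle, abs=1e-12)

    def test_appending_low_confidence_fp_never_increases(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 10))
            flags = [bool(b) for b in rng.random(n) < 0.5]
            n_gt = max(1, sum(flags))
            base = average_precision(_mr_from_flags(flags, n_gt)).ap
            with_fp = average_precision(_mr_from_flags(flags + [False], n_gt)).ap
            assert with_fp <= base + 1e-12

    def test_appending_final_tp_never_decreases(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 10))
            flags = [bool(b) for b in rng.random(n) < 0.5]
            n_gt = sum(flags) + 1  # one flower still undetected
            base = average_precision(_mr_from_flags(flags, n_gt)).ap
            extended = average_precision(_mr_from_flags(flags + [True], n_gt)).ap
            assert extended >= base - 1e-12

    def test_interp_mode_at_least_raw(self, rng):
        for _ in range(20):
            flags = [bool(b) for b in rng.random(8) < 0.5]
            n_gt = max(1, sum(flags))
            mr = _mr_from_flags(flags, n_gt)
            assert average_precision(mr, "interp").ap >= average_precision(mr).ap - 1e-12

    def test_no_ground_truth_rejected(self):
        mr = MatchResult("flower", tp=0, fp=1, fn=0, flags=(False,), confidences=(0.5,))
        with pytest.raises(DataValidationError):
            average_precision(mr)


class TestMeanAveragePrecision:
    def test_unweighted_mean_and_permutation_invariance(self):
        a = average_precision(_mr_from_flags([True], 1))
        b = average_precision(_mr_from_flags([False, True], 2))
        assert mean_average_precision([a, b]) == pytest.approx(
            mean_average_precision([b, a])
        ) == pytest.approx((a.ap + b.ap) / 2)

    def test_single_class(self):
        a = average_precision(_mr_from_flags([True, False], 2))
        assert mean_average_precision([a]) == a.ap


class TestMiou:
    def test_identical_masks(self):
        m = np.array([[0, 1], [1, 0]])
        assert mean_iou_segmentation(m, m) == 1.0

    def test_hand_confusion_matrix(self):
        gt = np.array([0, 0, 1, 1])
        pred = np.zeros(4, dtype=int)
        # class0 IoU 2/4, class1 IoU 0
        assert mean_iou_segmentation(pred, gt) == pytest.approx(0.25)

    def test_symmetric_in_pred_and_gt(self, rng):
        pred = rng.integers(0, 3, size=(12, 12))
        gt = rng.integers(0, 3, size=(12, 12))
        assert mean_iou_segmentation(pred, gt) == pytest.approx(
            mean_iou_segmentation(gt, pred)
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DataValidationError):
            mean_iou_segmentation(np.zeros((2, 2)), np.zeros((3, 3)))


def test_detection_csv_round_trip():
    dets = [
        _det("a", _box(0, 0, 10.5, 12, label="pod"), 0.75),
        _det("b", _box(3, 4, 8, 9), 0.5),
    ]
    out = read_detections_csv(detections_csv(dets))
    assert [(d.image_id, d.label, d.confidence) for d in out] == [
        ("a", "pod", 0.75), ("b", "flower", 0.5),
    ]
    assert out[0].box.x_max == pytest.approx(10.5)
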