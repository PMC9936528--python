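"""Evaluation metrics: greedy matching, FROC, sensitivity read-out and mAP,
cross-checked against independently coded oracles."""

import numpy as np
import pytest

from pacdet.evaluation import (DEFAULT_FPS_TARGETS, FROCCurve, average_precision,
                               froc_curve, map_coco, match_detections,
                               mean_sensitivity, pairwise_iou,
                               sensitivity_at_fps, stratified_hit_counts)
from conftest import random_box


def greedy_match_oracle(det_boxes, det_scores, gt_boxes, thr):
    """Literal re-implementation of the greedy rule with python loops."""
    order = sorted(range(len(det_scores)), key=lambda i: (-det_scores[i], i))
    claimed = set()
    tp = {}
    for i in order:
        best_j, best_iou = -1, 0.0
        for j in range(len(gt_boxes)):
            if j in claimed:
                continue
            v = pairwise_iou(np.array([det_boxes[i]]), np.array([gt_boxes[j]]))[0, 0]
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= thr:
            tp[i] = True
            claimed.add(best_j)
        else:
            tp[i] = False
    return [tp[i] for i in order]


def ap_oracle(dets_by_image, gts_by_image, thr, max_dets=100):
    """Independent 101-point AP: per-image greedy flags + direct summation."""
    records = []
    n_gt = 0
    for img, gts in gts_by_image.items():
        gts = np.asarray(gts, dtype=float).reshape(-1, 4)
        n_gt += len(gts)
        boxes, scores = dets_by_image.get(img, (np.empty((0, 4)), np.empty(0)))
        boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
        scores = np.asarray(scores, dtype=float).reshape(-1)
        keep = sorted(range(len(scores)), key=lambda i: (-scores[i], i))[:max_dets]
        keep = sorted(keep)
        flags = greedy_match_oracle(boxes[keep], scores[keep], gts, thr)
        srt = sorted(scores[keep], reverse=True)
        records += list(zip(srt, flags))
    records.sort(key=lambda t: -t[0])
    tp_cum = fp_cum = 0
    pr = []
    for _, is_tp in records:
        tp_cum += is_tp
        fp_cum += not is_tp
        pr.append((tp_cum / n_gt, tp_cum / (tp_cum + fp_cum)))
    ap = 0.0
    for r in np.linspace(0, 1, 101):
        best = max((p for rec, p in pr if rec >= r - 1e-12), default=0.0)
        ap += best / 101
    return ap


class TestMatching:
    def test_exact_hit_is_single_tp(self):
        gt = np.array([[0.0, 0, 10, 10]])
        m = match_detections(gt, np.array([0.9]), gt, 0.5)
        assert m.n_tp == 1 and m.n_fp == 0 and m.gt_hit.all()

    def test_second_detection_on_same_gt_is_fp(self):
        gt = np.array([[0.0, 0, 10, 10]])
        dets = np.array([[0.0, 0, 10, 10], [1.0, 1, 11, 11]])
        m = match_detections(dets, np.array([0.9, 0.8]), gt, 0.5)
        assert m.n_tp == 1 and m.n_fp == 1

    def test_each_gt_credited_once_and_flags_partition(self, rng):
        for _ in range(25):
            dets = np.stack([random_box(rng, hi=30) for _ in range(10)])
            gts = np.stack([random_box(rng, hi=30) for _ in range(3)])
            scores = rng.random(10)
            m = match_detections(dets, scores, gts, 0.3)
            assert m.n_tp + m.n_fp == 10
            assert m.n_tp == m.gt_hit.sum() <= 3
            assert list(m.tp) == greedy_match_oracle(dets, scores, gts, 0.3)

    def test_unsorted_input_sorted_internally(self):
        gt = np.array([[0.0, 0, 10, 10]])
        dets = np.array([[20.0, 20, 30, 30], [0.0, 0, 10, 10]])
        m = match_detections(dets, np.array([0.2, 0.9]), gt, 0.5)
        assert m.tp[0]  # highest score first after internal sort
        assert not m.tp[1]


def toy_three_image_setup():
    """Hand-enumerated 3-image set.

    img0: 2 GT; hits at scores .9 (TP) and .5 (TP), one FP at .7
    img1: 1 GT; one FP at .8, hit at .6 (TP)
    img2: 1 GT; no detections
    Expected sweep (threshold descending):
      s>=.9: TP=1 FP=0 -> (0/3 fpi, 1/4)
      s>=.8: TP=1 FP=1 -> (1/3, 1/4)
      s>=.7: TP=1 FP=2 -> (2/3, 1/4)
      s>=.6: TP=2 FP=2 -> (2/3, 2/4)
      s>=.5: TP=3 FP=2 -> (2/3, 3/4)
    """
    gts = {0: np.array([[0.0, 0, 10, 10], [20.0, 20, 30, 30]]),
           1: np.array([[5.0, 5, 15, 15]]),
           2: np.array([[0.0, 0, 8, 8]])}
    dets = {0: (np.array([[0.0, 0, 10, 10], [40.0, 40, 50, 50], [20.0, 20, 30, 30]]),
                np.array([0.9, 0.7, 0.5])),
            1: (np.array([[40.0, 0, 50, 10], [5.0, 5, 15, 15]]),
                np.array([0.8, 0.6]))}
    return dets, gts


class TestFROC:
    def test_hand_enumerated_curve(self):
        dets, gts = toy_three_image_setup()
        curve = froc_curve(dets, gts, 0.5)
        expected = {0.0: 0.0, 1 / 3: 0.25, 2 / 3: 0.75}
        # step read-out at the distinct FP rates of the sweep
        assert sensitivity_at_fps(curve, 0.0) == 0.25  # zero-FP point exists
        assert sensitivity_at_fps(curve, 1 / 3) == 0.25
        assert sensitivity_at_fps(curve, 0.5) == 0.25
        assert sensitivity_at_fps(curve, 2 / 3) == 0.75
        assert sensitivity_at_fps(curve, 8.0) == 0.75
        assert curve.n_images == 3 and curve.n_gt == 4

    def test_perfect_detector_hits_everything_at_zero_fp(self):
        gts = {i: np.array([[0.0, 0, 10, 10]]) for i in range(4)}
        dets = {i: (g.copy(), np.array([1.0])) for i, g in gts.items()}
        curve = froc_curve(dets, gts, 0.5)
        for t in DEFAULT_FPS_TARGETS:
            assert sensitivity_at_fps(curve, t) == 1.0
        assert mean_sensitivity(curve) == 1.0

    def test_no_detections_gives_zero_sensitivity(self):
        gts = {0: np.array([[0.0, 0, 5, 5]])}
        curve = froc_curve({}, gts, 0.5)
        assert sensitivity_at_fps(curve, 8.0) == 0.0

    def test_zero_gt_rejected(self):
        with pytest.raises(ValueError, match="zero ground-truth"):
            froc_curve({}, {0: np.empty((0, 4))}, 0.5)

    def test_monotone_and_recall_at_infinite_budget(self, rng):
        gts = {i: np.stack([random_box(rng, hi=40) for _ in range(3)])
               for i in range(5)}
        dets = {i: (np.stack([random_box(rng, hi=40) for _ in range(8)]),
                    rng.random(8)) for i in range(5)}
        curve = froc_curve(dets, gts, 0.3)
        assert (np.diff(curve.sensitivity) >= -1e-12).all()
        assert (np.diff(curve.fps_per_image) >= -1e-12).all()
        # at unlimited FP budget, FROC sensitivity equals plain recall
        total_tp = sum(match_detections(d, s, gts[i], 0.3).n_tp
                       for i, (d, s) in dets.items())
        assert sensitivity_at_fps(curve, np.inf) == pytest.approx(total_tp / 15)

    def test_step_readout_rules(self):
        curve = FROCCurve(fps_per_image=np.array([0.5, 2.0]),
                          sensitivity=np.array([0.6, 0.8]))
        assert sensitivity_at_fps(curve, 1.0) == 0.6
        assert sensitivity_at_fps(curve, 2.0) == 0.8
        assert sensitivity_at_fps(curve, 0.25) == 0.0  # below every point


class TestMAP:
    def test_perfect_and_absent_detections(self):
        gts = {0: np.array([[0.0, 0, 10, 10]]), 1: np.array([[5.0, 5, 20, 20]])}
        perfect = {k: (v.copy(), np.ones(len(v))) for k, v in gts.items()}
        assert map_coco(perfect, gts) == pytest.approx(1.0)
        assert map_coco({}, gts) == 0.0

    def test_matches_independent_oracle_on_random_sets(self, rng):
        gts = {i: np.stack([random_box(rng, hi=40) for _ in range(3)])
               for i in range(4)}
        dets = {i: (np.stack([random_box(rng, hi=40) for _ in range(10)]),
                    rng.random(10)) for i in range(4)}
        for thr in (0.5, 0.75):
            assert average_precision(dets, gts, thr) == pytest.approx(
                ap_oracle(dets, gts, thr), abs=1e-4)
        oracle_map = np.mean([ap_oracle(dets, gts, t)
                              for t in np.arange(0.5, 0.96, 0.05)])
        assert map_coco(dets, gts) == pytest.approx(oracle_map, abs=1e-4)

    def test_imperfect_localization_scores_between(self):
        gts = {0: np.array([[0.0, 0, 10, 10]])}
        dets = {0: (np.array([[1.0, 1, 11, 11]]), np.array([0.9]))}  # IoU ~0.68
        v = map_coco(dets, gts)
        assert 0.0 < v < 1.0


def test_stratified_counts_recompose_totals(rng):
    gts = {0: np.array([[0.0, 0, 10, 10], [20.0, 20, 30, 30]]),
           1: np.array([[0.0, 0, 10, 10]])}
    tiers = {0: ["easy", "hard"], 1: ["easy"]}
    dets = {0: (np.array([[0.0, 0, 10, 10]]), np.array([0.9])),
            1: (np.array([[0.0, 0, 10, 10]]), np.array([0.8]))}
    matches = {i: match_detections(*dets[i], gts[i], 0.5) for i in gts}
    counts = stratified_hit_counts(matches, tiers)
    assert counts["easy"] == (2, 2)
    assert counts["hard"] == (0, 1)
    total_tp = sum(tp for tp, _ in counts.values())
    total_gt = sum(n for _, n in counts.values())
    assert total_tp == sum(m.n_tp for m in matches.values())
    assert total_gt == 3
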