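"""Detection evaluation: greedy matching, FROC curves, sensitivity at fixed
false-positive rates, and COCO-style mAP.

FROC (free-response ROC) is the standard lesion-detection metric: for a sweep
of score cutoffs, plot sensitivity (fraction of ground-truth lesions hit)
against the average number of false positives per image.  A detection counts
as a hit when its IoU with an unclaimed ground-truth box reaches the
criterion (default 0.5); detections are matched greedily in descending score
order and each ground truth is credited at most once.

``sensitivity_at_fps`` reads the curve with a step-function (floor)
convention: the sensitivity reported at a target rate is that of the largest
operating point whose FPs/image does not exceed the target.  This matters
when comparing against other implementations that interpolate.

mAP follows the COCO protocol for a single class: average precision with
101-point interpolation, averaged over IoU thresholds 0.50:0.05:0.95, with
at most 100 detections per image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MatchResult", "FROCCurve", "match_detections", "froc_curve",
    "sensitivity_at_fps", "mean_sensitivity", "map_coco", "average_precision",
    "pairwise_iou", "stratified_hit_counts", "DEFAULT_FPS_TARGETS",
]

DEFAULT_FPS_TARGETS = (0.125, 0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 8.0)
COCO_IOU_THRESHOLDS = np.arange(0.5, 0.96, 0.05)


def pairwise_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU matrix between (N,4) and (M,4) corner-coordinate boxes."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    ix1 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy1 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix2 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(union > 0, inter / union, 0.0)


@dataclass
class MatchResult:
    """Per-detection TP flags and per-GT hit flags at one IoU criterion."""

    tp: np.ndarray          # bool, per detection (score-descending order)
    scores: np.ndarray      # float, same order
    gt_hit: np.ndarray      # bool, per ground truth
    matched_gt: np.ndarray  # int, index of matched GT or -1
    order: np.ndarray       # indices mapping back to the input detection order

    @property
    def n_tp(self) -> int:
        return int(self.tp.sum())

    @property
    def n_fp(self) -> int:
        return int((~self.tp).sum())


def match_detections(det_boxes, det_scores, gt_boxes,
                     iou_threshold: float = 0.5) -> MatchResult:
    """Greedy score-ordered matching of detections against ground truth.

    Each detection (highest score first; score ties keep input order) claims
    the unclaimed GT of highest IoU, provided that IoU reaches the criterion;
    otherwise it is a false positive.  Input need not be pre-sorted.
    """
    det_boxes = np.asarray(det_boxes, dtype=np.float64).reshape(-1, 4)
    det_scores = np.asarray(det_scores, dtype=np.float64).reshape(-1)
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    order = np.argsort(-det_scores, kind="stable")  # ties by insertion order
    n_det, n_gt = len(det_boxes), len(gt_boxes)
    tp = np.zeros(n_det, dtype=bool)
    matched = np.full(n_det, -1, dtype=int)
    gt_hit = np.zeros(n_gt, dtype=bool)
    if n_det and n_gt:
        ious = pairwise_iou(det_boxes[order], gt_boxes)
        for i in range(n_det):
            row = ious[i].copy()
            row[gt_hit] = -1.0
            j = int(row.argmax()) if n_gt else -1
            if n_gt and row[j] >= iou_threshold:
                tp[i] = True
                matched[i] = j
                gt_hit[j] = True
    return MatchResult(tp=tp, scores=det_scores[order], gt_hit=gt_hit,
                       matched_gt=matched, order=order)


@dataclass
class FROCCurve:
    """Operating points (FPs/image, sensitivity), sorted by FPs/image."""

    fps_per_image: np.ndarray
    sensitivity: np.ndarray
    thresholds: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_images: int = 0
    n_gt: int = 0


def froc_curve(dets_by_image: dict, gts_by_image: dict,
               iou_threshold: float = 0.5) -> FROCCurve:
    """FROC over a set of images.

    ``dets_by_image`` maps image id -> (boxes (N,4), scores (N,)); missing ids
    mean no detections.  ``gts_by_image`` maps image id -> boxes (M,4).  The
    TP/FP flag of each detection is fixed by one greedy matching pass with all
    detections, then score cutoffs are swept over the pooled detections.
    """
    image_ids = list(gts_by_image)
    n_images = len(image_ids)
    n_gt = int(sum(np.asarray(gts_by_image[i], dtype=np.float64).reshape(-1, 4).shape[0]
                   for i in image_ids))
    if n_gt == 0:
        raise ValueError("FROC sensitivity is undefined with zero ground-truth boxes")
    all_scores: list[np.ndarray] = []
    all_tp: list[np.ndarray] = []
    for img in image_ids:
        gts = np.asarray(gts_by_image[img], dtype=np.float64).reshape(-1, 4)
        boxes, scores = dets_by_image.get(img, (np.empty((0, 4)), np.empty(0)))
        m = match_detections(boxes, scores, gts, iou_threshold)
        all_scores.append(m.scores)
        all_tp.append(m.tp)
    scores = np.concatenate(all_scores) if all_scores else np.empty(0)
    tp = np.concatenate(all_tp) if all_tp else np.empty(0, dtype=bool)
    if len(scores) == 0:
        return FROCCurve(fps_per_image=np.array([0.0]), sensitivity=np.array([0.0]),
                         thresholds=np.array([np.inf]), n_images=n_images, n_gt=n_gt)
    order = np.argsort(-scores, kind="stable")
    scores, tp = scores[order], tp[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    # one operating point per distinct threshold (include every det at that
    # score), plus the empty-detection anchor point (0 FPs, 0 sensitivity)
    keep = np.r_[scores[1:] != scores[:-1], True]
    fps = np.r_[0.0, cum_fp[keep] / n_images]
    sens = np.r_[0.0, cum_tp[keep] / n_gt]
    thresholds = np.r_[np.inf, scores[keep]]
    return FROCCurve(fps_per_image=fps, sensitivity=sens,
                     thresholds=thresholds, n_images=n_images, n_gt=n_gt)


def sensitivity_at_fps(curve: FROCCurve, targets=DEFAULT_FPS_TARGETS):
    """Step-function read-out: sensitivity of the largest operating point with
    FPs/image <= target; 0 when no such point exists."""
    scalar = np.isscalar(targets)
    targets_arr = np.atleast_1d(np.asarray(targets, dtype=np.float64))
    out = np.zeros(len(targets_arr))
    for i, t in enumerate(targets_arr):
        ok = curve.fps_per_image <= t + 1e-12
        out[i] = curve.sensitivity[ok].max() if ok.any() else 0.0
    return float(out[0]) if scalar else dict(zip(targets_arr.tolist(), out.tolist()))


def mean_sensitivity(curve: FROCCurve, targets=DEFAULT_FPS_TARGETS) -> float:
    """Arithmetic mean of the sensitivities at the given FP targets (the
    conventional summary column alongside FROC tables)."""
    vals = sensitivity_at_fps(curve, targets)
    return float(np.mean(list(vals.values())))


def average_precision(dets_by_image: dict, gts_by_image: dict,
                      iou_threshold: float, max_dets: int = 100) -> float:
    """COCO-style AP at one IoU threshold (101-point interpolation)."""
    n_gt = int(sum(np.asarray(g).reshape(-1, 4).shape[0] for g in gts_by_image.values()))
    if n_gt == 0:
        raise ValueError("AP undefined with zero ground-truth boxes")
    scores_list, tp_list = [], []
    for img in gts_by_image:
        gts = np.asarray(gts_by_image[img], dtype=np.float64).reshape(-1, 4)
        boxes, scores = dets_by_image.get(img, (np.empty((0, 4)), np.empty(0)))
        boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
        scores = np.asarray(scores, dtype=np.float64).reshape(-1)
        if len(scores) > max_dets:
            keep = np.argsort(-scores, kind="stable")[:max_dets]
            keep.sort()
            boxes, scores = boxes[keep], scores[keep]
        m = match_detections(boxes, scores, gts, iou_threshold)
        scores_list.append(m.scores)
        tp_list.append(m.tp)
    scores = np.concatenate(scores_list)
    tp = np.concatenate(tp_list)
    if len(scores) == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    tp = tp[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / n_gt
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1)
    # precision envelope, then sample at 101 recall points
    for i in range(len(precision) - 2, -1, -1):
        precision[i] = max(precision[i], precision[i + 1])
    recall_points = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(recall, recall_points, side="left")
    prec_at = np.where(idx < len(precision), precision[np.minimum(idx, len(precision) - 1)], 0.0)
    return float(prec_at.mean())


def map_coco(dets_by_image: dict, gts_by_image: dict, max_dets: int = 100) -> float:
    """Mean of AP over IoU thresholds 0.50:0.05:0.95."""
    aps = [average_precision(dets_by_image, gts_by_image, float(t), max_dets)
           for t in COCO_IOU_THRESHOLDS]
    return float(np.mean(aps))


def stratified_hit_counts(match_results: dict, gt_labels: dict) -> dict:
    """Per-label (TP, n_GT) counts from per-image match results.

    ``match_results`` maps image id -> :class:`MatchResult`; ``gt_labels``
    maps image id -> sequence of labels, aligned with the GT boxes the match
    was computed against.  Summing the per-label counts recovers the overall
    totals because every GT carries exactly one label.
    """
    counts: dict = {}
    for img, m in match_results.items():
        labels = list(gt_labels[img])
        if len(labels) != len(m.gt_hit):
            raise ValueError(f"label/GT length mismatch for image {img!r}")
        for lab, hit in zip(labels, m.gt_hit):
            tp, n = counts.get(lab, (0, 0))
            counts[lab] = (tp + int(hit), n + 1)
    return counts
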