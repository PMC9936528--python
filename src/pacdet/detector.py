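"""Minimal two-stage lesion detector over the multi-pathway PAC backbone.

Stage one is a region proposal network (RPN) sliding over every pyramid
level: a shared 3x3 convolution followed by 1x1 objectness and box-offset
heads, with one anchor scale per level (16 at stride 4 up to 256 at stride
64) and aspect ratios (0.5, 1, 2).  Stage two pools each proposal to a 7x7
grid by bilinear sampling and classifies/refines it with a small MLP.

Box regression operates directly on corner coordinates — the network emits
additive corner offsets (scaled by the anchor stride or proposal size) and
the regression loss is any member of the IoU family, by default the
vertex-distance IoU loss.  Classification uses sigmoid (RPN) or softmax
(head) cross-entropy.  Anchor/proposal assignment follows the usual
two-stage conventions: RPN positives at IoU >= 0.7 (plus the best anchor per
GT), negatives below 0.3, sampled 1:1 up to 256; head positives at IoU >=
0.5 with a quarter-positive sample of 64.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import evaluation
from .autodiff import Tensor, concat, no_grad, stack
from .backbone import LEVELS, STRIDES, BackboneConfig, MultiPathwayBackbone
from .box_losses import LOSS_NAMES, Box, batched_loss
from .nn import SGD, Conv2d, Linear, Module, load_checkpoint, save_checkpoint

__all__ = [
    "AnchorSet", "TrainConfig", "Detection", "generate_anchors",
    "assign_boxes", "assign_and_losses", "nms", "TwoStageDetector",
    "train", "predict", "MIN_BOX_SIZE",
]

MIN_BOX_SIZE = 1e-3  # predicted boxes are clamped to this width/height
ANCHOR_SCALES = {2: 16, 3: 32, 4: 64, 5: 128, 6: 256}
ANCHOR_RATIOS = (0.5, 1.0, 2.0)


@dataclass(frozen=True)
class Detection:
    """One predicted lesion box with its confidence score."""

    image_id: str
    box: Box
    score: float
    label: str = "lesion"


@dataclass
class TrainConfig:
    """Optimization and assignment settings for detector training.

    The defaults mirror the reference schedule (SGD, base learning rate
    0.004 decayed by 10x after 4 epochs, 15 epochs, mini-batch 2); scale
    ``epochs``/``decay_epoch`` down for desk-scale runs.
    """

    lr: float = 0.004
    decay_factor: float = 0.1
    decay_epoch: int = 4
    epochs: int = 15
    batch_size: int = 2
    loss_name: str = "vdiou"
    seed: int = 0
    momentum: float = 0.9
    rpn_pos_iou: float = 0.7
    rpn_neg_iou: float = 0.3
    head_pos_iou: float = 0.5
    rpn_batch: int = 256
    rpn_pos_fraction: float = 0.5
    head_batch: int = 64
    head_pos_fraction: float = 0.25
    pre_nms_top: int = 1000
    post_nms_top: int = 100
    rpn_nms_iou: float = 0.7
    grad_clip: float = 10.0     # global gradient-norm clip
    vdiou_in_rpn: bool = True   # apply the configured IoU-family loss in the RPN too
    rpn_loss_fallback: str = "giou"  # used in the RPN when vdiou_in_rpn is False

    def __post_init__(self):
        if self.lr <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("learning rate, epochs and batch size must be positive")
        if self.loss_name not in LOSS_NAMES:
            raise ValueError(f"unknown loss {self.loss_name!r}")


@dataclass
class AnchorSet:
    """Per-level anchor boxes on the feature grid of an image size."""

    boxes_by_level: dict[int, np.ndarray]   # (H*W*A, 4), row-major grid, A fastest
    image_size: tuple[int, int]
    scales: dict[int, float] = field(default_factory=lambda: dict(ANCHOR_SCALES))
    ratios: tuple[float, ...] = ANCHOR_RATIOS

    @property
    def all_boxes(self) -> np.ndarray:
        return np.concatenate([self.boxes_by_level[lvl] for lvl in LEVELS])

    @property
    def n_per_cell(self) -> int:
        return len(self.ratios)


def generate_anchors(image_size: tuple[int, int],
                     scales: dict[int, float] | None = None,
                     ratios: tuple[float, ...] = ANCHOR_RATIOS) -> AnchorSet:
    """Anchors centered on every feature-grid cell of every pyramid level.

    An anchor of scale ``s`` and aspect ratio ``r`` (height/width) spans
    ``s/sqrt(r) x s*sqrt(r)``, so ratio 1 gives an ``s x s`` square.
    """
    h, w = image_size
    if h % STRIDES[6] or w % STRIDES[6]:
        raise ValueError(f"image size {image_size} not divisible by stride {STRIDES[6]}")
    scales = dict(ANCHOR_SCALES) if scales is None else scales
    boxes_by_level: dict[int, np.ndarray] = {}
    for lvl in LEVELS:
        stride = STRIDES[lvl]
        scale = scales[lvl]
        gh, gw = h // stride, w // stride
        cy = (np.arange(gh) + 0.5) * stride
        cx = (np.arange(gw) + 0.5) * stride
        shapes = np.array([[scale / math.sqrt(r), scale * math.sqrt(r)]
                           for r in ratios])  # (A, [w, h])
        cyy, cxx = np.meshgrid(cy, cx, indexing="ij")
        centers = np.stack([cxx.ravel(), cyy.ravel()], axis=1)  # (HW, 2)
        half = shapes / 2.0
        x1 = centers[:, None, 0] - half[None, :, 0]
        y1 = centers[:, None, 1] - half[None, :, 1]
        x2 = centers[:, None, 0] + half[None, :, 0]
        y2 = centers[:, None, 1] + half[None, :, 1]
        boxes_by_level[lvl] = np.stack([x1, y1, x2, y2], axis=-1).reshape(-1, 4)
    return AnchorSet(boxes_by_level=boxes_by_level, image_size=(h, w),
                     scales=scales, ratios=tuple(ratios))


def assign_boxes(boxes: np.ndarray, gt_boxes: np.ndarray, pos_iou: float,
                 neg_iou: float, allow_low_quality: bool = True):
    """Label anchors/proposals against GT: 1 positive, 0 negative, -1 ignore.

    Returns ``(labels, assigned_gt_index)``.  The highest-IoU anchor of every
    GT is promoted to positive even below the threshold when
    ``allow_low_quality`` is set (so no GT goes unclaimed).
    """
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    n = len(boxes)
    labels = np.zeros(n, dtype=int)
    assigned = np.full(n, -1, dtype=int)
    if len(gt_boxes) == 0:
        return labels, assigned
    ious = evaluation.pairwise_iou(boxes, gt_boxes)
    best_gt = ious.argmax(axis=1)
    best_iou = ious[np.arange(n), best_gt]
    labels[best_iou >= pos_iou] = 1
    labels[(best_iou < pos_iou) & (best_iou >= neg_iou)] = -1
    assigned[labels == 1] = best_gt[labels == 1]
    if allow_low_quality:
        top_per_gt = ious.argmax(axis=0)
        for j, i in enumerate(top_per_gt):
            if ious[i, j] > 0:
                labels[i] = 1
                assigned[i] = j
    return labels, assigned


def _sample_balanced(labels: np.ndarray, batch: int, pos_fraction: float,
                     rng: np.random.Generator):
    """Sample keeping the positive:negative ratio at ``pos_fraction`` (1:1 for
    0.5), rather than padding the batch with negatives when positives are
    scarce; a few negatives are always kept so pure-background images train."""
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    n_pos = min(len(pos), int(round(batch * pos_fraction)))
    ratio = (1.0 - pos_fraction) / pos_fraction
    n_neg = min(len(neg), max(int(round(n_pos * ratio)), 4))
    pos_sel = rng.choice(pos, n_pos, replace=False) if n_pos else pos[:0]
    neg_sel = rng.choice(neg, n_neg, replace=False) if n_neg else neg[:0]
    return pos_sel, neg_sel


def assign_and_losses(proposals, gt_boxes, loss_name: str,
                      cls_logits=None, pred_boxes=None,
                      pos_iou: float = 0.5, neg_iou: float = 0.5,
                      batch: int | None = None, pos_fraction: float = 0.5,
                      rng: np.random.Generator | None = None):
    """Classification + regression losses for a set of proposals.

    With the defaults the function is a pure assignment probe: logits default
    to zeros (so the classification term is ``log 2`` per sampled box) and
    predicted boxes default to the proposals themselves, making the
    regression term the chosen loss between each positive proposal and its
    assigned GT.  Tensor ``cls_logits``/``pred_boxes`` give differentiable
    losses for training.  Returns ``(cls_loss, reg_loss)``.
    """
    if loss_name not in LOSS_NAMES:
        raise ValueError(f"unknown loss {loss_name!r}")
    proposals = np.asarray(proposals, dtype=np.float64).reshape(-1, 4)
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    n = len(proposals)
    if n == 0 and len(gt_boxes) == 0:
        return 0.0, 0.0
    labels, assigned = assign_boxes(proposals, gt_boxes, pos_iou, neg_iou)
    rng = rng if rng is not None else np.random.default_rng(0)
    if batch is not None:
        pos_sel, neg_sel = _sample_balanced(labels, batch, pos_fraction, rng)
    else:
        pos_sel = np.flatnonzero(labels == 1)
        neg_sel = np.flatnonzero(labels == 0)
    sampled = np.concatenate([pos_sel, neg_sel]).astype(int)
    targets = np.zeros(len(sampled))
    targets[:len(pos_sel)] = 1.0

    tensor_path = isinstance(cls_logits, Tensor) or isinstance(pred_boxes, Tensor)
    # classification: binary cross-entropy with logits
    if len(sampled) == 0:
        cls_loss = Tensor(np.float32(0.0)) if tensor_path else 0.0
    elif isinstance(cls_logits, Tensor):
        z = cls_logits[sampled]
        t = Tensor(targets.astype(cls_logits.dtype.type))
        # log(1+e^z) - t*z, computed stably as max(z,0) - t*z + log(1+e^-|z|)
        abs_z = z.maximum(-z)
        cls_loss = (z.maximum(0.0) - z * t + ((-abs_z).exp() + 1.0).log()).mean()
    else:
        z = np.zeros(len(sampled)) if cls_logits is None else \
            np.asarray(cls_logits, dtype=np.float64).reshape(-1)[sampled]
        cls_loss = float(np.mean(np.maximum(z, 0) - z * targets
                                 + np.log1p(np.exp(-np.abs(z)))))
    # regression: IoU-family loss over positives only
    if len(pos_sel) == 0:
        reg_loss = Tensor(np.float32(0.0)) if tensor_path else 0.0
    else:
        gt_pos = gt_boxes[assigned[pos_sel]]
        if isinstance(pred_boxes, Tensor):
            pred_pos = pred_boxes[pos_sel.astype(int)]
            reg_loss = batched_loss(loss_name, Tensor(gt_pos.astype(pred_pos.dtype.type)),
                                    pred_pos, reduction="mean")
        else:
            pred = proposals if pred_boxes is None else \
                np.asarray(pred_boxes, dtype=np.float64).reshape(-1, 4)
            reg_loss = batched_loss(loss_name, gt_pos, pred[pos_sel], "mean").value
    return cls_loss, reg_loss


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, score-descending."""
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    scores = np.asarray(scores, dtype=np.float64).reshape(-1)
    order = np.argsort(-scores, kind="stable")
    keep: list[int] = []
    while order.size:
        i = int(order[0])
        keep.append(i)
        if order.size == 1:
            break
        rest = order[1:]
        ious = evaluation.pairwise_iou(boxes[i:i + 1], boxes[rest])[0]
        order = rest[ious <= iou_threshold]
    return np.array(keep, dtype=int)


def _clamp_boxes_tensor(b: Tensor, image_size: tuple[int, int]) -> Tensor:
    """Clip to image bounds and enforce the minimum box size."""
    h, w = image_size
    x1 = b[:, 0].maximum(0.0).minimum(w - MIN_BOX_SIZE)
    y1 = b[:, 1].maximum(0.0).minimum(h - MIN_BOX_SIZE)
    x2 = b[:, 2].minimum(float(w)).maximum(x1 + MIN_BOX_SIZE)
    y2 = b[:, 3].minimum(float(h)).maximum(y1 + MIN_BOX_SIZE)
    return stack([x1, y1, x2, y2], axis=1)


class TwoStageDetector(Module):
    """Backbone + RPN + ROI head, trained with an IoU-family regression loss."""

    def __init__(self, backbone_config: BackboneConfig | None = None,
                 train_config: TrainConfig | None = None):
        super().__init__()
        self.backbone_config = backbone_config or BackboneConfig()
        self.train_config = train_config or TrainConfig()
        rng = np.random.default_rng(self.train_config.seed)
        self.backbone = MultiPathwayBackbone(self.backbone_config, rng)
        w = self.backbone.pathway.width
        a = len(ANCHOR_RATIOS)
        self.rpn_conv = Conv2d(w, w, 3, rng, padding=1)
        self.rpn_cls = Conv2d(w, a, 1, rng)
        self.rpn_cls.bias.data[:] = -2.0  # low-objectness prior for stable starts
        self.rpn_reg = Conv2d(w, 4 * a, 1, rng, init="zero")
        self.head_fc = Linear(w * 49, 128, rng)
        self.head_cls = Linear(128, 2, rng)
        self.head_reg = Linear(128, 4, rng)
        self.head_reg.weight.data *= 0.0  # start refinement at the proposal
        self._rng = rng

    # -- forward pieces ------------------------------------------------
    def rpn_forward(self, pyramids: dict[int, Tensor], anchors: AnchorSet):
        """Flattened objectness logits and predicted corner boxes, level-major,
        aligned with ``anchors.all_boxes``."""
        logits_parts, box_parts = [], []
        a = len(ANCHOR_RATIOS)
        for lvl in LEVELS:
            feat = self.rpn_conv(pyramids[lvl]).relu()
            cls = self.rpn_cls(feat)          # (1, A, H, W)
            reg = self.rpn_reg(feat)          # (1, 4A, H, W)
            _, _, gh, gw = cls.shape
            logits_parts.append(cls.transpose(0, 2, 3, 1).reshape(gh * gw * a))
            offsets = reg.reshape(a, 4, gh, gw).transpose(2, 3, 0, 1).reshape(gh * gw * a, 4)
            anchor_t = Tensor(anchors.boxes_by_level[lvl].astype(np.float32))
            # offsets in units of half the level stride: small enough for
            # stable SGD, large enough to reach any box the level anchors
            box_parts.append(anchor_t + offsets * (0.5 * STRIDES[lvl]))
        logits = concat(logits_parts, axis=0)
        boxes = concat(box_parts, axis=0)
        return logits, _clamp_boxes_tensor(boxes, anchors.image_size)

    def proposals_from_rpn(self, logits: Tensor, boxes: Tensor,
                           training: bool) -> tuple[np.ndarray, np.ndarray]:
        cfg = self.train_config
        with no_grad():
            z = logits.numpy().astype(np.float64)
            scores = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                              np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
            raw = boxes.numpy().astype(np.float64)
        top = min(cfg.pre_nms_top, len(scores))
        order = np.argsort(-scores, kind="stable")[:top]
        keep = nms(raw[order], scores[order], cfg.rpn_nms_iou)
        n_post = cfg.post_nms_top if training else max(cfg.post_nms_top // 2, 1)
        keep = keep[:n_post]
        return raw[order][keep], scores[order][keep]

    def roi_features(self, pyramids: dict[int, Tensor], rois: np.ndarray) -> Tensor:
        """7x7 bilinear pooling of each ROI from its size-matched level."""
        rois = np.asarray(rois, dtype=np.float64).reshape(-1, 4)
        areas = np.clip((rois[:, 2] - rois[:, 0]) * (rois[:, 3] - rois[:, 1]), 1e-6, None)
        levels = np.clip(2 + np.floor(np.log2(np.sqrt(areas) / 16.0 + 1e-9)), 2, 5).astype(int)
        out_parts: list[Tensor] = []
        out_order: list[np.ndarray] = []
        for lvl in (2, 3, 4, 5):
            sel = np.flatnonzero(levels == lvl)
            if len(sel) == 0:
                continue
            out_parts.append(self._roi_align_level(pyramids[lvl], rois[sel], STRIDES[lvl]))
            out_order.append(sel)
        order = np.concatenate(out_order)
        feats = concat(out_parts, axis=0)
        inv = np.empty(len(order), dtype=int)
        inv[order] = np.arange(len(order))
        return feats[inv]

    @staticmethod
    def _roi_align_level(feat: Tensor, rois: np.ndarray, stride: int) -> Tensor:
        _, c, fh, fw = feat.shape
        r = len(rois)
        # bin centers in feature coordinates (half-pixel convention)
        xs = (rois[:, 0, None] + (np.arange(7)[None, :] + 0.5)
              * (rois[:, 2] - rois[:, 0])[:, None] / 7.0) / stride - 0.5
        ys = (rois[:, 1, None] + (np.arange(7)[None, :] + 0.5)
              * (rois[:, 3] - rois[:, 1])[:, None] / 7.0) / stride - 0.5
        xs = np.clip(xs, 0, fw - 1)
        ys = np.clip(ys, 0, fh - 1)
        x0 = np.floor(xs).astype(int)
        y0 = np.floor(ys).astype(int)
        x1 = np.minimum(x0 + 1, fw - 1)
        y1 = np.minimum(y0 + 1, fh - 1)
        wx = (xs - x0).astype(np.float32)
        wy = (ys - y0).astype(np.float32)
        fmap = feat.reshape(c, fh, fw)
        # gather the four corners for every (roi, bin_y, bin_x) pair
        yy0 = np.broadcast_to(y0[:, :, None], (r, 7, 7))
        yy1 = np.broadcast_to(y1[:, :, None], (r, 7, 7))
        xx0 = np.broadcast_to(x0[:, None, :], (r, 7, 7))
        xx1 = np.broadcast_to(x1[:, None, :], (r, 7, 7))
        wyy = np.broadcast_to(wy[:, :, None], (r, 7, 7)).astype(np.float32)
        wxx = np.broadcast_to(wx[:, None, :], (r, 7, 7)).astype(np.float32)
        v00 = fmap[:, yy0, xx0]
        v01 = fmap[:, yy0, xx1]
        v10 = fmap[:, yy1, xx0]
        v11 = fmap[:, yy1, xx1]
        top = v00 * (1 - wxx) + v01 * wxx
        bot = v10 * (1 - wxx) + v11 * wxx
        pooled = top * (1 - wyy) + bot * wyy      # (C, R, 7, 7)
        return pooled.transpose(1, 0, 2, 3).reshape(r, c * 49)

    def head_forward(self, pyramids: dict[int, Tensor], rois: np.ndarray,
                     image_size: tuple[int, int]):
        feats = self.roi_features(pyramids, rois)
        hidden = self.head_fc(feats).relu()
        logits = self.head_cls(hidden)            # (R, 2)
        offsets = self.head_reg(hidden)           # (R, 4) relative corner shifts
        rw = (rois[:, 2] - rois[:, 0]).astype(np.float32)
        rh = (rois[:, 3] - rois[:, 1]).astype(np.float32)
        # offsets are in units of a tenth of the proposal size (the usual
        # delta weighting), which keeps refinement steps small and stable
        scale = Tensor(0.1 * np.stack([rw, rh, rw, rh], axis=1))
        boxes = Tensor(rois.astype(np.float32)) + offsets * scale
        return logits, _clamp_boxes_tensor(boxes, image_size)

    # -- losses --------------------------------------------------------
    def sample_losses(self, group: np.ndarray, gt_boxes: np.ndarray,
                      anchors: AnchorSet, rng: np.random.Generator):
        """Total loss (Tensor) and a float breakdown for one sample."""
        cfg = self.train_config
        pyramids = self.backbone(Tensor(np.asarray(group, dtype=np.float32)))
        logits, pred_boxes = self.rpn_forward(pyramids, anchors)
        rpn_loss_name = cfg.loss_name if cfg.vdiou_in_rpn else cfg.rpn_loss_fallback
        rpn_cls, rpn_reg = assign_and_losses(
            anchors.all_boxes, gt_boxes, rpn_loss_name,
            cls_logits=logits, pred_boxes=pred_boxes,
            pos_iou=cfg.rpn_pos_iou, neg_iou=cfg.rpn_neg_iou,
            batch=cfg.rpn_batch, pos_fraction=cfg.rpn_pos_fraction, rng=rng)
        proposals, _ = self.proposals_from_rpn(logits, pred_boxes, training=True)
        if len(gt_boxes):
            proposals = np.concatenate([proposals, gt_boxes])  # guarantees positives
        labels, assigned = assign_boxes(proposals, gt_boxes,
                                        cfg.head_pos_iou, cfg.head_pos_iou,
                                        allow_low_quality=False)
        pos_sel, neg_sel = _sample_balanced(labels, cfg.head_batch,
                                            cfg.head_pos_fraction, rng)
        sampled = np.concatenate([pos_sel, neg_sel]).astype(int)
        zero = Tensor(np.float32(0.0))
        if len(sampled) == 0:
            head_cls = head_reg = zero
        else:
            rois = proposals[sampled]
            logits2, boxes2 = self.head_forward(pyramids, rois, anchors.image_size)
            targets = np.zeros(len(sampled), dtype=int)
            targets[:len(pos_sel)] = 1
            probs = logits2.softmax(axis=-1)
            picked = probs[np.arange(len(sampled)), targets]
            head_cls = -(picked.clamp_min(1e-12).log()).mean()
            if len(pos_sel):
                gt_pos = gt_boxes[assigned[pos_sel]].astype(np.float32)
                head_reg = batched_loss(cfg.loss_name, Tensor(gt_pos),
                                        boxes2[np.arange(len(pos_sel))], "mean")
            else:
                head_reg = zero
        total = rpn_cls + rpn_reg + head_cls + head_reg
        parts = {"rpn_cls": float(rpn_cls.numpy()), "rpn_reg": float(rpn_reg.numpy()),
                 "head_cls": float(head_cls.numpy()), "head_reg": float(head_reg.numpy())}
        return total, parts


def _dataset_split(dataset):
    if isinstance(dataset, dict):
        return list(dataset.get("train", [])), list(dataset.get("val", []))
    return list(dataset), []


def train(dataset, config: TrainConfig | None = None,
          backbone_config: BackboneConfig | None = None,
          model: TwoStageDetector | None = None,
          checkpoint_path=None, progress: bool = False):
    """Train a detector with SGD on grouped-slice samples.

    ``dataset`` is either a sequence of samples or ``{"train": [...],
    "val": [...]}``; each sample is a mapping with ``group`` ((pathways, 3,
    H, W) float array), ``boxes`` ((N, 4) corner boxes of the key slice) and
    ``image_id``.  Returns ``(model, log)`` where the log holds per-iteration
    losses, per-epoch means, and validation sensitivity@2FP per epoch when a
    validation split is present.  Raises on empty data or non-finite loss.
    """
    config = config or TrainConfig()
    train_samples, val_samples = _dataset_split(dataset)
    if not train_samples:
        raise ValueError("empty training dataset")
    if model is None:
        model = TwoStageDetector(backbone_config, config)
    rng = np.random.default_rng(config.seed + 1)
    h, w = np.asarray(train_samples[0]["group"]).shape[-2:]
    anchors = generate_anchors((h, w))
    opt = SGD(model.parameters(), lr=config.lr, momentum=config.momentum,
              clip_norm=config.grad_clip)
    log = {"iter_loss": [], "epoch_loss": [], "val_sensitivity_2fp": [],
           "val_map": [], "epochs": config.epochs, "loss_name": config.loss_name}
    order = np.arange(len(train_samples))
    for epoch in range(config.epochs):
        if epoch == config.decay_epoch:
            opt.lr *= config.decay_factor
        rng.shuffle(order)
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            total = None
            for i in idx:
                s = train_samples[i]
                loss, _ = model.sample_losses(np.asarray(s["group"]),
                                              np.asarray(s["boxes"], dtype=np.float64).reshape(-1, 4),
                                              anchors, rng)
                total = loss if total is None else total + loss
            total = total * (1.0 / len(idx))
            value = float(total.numpy())
            if not math.isfinite(value):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {value}")
            total.backward()
            opt.step()
            log["iter_loss"].append(value)
            epoch_losses.append(value)
        log["epoch_loss"].append(float(np.mean(epoch_losses)))
        if val_samples:
            sens, vmap = _validate(model, val_samples, anchors)
            log["val_sensitivity_2fp"].append(sens)
            log["val_map"].append(vmap)
        if progress:
            msg = f"epoch {epoch}: loss {log['epoch_loss'][-1]:.4f}"
            if val_samples:
                msg += f"  val sens@2FP {log['val_sensitivity_2fp'][-1]:.3f}  mAP {log['val_map'][-1]:.3f}"
            print(msg)
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, model,
                        meta={"train_config": vars(config).copy(),
                              "backbone_config": vars(model.backbone_config).copy(),
                              "log": log})
    return model, log


def _validate(model, val_samples, anchors, score_threshold=0.05, nms_iou=0.5):
    dets, gts = {}, {}
    for s in val_samples:
        img = s["image_id"]
        gts[img] = np.asarray(s["boxes"], dtype=np.float64).reshape(-1, 4)
        found = predict(model, np.asarray(s["group"]), score_threshold=score_threshold,
                        nms_iou=nms_iou, image_id=img, anchors=anchors)
        dets[img] = (np.array([[d.box.x1, d.box.y1, d.box.x2, d.box.y2] for d in found])
                     .reshape(-1, 4),
                     np.array([d.score for d in found]))
    total_gt = sum(len(g) for g in gts.values())
    if total_gt == 0:
        return float("nan"), float("nan")
    curve = evaluation.froc_curve(dets, gts)
    sens = evaluation.sensitivity_at_fps(curve, 2.0)
    vmap = evaluation.map_coco(dets, gts)
    return float(sens), float(vmap)


def predict(model: TwoStageDetector, sample_group, score_threshold: float = 0.05,
            nms_iou: float = 0.5, image_id: str = "0",
            anchors: AnchorSet | None = None) -> list[Detection]:
    """Detections for one grouped-slice sample, sorted by score descending."""
    group = np.asarray(sample_group, dtype=np.float32)
    h, w = group.shape[-2:]
    if anchors is None or anchors.image_size != (h, w):
        anchors = generate_anchors((h, w))
    with no_grad():
        pyramids = model.backbone(Tensor(group))
        logits, boxes = model.rpn_forward(pyramids, anchors)
        proposals, _ = model.proposals_from_rpn(logits, boxes, training=False)
        if len(proposals) == 0:
            return []
        logits2, boxes2 = model.head_forward(pyramids, proposals, (h, w))
        probs = logits2.softmax(axis=-1).numpy()[:, 1]
        final = boxes2.numpy().astype(np.float64)
    keep = probs >= score_threshold
    final, probs = final[keep], probs[keep]
    if len(final) == 0:
        return []
    kept = nms(final, probs, nms_iou)
    out = []
    for i in kept:
        b = final[i]
        if b[2] - b[0] <= MIN_BOX_SIZE or b[3] - b[1] <= MIN_BOX_SIZE:
            continue
        out.append(Detection(image_id=image_id,
                             box=Box(float(b[0]), float(b[1]), float(b[2]), float(b[3])),
                             score=float(probs[i])))
    return out


def load_detector(checkpoint_path) -> tuple[TwoStageDetector, dict]:
    """Rebuild a detector from a training checkpoint."""
    payload = load_checkpoint(checkpoint_path)
    meta = payload["meta"]
    bc = BackboneConfig(**meta["backbone_config"])
    tc = TrainConfig(**meta["train_config"])
    model = TwoStageDetector(bc, tc)
    model.load_state_dict(payload["state"])
    return model, meta
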