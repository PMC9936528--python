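"""IoU-family bounding-box regression losses: IoU, GIoU, DIoU, CIoU and the
vertex-distance IoU (VDIoU) loss.

All losses share the form ``L = iou_term + penalty_term`` with
``iou_term = 1 - IoU``.  The penalties are, for a ground-truth box GT and a
region proposal RP with minimum bounding rectangle MBR:

* GIoU:   ``(area(MBR) - area(GT ∪ RP)) / area(MBR)``
* DIoU:   ``d^2 / c^2`` — squared center distance over squared MBR diagonal
* CIoU:   DIoU plus ``α·υ`` with
  ``υ = (4/π²)(arctan(w_GT/h_GT) - arctan(w_RP/h_RP))²`` and
  ``α = υ / ((1 - IoU) + υ)``
* VDIoU:  ``(AE + BF + CG + DH) / (2·XY)`` — the Euclidean distances between
  same-named corners (top-left to top-left, and so on) summed and divided by
  twice the MBR diagonal ``XY``.

The vertex-distance penalty stays informative where the older penalties
degenerate: it separates proposals strictly inside the ground truth (where
GIoU reduces to IoU) and concentric proposals of equal area but different
aspect ratio (where DIoU reduces to IoU).

Boxes use the corner convention ``(x1, y1, x2, y2)`` with continuous 0-based
pixel coordinates and area ``(x2-x1)·(y2-y1)``; no +1 pixel offset.  Every
function accepts plain float arrays (exact float64 reference path) or
:class:`~pacdet.autodiff.Tensor` batches (differentiable training path).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Box", "MBR", "LossValue", "InvalidBoxError", "LOSS_NAMES",
    "iou", "iou_loss", "giou_loss", "diou_loss", "ciou_loss",
    "vdiou_penalty", "vdiou_loss", "batched_loss", "loss_terms",
    "minimum_bounding_rectangle", "loss_gradient",
]

LOSS_NAMES = ("iou", "giou", "diou", "ciou", "vdiou")

_SQRT_EPS = 1e-12  # clamp under sqrt on the differentiable path only


class InvalidBoxError(ValueError):
    """Raised for degenerate (zero-area or inverted) or non-finite boxes."""


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle in continuous 0-based pixel coordinates."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self):
        vals = (self.x1, self.y1, self.x2, self.y2)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidBoxError(f"non-finite box coordinates {vals}")
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise InvalidBoxError(
                f"degenerate box {vals}: requires x2 > x1 and y2 > y1")

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=np.float64)


@dataclass(frozen=True)
class MBR:
    """Minimum bounding rectangle of a GT/RP pair and its diagonal length."""

    box: Box
    diagonal: float


@dataclass(frozen=True)
class LossValue:
    """A scalar loss split into its IoU term and additive penalty term."""

    value: float
    iou_term: float
    penalty_term: float
    components: dict = field(default_factory=dict)


ArrayLike = Union[np.ndarray, Tensor]


def _as_pair_arrays(gt, rp) -> tuple[np.ndarray, np.ndarray]:
    g = gt.as_array() if isinstance(gt, Box) else np.asarray(gt, dtype=np.float64)
    r = rp.as_array() if isinstance(rp, Box) else np.asarray(rp, dtype=np.float64)
    for arr, tag in ((g, "gt"), (r, "rp")):
        if arr.shape[-1] != 4:
            raise InvalidBoxError(f"{tag} must have 4 coordinates, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise InvalidBoxError(f"{tag} contains non-finite coordinates")
        if np.any(arr[..., 2] <= arr[..., 0]) or np.any(arr[..., 3] <= arr[..., 1]):
            raise InvalidBoxError(f"{tag} contains degenerate boxes (x2<=x1 or y2<=y1)")
    return g, r


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _maximum(a, b):
    if _is_tensor(a):
        return a.maximum(b)
    if _is_tensor(b):
        return b.maximum(a)  # max is symmetric
    return np.maximum(a, b)


def _minimum(a, b):
    if _is_tensor(a):
        return a.minimum(b)
    if _is_tensor(b):
        return b.minimum(a)
    return np.minimum(a, b)


def _sqrt(x, safe: bool):
    if _is_tensor(x):
        return x.clamp_min(_SQRT_EPS).sqrt() if safe else x.sqrt()
    return np.sqrt(x)


def _arctan(x):
    return x.arctan() if _is_tensor(x) else np.arctan(x)


def _split(b):
    return b[..., 0], b[..., 1], b[..., 2], b[..., 3]


def loss_terms(name: str, gt: ArrayLike, rp: ArrayLike):
    """Return ``(iou_term, penalty_term)`` for batches of box pairs.

    ``gt``/``rp`` are ``(..., 4)`` arrays or Tensors; Tensor inputs produce a
    differentiable graph (with an epsilon-guarded sqrt), plain arrays follow
    the exact reference arithmetic.
    """
    if name not in LOSS_NAMES:
        raise ValueError(f"unknown loss {name!r}; expected one of {LOSS_NAMES}")
    tensor_path = _is_tensor(gt) or _is_tensor(rp)
    gx1, gy1, gx2, gy2 = _split(gt)
    rx1, ry1, rx2, ry2 = _split(rp)

    garea = (gx2 - gx1) * (gy2 - gy1)
    rarea = (rx2 - rx1) * (ry2 - ry1)
    iw = _maximum(_minimum(gx2, rx2) - _maximum(gx1, rx1), 0.0)
    ih = _maximum(_minimum(gy2, ry2) - _maximum(gy1, ry1), 0.0)
    inter = iw * ih
    union = garea + rarea - inter
    iou_val = inter / union
    iou_term = 1.0 - iou_val

    if name == "iou":
        return iou_term, iou_term * 0.0

    # minimum bounding rectangle of the pair
    mx1 = _minimum(gx1, rx1)
    my1 = _minimum(gy1, ry1)
    mx2 = _maximum(gx2, rx2)
    my2 = _maximum(gy2, ry2)

    if name == "giou":
        marea = (mx2 - mx1) * (my2 - my1)
        return iou_term, (marea - union) / marea

    c2 = (mx2 - mx1) ** 2 + (my2 - my1) ** 2  # squared MBR diagonal

    if name == "vdiou":
        diag = _sqrt(c2, safe=False)  # > 0 for any valid pair
        dist_sum = None
        for gx, gy, rx, ry in (
            (gx1, gy1, rx1, ry1),  # top-left
            (gx2, gy1, rx2, ry1),  # top-right
            (gx2, gy2, rx2, ry2),  # bottom-right
            (gx1, gy2, rx1, ry2),  # bottom-left
        ):
            d = _sqrt((gx - rx) ** 2 + (gy - ry) ** 2, safe=tensor_path)
            dist_sum = d if dist_sum is None else dist_sum + d
        return iou_term, dist_sum / (2.0 * diag)

    # DIoU / CIoU share the center-distance term
    d2 = (0.5 * (gx1 + gx2) - 0.5 * (rx1 + rx2)) ** 2 \
        + (0.5 * (gy1 + gy2) - 0.5 * (ry1 + ry2)) ** 2
    diou_pen = d2 / c2
    if name == "diou":
        return iou_term, diou_pen

    # CIoU aspect-ratio term
    upsilon = (4.0 / math.pi ** 2) * (
        _arctan((gx2 - gx1) / (gy2 - gy1)) - _arctan((rx2 - rx1) / (ry2 - ry1))) ** 2
    if tensor_path:
        alpha = upsilon / (iou_term + upsilon).clamp_min(1e-9)
    else:
        denom = iou_term + upsilon
        with np.errstate(invalid="ignore", divide="ignore"):
            alpha = np.where(denom > 0.0, upsilon / np.where(denom > 0.0, denom, 1.0), 0.0)
    return iou_term, diou_pen + alpha * upsilon


def _scalar_loss(name: str, gt, rp) -> LossValue:
    g, r = _as_pair_arrays(gt, rp)
    it, pt = loss_terms(name, g, r)
    it, pt = float(it), float(pt)
    return LossValue(value=it + pt, iou_term=it, penalty_term=pt,
                     components={"loss": name})


def iou(gt, rp) -> float:
    """Intersection-over-union of two boxes, in [0, 1]."""
    g, r = _as_pair_arrays(gt, rp)
    it, _ = loss_terms("iou", g, r)
    return float(1.0 - it)


def iou_loss(gt, rp) -> LossValue:
    return _scalar_loss("iou", gt, rp)


def giou_loss(gt, rp) -> LossValue:
    return _scalar_loss("giou", gt, rp)


def diou_loss(gt, rp) -> LossValue:
    return _scalar_loss("diou", gt, rp)


def ciou_loss(gt, rp) -> LossValue:
    return _scalar_loss("ciou", gt, rp)


def vdiou_loss(gt, rp) -> LossValue:
    return _scalar_loss("vdiou", gt, rp)


def vdiou_penalty(gt, rp) -> float:
    """Sum of the four corner-to-corner distances over twice the MBR diagonal."""
    return vdiou_loss(gt, rp).penalty_term


def minimum_bounding_rectangle(gt, rp) -> MBR:
    g, r = _as_pair_arrays(gt, rp)
    x1 = min(g[0], r[0])
    y1 = min(g[1], r[1])
    x2 = max(g[2], r[2])
    y2 = max(g[3], r[3])
    return MBR(box=Box(x1, y1, x2, y2),
               diagonal=float(np.hypot(x2 - x1, y2 - y1)))


def _stack_boxes(boxes) -> np.ndarray:
    if isinstance(boxes, np.ndarray):
        return np.asarray(boxes, dtype=np.float64)
    return np.stack([b.as_array() if isinstance(b, Box) else np.asarray(b, dtype=np.float64)
                     for b in boxes])


def batched_loss(name: str, gts, rps, reduction: str = "mean"):
    """Element-wise IoU-family loss over paired box sequences.

    ``gts``/``rps`` may be sequences of :class:`Box`, ``(N, 4)`` arrays, or
    Tensors.  Tensor input returns a Tensor (differentiable w.r.t. the box
    coordinates); array input returns a :class:`LossValue` for ``mean``/``sum``
    or a per-pair float array for ``reduction='none'``.
    """
    if reduction not in ("none", "mean", "sum"):
        raise ValueError(f"unknown reduction {reduction!r}")
    if _is_tensor(gts) or _is_tensor(rps):
        if len(gts) != len(rps):
            raise ValueError(f"length mismatch: {len(gts)} gts vs {len(rps)} rps")
        it, pt = loss_terms(name, gts, rps)
        per_pair = it + pt
        if reduction == "none":
            return per_pair
        return per_pair.mean() if reduction == "mean" else per_pair.sum()
    g = _stack_boxes(gts)
    r = _stack_boxes(rps)
    if g.shape != r.shape:
        raise ValueError(f"length mismatch: {g.shape[0]} gts vs {r.shape[0]} rps")
    g, r = _as_pair_arrays(g, r)
    it, pt = loss_terms(name, g, r)
    if reduction == "none":
        return it + pt
    red = np.mean if reduction == "mean" else np.sum
    return LossValue(value=float(red(it + pt)), iou_term=float(red(it)),
                     penalty_term=float(red(pt)), components={"loss": name, "n": len(g)})


def loss_gradient(name: str, gt, rp) -> np.ndarray:
    """Gradient of the summed loss w.r.t. the RP corner coordinates.

    Computed in float64 by reverse-mode differentiation of the same arithmetic
    the loss uses; shape matches ``rp`` (``(4,)`` or ``(N, 4)``).
    """
    g, r = _as_pair_arrays(gt, rp)
    squeeze = g.ndim == 1
    if squeeze:
        g, r = g[None], r[None]
    gt_t = Tensor(g)
    rp_t = Tensor(r, requires_grad=True)
    total = batched_loss(name, gt_t, rp_t, reduction="sum")
    total.backward()
    grad = rp_t.grad
    return grad[0] if squeeze else grad
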