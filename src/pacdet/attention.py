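"""Context attention (CA), position attention (PA) and the PAC blocks built
from them.

Both attention variants share one scheme: 1x1 convolutions embed a feature
map into query/key spaces, the HWxHW correlation matrix ``S = Qᵀ K`` is
row-softmaxed, and averaging the row-stochastic matrix over the query axis
yields a single weight per spatial location — a ``1xHxW`` attention map that
rescales a value-transformed feature map elementwise.

When a block applies the map to a value-transformed feature it rescales it
to mean one (multiplying by H*W), so uniform attention acts as the identity
and salient locations are amplified rather than the whole map being
attenuated by 1/(H*W); ``weight_map`` still exposes the raw distribution
(non-negative, summing to 1 over the grid).

CA computes everything from one map (the SPP-refined top of the bottom-up
path), sharpening semantically correlated regions.  PA computes both the
weight map and the value transform from the *bottom-up* feature ``Fn``,
whose positions are exact; the attention-reweighted bottom-up content is
then fused with the top-down feature ``Pn`` (blurred by repeated
upsampling) inside the PAC blocks, so each pyramid level keeps full-
resolution positional content alongside the semantic top-down stream.

PAC blocks compose these: the top-level block sums (or concatenates) CA and
PA outputs through a 1x1 convolution; the lateral block concatenates the PA
output with a 1x1-transformed ``Pn`` and reduces back to the pyramid width.

The dense correlation is quadratic in spatial size, so the modules refuse
``H*W`` beyond a configured budget; the lateral block may instead compute
attention on an average-pooled grid and bilinearly upsample the weight map
(flag-controlled).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat
from .nn import Conv2d, Module

__all__ = [
    "AttentionBudgetError", "ContextAttention", "PositionAttention",
    "PACTop", "PACLateral",
    "context_attention", "position_attention", "pac_top", "pac_lateral",
]

DEFAULT_BUDGET = 4096  # max H*W for the dense HWxHW correlation


class AttentionBudgetError(RuntimeError):
    """Raised when a dense correlation would exceed the configured budget."""


def _as_batched_tensor(x) -> tuple[Tensor, bool]:
    """Accept CxHxW arrays or NxCxHxW tensors; return NCHW tensor + flag."""
    if isinstance(x, Tensor):
        if x.ndim == 3:
            return x.reshape((1,) + x.shape), True
        return x, False
    arr = np.asarray(x)
    if arr.dtype not in (np.float32, np.float64):
        arr = arr.astype(np.float32)
    if arr.ndim == 3:
        return Tensor(arr[None]), True
    if arr.ndim == 4:
        return Tensor(arr), False
    raise ValueError(f"expected CxHxW or NxCxHxW input, got shape {arr.shape}")


def _check_budget(h: int, w: int, budget: int, override: bool) -> None:
    if not override and h * w > budget:
        raise AttentionBudgetError(
            f"dense {h * w}x{h * w} correlation exceeds budget H*W <= {budget}; "
            f"pass override_budget=True or enable the pooled fallback")


def _pooled_weight_map(q: Tensor, k: Tensor, scale: float | None) -> Tensor:
    """Row-softmax the HWxHW correlation and average over the query axis.

    q, k: (N, C, H, W).  Returns the attention map with shape (N, 1, H, W);
    its entries are non-negative and sum to 1 over the spatial grid.
    """
    n, c, h, w = q.shape
    qf = q.reshape(n, c, h * w)
    kf = k.reshape(n, c, h * w)
    s = qf.transpose(0, 2, 1) @ kf  # (N, HW, HW); rows indexed by query
    if scale is not None:
        s = s * scale
    attn = s.softmax(axis=-1)
    pooled = attn.mean(axis=1)  # average the row-stochastic rows -> (N, HW)
    return pooled.reshape(n, 1, h, w)


class ContextAttention(Module):
    """Self-attention weight map from a single feature map.

    The 1x1 query/key/value transforms are bias-free so that a zero input
    yields a zero output.  ``scaled`` optionally applies the 1/sqrt(C)
    temperature (off by default).
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 budget: int = DEFAULT_BUDGET, scaled: bool = False):
        super().__init__()
        self.channels = channels
        self.budget = budget
        self.scale = 1.0 / np.sqrt(channels) if scaled else None
        self.w_q = Conv2d(channels, channels, 1, rng, bias=False)
        self.w_k = Conv2d(channels, channels, 1, rng, bias=False)
        self.w_v = Conv2d(channels, channels, 1, rng, bias=False)

    def __call__(self, p5: Tensor, override_budget: bool = False) -> Tensor:
        _, _, h, w = p5.shape
        _check_budget(h, w, self.budget, override_budget)
        weight = _pooled_weight_map(self.w_q(p5), self.w_k(p5), self.scale)
        return weight * float(h * w) * self.w_v(p5)

    def weight_map(self, p5: Tensor, override_budget: bool = False) -> Tensor:
        _, _, h, w = p5.shape
        _check_budget(h, w, self.budget, override_budget)
        return _pooled_weight_map(self.w_q(p5), self.w_k(p5), self.scale)


class PositionAttention(Module):
    """Attention over the position-accurate map ``fn``: the pooled weight map
    and the value transform are both computed from ``fn``, yielding
    attention-reweighted bottom-up content.  The semantically rich top-down
    map ``pn`` defines the expected spatial dims (the PAC blocks fuse it with
    this output).

    When ``H*W`` exceeds the budget and ``pool_fallback`` is set, the
    correlation is computed on an average-pooled grid and the weight map
    bilinearly upsampled back.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 fn_channels: int | None = None, budget: int = DEFAULT_BUDGET,
                 scaled: bool = False, pool_fallback: bool = False):
        super().__init__()
        self.channels = channels
        self.budget = budget
        self.pool_fallback = pool_fallback
        fc = fn_channels if fn_channels is not None else channels
        self.scale = 1.0 / np.sqrt(fc) if scaled else None
        self.w_q = Conv2d(fc, fc, 1, rng, bias=False)
        self.w_k = Conv2d(fc, fc, 1, rng, bias=False)
        self.w_v = Conv2d(fc, channels, 1, rng, bias=False)

    def weight_map(self, fn: Tensor, override_budget: bool = False) -> Tensor:
        n, c, h, w = fn.shape
        if h * w > self.budget and self.pool_fallback and not override_budget:
            factor = 1
            hh, ww = h, w
            while hh * ww > self.budget and hh % 2 == 0 and ww % 2 == 0:
                hh, ww, factor = hh // 2, ww // 2, factor * 2
            if hh * ww > self.budget:
                raise AttentionBudgetError(
                    f"pooled grid {hh}x{ww} still exceeds budget {self.budget}")
            pooled_fn = fn.reshape(n, c, hh, factor, ww, factor).mean(axis=(3, 5))
            wmap = _pooled_weight_map(self.w_q(pooled_fn), self.w_k(pooled_fn), self.scale)
            for _ in range(int(np.log2(factor))):
                wmap = wmap.upsample_bilinear2x()
            # renormalize so the upsampled map still sums to 1 over the grid
            wmap = wmap * (1.0 / float(factor * factor))
            return wmap
        _check_budget(h, w, self.budget, override_budget)
        return _pooled_weight_map(self.w_q(fn), self.w_k(fn), self.scale)

    def __call__(self, pn: Tensor, fn: Tensor, override_budget: bool = False) -> Tensor:
        if pn.shape[2:] != fn.shape[2:]:
            raise ValueError(
                f"spatial dims differ: pn {pn.shape[2:]} vs fn {fn.shape[2:]}")
        _, _, h, w = fn.shape
        return self.weight_map(fn, override_budget) * float(h * w) * self.w_v(fn)


class PACTop(Module):
    """Top-level PAC: CA and PA outputs combined through a 1x1 convolution.

    ``combine`` is ``"sum"`` (default) or ``"concat"``.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 combine: str = "sum", budget: int = DEFAULT_BUDGET,
                 scaled: bool = False):
        super().__init__()
        if combine not in ("sum", "concat"):
            raise ValueError(f"combine must be 'sum' or 'concat', got {combine!r}")
        self.combine = combine
        self.ca = ContextAttention(channels, rng, budget=budget, scaled=scaled)
        self.pa = PositionAttention(channels, rng, budget=budget, scaled=scaled)
        cin = channels if combine == "sum" else 2 * channels
        self.w_out = Conv2d(cin, channels, 1, rng)

    def __call__(self, p5_after_spp: Tensor, f5: Tensor,
                 override_budget: bool = False) -> Tensor:
        e_ca = self.ca(p5_after_spp, override_budget)
        e_pa = self.pa(p5_after_spp, f5, override_budget)
        if self.combine == "sum":
            return self.w_out(e_ca + e_pa)
        return self.w_out(concat([e_ca, e_pa], axis=1))


class PACLateral(Module):
    """Lateral PAC: PA output concatenated with a 1x1-transformed top-down map,
    reduced back to the pyramid width by a second 1x1 convolution."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 fn_channels: int | None = None, budget: int = DEFAULT_BUDGET,
                 scaled: bool = False, pool_fallback: bool = True):
        super().__init__()
        self.pa = PositionAttention(channels, rng, fn_channels=fn_channels,
                                    budget=budget, scaled=scaled,
                                    pool_fallback=pool_fallback)
        self.w_lat = Conv2d(channels, channels, 1, rng)
        self.w_out = Conv2d(2 * channels, channels, 1, rng)

    def __call__(self, pn: Tensor, fn: Tensor, override_budget: bool = False) -> Tensor:
        e = self.pa(pn, fn, override_budget)
        return self.w_out(concat([e, self.w_lat(pn)], axis=1))


# -- functional wrappers over CxHxW arrays -----------------------------------

def _functional(module, *maps, override_budget=False):
    tensors = []
    squeeze = False
    for m in maps:
        t, sq = _as_batched_tensor(m)
        tensors.append(t)
        squeeze = squeeze or sq
    out = module(*tensors, override_budget=override_budget)
    arr = out.numpy()
    return arr[0] if squeeze else arr


def context_attention(p5, params: ContextAttention, override_budget: bool = False):
    """Apply CA to a CxHxW map; returns an array of the same shape."""
    return _functional(params, p5, override_budget=override_budget)


def position_attention(pn, fn, params: PositionAttention, override_budget: bool = False):
    """Apply PA; the weight map comes from ``fn``, the values from ``pn``."""
    return _functional(params, pn, fn, override_budget=override_budget)


def pac_top(p5_after_spp, f5, params: PACTop, override_budget: bool = False):
    return _functional(params, p5_after_spp, f5, override_budget=override_budget)


def pac_lateral(pn, fn, params: PACLateral, override_budget: bool = False):
    return _functional(params, pn, fn, override_budget=override_budget)
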