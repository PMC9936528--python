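"""Multi-pathway feature pyramid backbone with SPP and PAC connections.

Layout per pathway (one 3-channel slice image each):

* bottom-up convolutional stages produce ``F2..F5`` at strides 4..32;
* an SPP block (parallel stride-1 max pools, concatenated with the identity
  and reduced by a 1x1 convolution) enlarges the receptive field at ``F5``;
* the top pyramid map is the top-level PAC block (context + position
  attention) applied to the SPP output;
* each lower level bilinearly upsamples the map above and passes it with the
  matching bottom-up feature through a lateral PAC block (position attention
  only);
* an extra stride-64 level ``P6`` is a stride-2 subsampling of ``P5``.

The three pathways share every parameter; their pyramids are fused per level
by channel concatenation and a 1x1 convolution back to the pyramid width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attention import PACLateral, PACTop
from .autodiff import Tensor, concat
from .nn import Conv2d, Module

__all__ = ["BackboneConfig", "SPPBlock", "PyramidBackbone", "MultiPathwayBackbone",
           "spp_block", "forward_single_pathway", "multi_pathway_fuse", "LEVELS"]

LEVELS = (2, 3, 4, 5, 6)
STRIDES = {2: 4, 3: 8, 4: 16, 5: 32, 6: 64}


@dataclass
class BackboneConfig:
    """Configuration of the multi-pathway pyramid backbone.

    ``preset`` selects the bottom-up depth: ``"tiny"`` (one stem + four
    stride-2 stages at ``width`` channels, for desk-scale experiments) or
    ``"resnet50-like"`` (two 3x3 convolutions per stage at twice the width).
    """

    preset: str = "tiny"
    width: int = 32
    spp_kernels: tuple[int, ...] = (5, 9, 13)
    pathways: int = 3
    seed: int = 0
    combine: str = "sum"            # top-level PAC combination
    scaled_attention: bool = False  # 1/sqrt(C) temperature on Q.K
    attention_budget: int = 4096
    pa_pool_fallback: bool = True   # pooled-grid PA at large H*W

    def __post_init__(self):
        if self.pathways < 1:
            raise ValueError("pathway count must be >= 1")
        if self.width < 1:
            raise ValueError("pyramid width must be positive")
        if self.preset not in ("tiny", "resnet50-like"):
            raise ValueError(f"unknown preset {self.preset!r}")
        for k in self.spp_kernels:
            if k % 2 == 0 or k < 3:
                raise ValueError(f"SPP kernel sizes must be odd and >= 3, got {k}")


class SPPBlock(Module):
    """Spatial pyramid pooling: identity plus stride-1 same-size max pools of
    the configured kernel sizes, concatenated and reduced by a 1x1 conv."""

    def __init__(self, channels: int, kernel_sizes, rng: np.random.Generator):
        super().__init__()
        for k in kernel_sizes:
            if k % 2 == 0 or k < 3:
                raise ValueError(f"SPP kernel sizes must be odd and >= 3, got {k}")
        self.kernel_sizes = tuple(kernel_sizes)
        self.reduce = Conv2d(channels * (1 + len(self.kernel_sizes)), channels, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        pools = [x] + [x.maxpool2d(k, stride=1, padding=k // 2) for k in self.kernel_sizes]
        return self.reduce(concat(pools, axis=1))


class _BottomUp(Module):
    """Stem + four stride-2 stages emitting F2..F5, all at ``width`` channels."""

    def __init__(self, width: int, rng: np.random.Generator, deep: bool):
        super().__init__()
        self.deep = deep
        stem_w = max(width // 2, 8)
        self.stem = Conv2d(3, stem_w, 3, rng, stride=2, padding=1)
        self.stages = []
        cin = stem_w
        for i in range(4):
            convs = [Conv2d(cin, width, 3, rng, stride=2, padding=1)]
            if deep:
                convs.append(Conv2d(width, width, 3, rng, stride=1, padding=1))
            for j, c in enumerate(convs):
                setattr(self, f"stage{i}_conv{j}", c)
            self.stages.append(convs)
            cin = width

    def __call__(self, x: Tensor) -> dict[int, Tensor]:
        h = self.stem(x).relu()
        feats: dict[int, Tensor] = {}
        for i, convs in enumerate(self.stages):
            for c in convs:
                h = c(h).relu()
            feats[i + 2] = h  # F2 at stride 4 ... F5 at stride 32
        return feats


class PyramidBackbone(Module):
    """Single-pathway pyramid: bottom-up + SPP + PAC top + PAC laterals."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        w = config.width if config.preset == "tiny" else config.width * 2
        self.width = w
        self.bottom_up = _BottomUp(w, rng, deep=config.preset == "resnet50-like")
        self.spp = SPPBlock(w, config.spp_kernels, rng)
        self.pac_top = PACTop(w, rng, combine=config.combine,
                              budget=config.attention_budget,
                              scaled=config.scaled_attention)
        for lvl in (4, 3, 2):
            setattr(self, f"lateral{lvl}",
                    PACLateral(w, rng, budget=config.attention_budget,
                               scaled=config.scaled_attention,
                               pool_fallback=config.pa_pool_fallback))

    def __call__(self, image: Tensor) -> dict[int, Tensor]:
        _, _, h, w = image.shape
        if h % STRIDES[6] or w % STRIDES[6]:
            raise ValueError(f"input dims {h}x{w} must be divisible by {STRIDES[6]}")
        feats = self.bottom_up(image)
        top = self.spp(feats[5])
        pyr: dict[int, Tensor] = {}
        pyr[5] = self.pac_top(top, feats[5])
        for lvl in (4, 3, 2):
            up = pyr[lvl + 1].upsample_bilinear2x()
            pyr[lvl] = getattr(self, f"lateral{lvl}")(up, feats[lvl])
        pyr[6] = pyr[5].maxpool2d(1, stride=2)
        return pyr


class MultiPathwayBackbone(Module):
    """Weight-shared pathways over grouped slice images, fused per level."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.pathway = PyramidBackbone(config, rng)  # shared across all groups
        w = self.pathway.width
        for lvl in LEVELS:
            setattr(self, f"fuse{lvl}", Conv2d(w * config.pathways, w, 1, rng))

    def __call__(self, group: Tensor) -> dict[int, Tensor]:
        """``group``: (pathways, 3, H, W) slice images for one sample."""
        p, c, h, w = group.shape
        if p != self.config.pathways:
            raise ValueError(f"expected {self.config.pathways} pathway images, got {p}")
        pyramids = [self.pathway(group[i:i + 1]) for i in range(p)]
        return multi_pathway_fuse(pyramids, {lvl: getattr(self, f"fuse{lvl}")
                                             for lvl in LEVELS})


def multi_pathway_fuse(pathway_pyramids: list[dict[int, Tensor]],
                       fuse_convs: dict[int, Conv2d]) -> dict[int, Tensor]:
    """Channel-concatenate level-aligned pyramids and reduce to pyramid width."""
    first = pathway_pyramids[0]
    for pyr in pathway_pyramids[1:]:
        if set(pyr) != set(first):
            raise ValueError("pathway pyramids have different level sets")
        for lvl in first:
            if pyr[lvl].shape != first[lvl].shape:
                raise ValueError(f"shape mismatch at level {lvl}: "
                                 f"{pyr[lvl].shape} vs {first[lvl].shape}")
    return {lvl: fuse_convs[lvl](concat([pyr[lvl] for pyr in pathway_pyramids], axis=1))
            for lvl in first}


# -- functional wrappers -----------------------------------------------------

def spp_block(top_feature, kernel_sizes, params: SPPBlock | None = None,
              rng: np.random.Generator | None = None):
    """Apply SPP to a CxHxW array; a fresh identity-reduce block is built when
    no parameters are given (useful for oracle comparisons)."""
    arr = np.asarray(top_feature, dtype=np.float32)
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    if params is None:
        params = SPPBlock(arr.shape[1], kernel_sizes,
                          rng if rng is not None else np.random.default_rng(0))
    out = params(Tensor(arr)).numpy()
    return out[0] if squeeze else out


def forward_single_pathway(image, config: BackboneConfig,
                           model: PyramidBackbone | None = None) -> dict[int, np.ndarray]:
    """Run one 3-channel image through a single pathway pyramid.

    Returns per-level arrays keyed by pyramid level (2..6, strides 4..64).
    """
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None]
    if model is None:
        model = PyramidBackbone(config)
    pyr = model(Tensor(arr))
    return {lvl: t.numpy()[0] for lvl, t in pyr.items()}
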