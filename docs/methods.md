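# Methods

`pacdet` implements a multi-pathway feature-pyramid lesion detector whose two
distinctive ingredients are (i) position-attention guided connections (PAC)
in the pyramid's lateral links and (ii) a vertex-distance IoU (VDIoU)
regression loss. Everything below the public API — including the
reverse-mode array autodiff engine the models train on — is part of this
package and runs on numpy alone.

## Bounding-box losses

Boxes are axis-aligned rectangles `(x1, y1, x2, y2)` in continuous 0-based
pixel coordinates with area `(x2-x1)(y2-y1)`; no +1 pixel convention. All
losses decompose as `L = (1 - IoU) + penalty`:

| loss  | penalty |
|-------|---------|
| IoU   | 0 |
| GIoU  | `(area(MBR) - area(union)) / area(MBR)` |
| DIoU  | `d² / c²` (center distance over MBR diagonal) |
| CIoU  | DIoU + `α·υ`, `υ = (4/π²)(arctan w_g/h_g − arctan w_r/h_r)²`, `α = υ/((1−IoU)+υ)` |
| VDIoU | `(AE+BF+CG+DH) / (2·XY)` |

where MBR is the minimum bounding rectangle of the pair, `XY` its diagonal,
and `AE…DH` are Euclidean distances between *same-named* corners (top-left
to top-left, and so on) — the only correspondence under which the penalty
vanishes for identical boxes. `XY` is the diagonal of the *pair's* MBR, not
of the ground truth alone. The VDIoU penalty is bounded by 2 (each corner
distance is at most one diagonal), so the loss lives in [0, 3].

Numerical choices:

* `α` is defined as 0 at the `υ = (1−IoU) = 0` point (identical aspect and
  perfect overlap) to avoid 0/0.
* The float64 array path uses exact arithmetic; the differentiable Tensor
  path clamps the argument of the vertex-distance square roots at 1e-12 so
  gradients stay finite when corners coincide during training. Worked
  values and invariant tests run on the exact path.
* `α` is differentiated through (not treated as a constant), so analytic
  gradients match central differences of the full expression.
* Gradients are produced by reverse-mode autodiff of the same arithmetic;
  the test suite checks all five losses against central differences at 100
  random non-degenerate configurations (1e-4 relative).
* Degenerate (zero-area or inverted) boxes are rejected at the loss API;
  inside the detector, predicted boxes are clamped to a minimum side of
  1e-3 px before loss computation.

## Attention and PAC connections

Context attention (CA) and position attention (PA) share one mechanism:
bias-free 1x1 convolutions embed a map into query/key spaces, the `HW x HW`
correlation `S = QᵀK` is softmax-normalized along its last (key) axis, and
the row-stochastic matrix is averaged over the query axis, giving one weight
per location (`1xHxW`, non-negative, summing to 1). No `1/√C` temperature is
applied by default (flag available). The dense correlation is refused above
`H·W = 4096` unless overridden; lateral PA can instead compute the
correlation on an average-pooled grid and bilinearly upsample the weight map
(flag-controlled, used for large inputs).

Two design points deserve emphasis because the composition was genuinely
open:

* **Value source in PA.** PA receives the top-down map `Pn` (semantically
  rich, positionally blurred by repeated bilinear upsampling) and the
  bottom-up map `Fn` (positionally exact). The correlation — hence the
  weight map — comes from `Fn`. The value transform is *also* taken from
  `Fn`: PA emits attention-reweighted position-accurate content, which the
  lateral block then fuses with a 1x1-transformed `Pn`
  (`out = 1x1(concat(PA_out, 1x1(Pn)))`). The alternative (values from
  `Pn`) makes every lateral output a pure function of the top-down stream:
  no bottom-up content ever reaches the pyramid, the fine levels are
  spatially near-uniform, and a detector trained on them cannot localize —
  we verified this empirically (flat objectness maps, proposal recall ~0.1).
  With values from `Fn`, the lateral is a true pyramid fusion with an
  attention gate, which is also the reading under which "combining semantic
  information with the accurate position information of the shallow features
  extracted by the PA module" is literal.
* **Mean-one application of the weight map.** Averaged softmax rows sum to 1
  over the grid, i.e. average weight `1/HW` (~1/256 at a 16x16 level).
  Applied raw, the attention branch is two orders of magnitude smaller than
  the lateral branch and, in a network without per-layer normalization, it
  contributes nothing trainable. Blocks therefore apply the map scaled by
  `HW`: uniform attention is the identity, salient locations are amplified.
  `weight_map()` still exposes the sum-to-one distribution.

The top-level PAC combines CA and PA outputs by element-wise sum followed by
a 1x1 convolution (concatenation + 1x1 available behind a flag).

## Backbone

Per pathway: a stem convolution (stride 2) and four stride-2 stages emit
`F2..F5` at strides 4–32; an SPP block (stride-1 max pools of kernel sizes
5/9/13 concatenated with the identity, reduced by a 1x1 convolution) widens
the receptive field at `F5`; the top pyramid map applies the CA+PA PAC
block; each lower level bilinearly upsamples (half-pixel centers) the map
above and applies a PA-only lateral PAC; `P6` is a stride-2 subsampling of
`P5`. PAC is applied at every lateral level, including feeding `P6`
implicitly through `P5`. The three slice-group pathways share all
parameters; per level, pathway outputs are concatenated and reduced to the
pyramid width by a 1x1 convolution.

Presets: `tiny` (width 32, single conv per stage) is the desk-scale default
used by all experiments here; `resnet50-like` (double width, two convs per
stage) exists for scale but carries no pretrained weights.

## Detector

A minimal two-stage head over the fused pyramid:

* **Anchors** — one scale per level (16, 32, 64, 128, 256 at strides 4–64),
  ratios (0.5, 1, 2), centered on feature-grid cells.
* **RPN** — shared 3x3 conv + 1x1 objectness/offset heads. Offsets are
  additive corner shifts in units of half the level stride; regression is
  therefore directly on corner coordinates, which is what IoU-family losses
  require. Objectness bias starts at −2 (a low-objectness prior) so early
  proposal floods do not destabilize the head.
* **Assignment** — RPN: positive at IoU ≥ 0.7 plus best-anchor-per-GT
  promotion, negative below 0.3, sampled 1:1 up to 256; head: positive at
  IoU ≥ 0.5, 64 ROIs at one-quarter positive fraction. Sampling keeps the
  configured positive:negative *ratio* instead of padding with negatives —
  at a few hundred total iterations the positive signal must not be diluted.
  Ground-truth boxes are appended to the training proposals.
* **ROI head** — 7x7 bilinear pooling from the size-matched level
  (`level = 2 + log2(√area/16)`, clamped to 2–5), a 128-unit hidden layer,
  softmax classification and corner refinement in units of a tenth of the
  proposal size (the usual delta weighting).
* **Optimization** — SGD, momentum 0.9, base learning rate 0.004 decayed
  10x; mini-batch 2. Gradients are clipped to global norm 10 — the corner
  parameterization otherwise lets one early step throw predicted boxes far
  off their proposals. The configured IoU-family loss is applied in both
  the RPN and the head (flag to restrict to the head).

## Synthetic data

Volumes are `64x64x12` stacks: a smooth low-frequency background (Gaussian
filtered noise, σ = 8 px in-plane), additive Gaussian noise, and soft-edged
ellipsoidal lesions (`(1-ρ²)^0.7` profile). Tiers set contrast as a fraction
of the dynamic range, in-plane radius, and noise σ:

| tier   | contrast    | radius (px) | noise σ |
|--------|-------------|-------------|---------|
| easy   | 0.30–0.50   | 6–12        | 0.02    |
| medium | 0.15–0.30   | 4–9         | 0.04    |
| hard   | 0.05–0.15   | 3–6         | 0.06    |

Through-plane half-extent is 2–4 slices. Ground-truth boxes are the pixel
bounding boxes of the rendered support, computed by pixel scan at render
time, so annotations are exact by construction. One detector sample is made
per lesion *key slice* (the slice through the lesion center): nine
consecutive slices, edge-replicated, grouped into three 3-channel images.
The default dataset is 200 volumes with Poisson(1.2) lesions (at least one)
per volume, split 80/20 into train/validation *by volume*. Datasets are
written as 16-bit PNGs plus CSV and COCO-style JSON; everything is
reproducible from the seed recorded in the manifest.

What this emulates — and what it does not: grouped 3D context, low-contrast
blob targets, tiered difficulty, exact boxes. It has none of real CT's
anatomy, Hounsfield calibration, annotation noise, or lesion morphology
diversity, so passing the end-to-end test demonstrates that the pipeline
learns and evaluates correctly at desk scale, not that it detects real
lesions.

## Evaluation

Greedy score-ordered matching (ties by insertion order, logged convention),
each ground truth credited once, hit criterion IoU ≥ 0.5 (configurable).
FROC sweeps score cutoffs after a single matching pass with all detections.
`sensitivity_at_fps` uses a step-function (floor) read-out: the sensitivity
of the largest operating point with FPs/image ≤ target, 0 if none — this is
documented prominently since interpolating conventions report higher
numbers. The mean over the eight standard targets (0.125–8) is provided as
a labeled convenience. mAP is COCO-style: 101-point interpolated AP averaged
over IoU 0.50:0.05:0.95, at most 100 detections per image, single
foreground class. The test suite cross-checks AP against an independently
coded brute-force evaluator.

## Convergence simulation

Gradient descent directly on proposal corner coordinates with
normalized-gradient steps of `step_size x` (GT diagonal) per step
(`step_size` 0.02 by default, stable ordering verified at 0.01–0.05), a
validity projection (minimum side 1e-3), criterion IoU ≥ 0.9, and at most
500 steps. The initialization mixture is one-third each: overlapping
perturbations, proposals inside the GT, and disjoint proposals. This is a
proxy for training-time convergence speed, not a reproduction of any
full-training curve: its purpose is the qualitative ordering — plain IoU
has zero gradient on disjoint pairs and stalls there, while the
vertex-distance penalty pulls corners together from any start.

## Known limitations

* The desk-scale experiment shows no early-epoch mAP advantage for VDIoU
  over IoU: with easy-tier lesions every anchor and proposal already
  overlaps its target, so the disjoint-plateau regime where VDIoU provably
  helps (see the convergence simulation) almost never arises during
  detector training.
* The autodiff engine is single-threaded numpy; training throughput is
  ~10 samples/s on one CPU at the tiny preset, which bounds experiment
  sizes (the defaults above were chosen to fit that envelope).
* mAP on 60 validation samples has seed-to-seed scatter of several points;
  comparisons at this scale should use paired seeds, as the experiment
  scripts do.
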