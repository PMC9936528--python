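"""IoU-family loss correctness: hand-geometry examples, a rasterization
oracle, degeneracy behavior, invariants and gradient checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pacdet.box_losses import (LOSS_NAMES, Box, InvalidBoxError, batched_loss,
                               ciou_loss, diou_loss, giou_loss, iou, iou_loss,
                               loss_gradient, minimum_bounding_rectangle,
                               vdiou_loss, vdiou_penalty)
from conftest import random_box

GT = Box(0, 0, 10, 10)
RP_CONCENTRIC = Box(2, 2, 8, 8)

coords = st.floats(0, 40, allow_nan=False, allow_infinity=False)
sides = st.floats(1, 25, allow_nan=False, allow_infinity=False)


def boxes_strategy():
    return st.tuples(coords, coords, sides, sides).map(
        lambda t: Box(t[0], t[1], t[0] + t[2], t[1] + t[3]))


def rasterized_iou(a: Box, b: Box) -> float:
    """Pixel-counting IoU oracle: exact for integer-coordinate boxes, where
    every unit pixel is either fully inside or fully outside each box."""
    extent = int(np.ceil(max(a.x2, b.x2, a.y2, b.y2))) + 1
    xs = np.arange(extent) + 0.5
    gx, gy = np.meshgrid(xs, xs)
    in_a = (gx > a.x1) & (gx < a.x2) & (gy > a.y1) & (gy < a.y2)
    in_b = (gx > b.x1) & (gx < b.x2) & (gy > b.y1) & (gy < b.y2)
    union = (in_a | in_b).sum()
    return float((in_a & in_b).sum() / union) if union else 0.0


class TestWorkedExamples:
    """Frozen hand-geometry values for each loss."""

    def test_iou_identity_disjoint_and_overlap(self):
        assert iou(GT, GT) == 1.0
        assert iou(GT, Box(20, 20, 30, 30)) == 0.0
        assert iou(GT, RP_CONCENTRIC) == pytest.approx(0.36, abs=1e-12)

    def test_iou_loss_values(self):
        assert iou_loss(GT, GT).value == 0.0
        assert iou_loss(GT, RP_CONCENTRIC).value == pytest.approx(0.64, abs=1e-12)
        assert iou_loss(GT, Box(20, 20, 30, 30)).value == 1.0

    def test_giou_disjoint_value(self):
        # union 2, enclosing box 3 -> 1 + 1/3
        lv = giou_loss(Box(0, 0, 1, 1), Box(2, 0, 3, 1))
        assert lv.value == pytest.approx(1 + 1 / 3, abs=1e-12)

    def test_diou_side_by_side_value(self):
        # center distance 10, MBR diagonal sqrt(500)
        lv = diou_loss(GT, Box(10, 0, 20, 10))
        assert lv.value == pytest.approx(1.2, abs=1e-12)

    def test_vdiou_penalty_concentric(self):
        # four corner distances of sqrt(8) over twice sqrt(200)
        assert vdiou_penalty(GT, RP_CONCENTRIC) == pytest.approx(0.4, abs=1e-12)

    def test_vdiou_loss_total(self):
        assert vdiou_loss(GT, RP_CONCENTRIC).value == pytest.approx(1.04, abs=1e-12)

    def test_vdiou_breaks_equal_iou_concentric_tie(self):
        rp2 = Box(3, 0.5, 7, 9.5)  # same area and center as RP_CONCENTRIC
        assert iou(GT, rp2) == pytest.approx(0.36, abs=1e-12)
        p1 = vdiou_penalty(GT, RP_CONCENTRIC)
        p2 = vdiou_penalty(GT, rp2)
        assert p2 == pytest.approx(4 * np.sqrt(9.25) / (2 * np.sqrt(200)), abs=1e-9)
        assert abs(p1 - p2) > 1e-3

    def test_ciou_equal_aspect_reduces_to_diou(self):
        assert ciou_loss(GT, RP_CONCENTRIC).value == pytest.approx(0.64, abs=1e-12)
        gt, rp = Box(0, 0, 12, 6), Box(5, 4, 13, 8)  # both aspect 2
        assert ciou_loss(gt, rp).value == pytest.approx(diou_loss(gt, rp).value, abs=1e-12)

    def test_mbr_contains_pair_and_diagonal(self):
        m = minimum_bounding_rectangle(GT, Box(10, 0, 20, 10))
        assert (m.box.x1, m.box.y1, m.box.x2, m.box.y2) == (0, 0, 20, 10)
        assert m.diagonal == pytest.approx(np.sqrt(500))


class TestDegeneracies:
    def test_giou_equals_iou_under_containment(self, rng):
        gt = Box(0, 0, 20, 20)
        for _ in range(20):
            x, y = rng.uniform(0, 12, 2)
            rp = Box(x, y, x + 8, y + 8)
            assert giou_loss(gt, rp).penalty_term == 0.0
            assert giou_loss(gt, rp).value == iou_loss(gt, rp).value

    def test_diou_equals_iou_for_concentric(self):
        assert diou_loss(GT, RP_CONCENTRIC).value == iou_loss(GT, RP_CONCENTRIC).value
        assert diou_loss(GT, RP_CONCENTRIC).penalty_term == 0.0

    def test_vdiou_separates_concentric_aspects(self):
        # note mirrored aspects (w/h and h/w) share a penalty by symmetry,
        # so the widths here are chosen pairwise non-mirrored
        rps = [Box(5 - w / 2, 5 - 18 / w, 5 + w / 2, 5 + 18 / w) for w in (4, 5, 6)]
        penalties = [vdiou_penalty(GT, rp) for rp in rps]
        assert len({round(p, 9) for p in penalties}) == len(penalties)


class TestInvariants:
    @given(boxes_strategy(), boxes_strategy())
    @settings(max_examples=200, deadline=None)
    def test_ranges_and_zero_iff_identical(self, gt, rp):
        bounds = {"iou": 1.0, "giou": 2.0, "diou": 2.0, "ciou": 3.0, "vdiou": 3.0}
        maxdiff = max(abs(gt.x1 - rp.x1), abs(gt.y1 - rp.y1),
                      abs(gt.x2 - rp.x2), abs(gt.y2 - rp.y2))
        for name in LOSS_NAMES:
            v = batched_loss(name, [gt], [rp], "none")[0]
            assert -1e-12 <= v <= bounds[name] + 1e-12
            if maxdiff < 1e-9:  # identical to numerical tolerance
                assert abs(v) < 1e-9
            elif name == "vdiou":
                assert v > 0.0

    @given(boxes_strategy(), boxes_strategy())
    @settings(max_examples=100, deadline=None)
    def test_symmetric_quantities(self, a, b):
        assert iou(a, b) == pytest.approx(iou(b, a), abs=1e-12)
        assert vdiou_penalty(a, b) == pytest.approx(vdiou_penalty(b, a), abs=1e-12)
        m_ab = minimum_bounding_rectangle(a, b)
        m_ba = minimum_bounding_rectangle(b, a)
        assert m_ab.diagonal == m_ba.diagonal

    @given(boxes_strategy(), boxes_strategy(),
           st.floats(0.1, 20, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, gt, rp, s):
        for name in LOSS_NAMES:
            v = batched_loss(name, [gt], [rp], "none")[0]
            gs = Box(gt.x1 * s, gt.y1 * s, gt.x2 * s, gt.y2 * s)
            rs = Box(rp.x1 * s, rp.y1 * s, rp.x2 * s, rp.y2 * s)
            vs = batched_loss(name, [gs], [rs], "none")[0]
            assert vs == pytest.approx(v, rel=1e-9, abs=1e-9)

    def test_loss_value_decomposition(self):
        for name in LOSS_NAMES:
            lv = batched_loss(name, [GT], [Box(3, 1, 12, 14)], "mean")
            assert lv.value == pytest.approx(lv.iou_term + lv.penalty_term, abs=1e-12)
            assert 0.0 <= lv.iou_term <= 1.0


def test_iou_matches_rasterization_oracle(rng):
    for _ in range(1000):
        a = random_box(rng, hi=30, min_side=2, max_side=20).round()
        b = random_box(rng, hi=30, min_side=2, max_side=20).round()
        box_a = Box(*a)
        box_b = Box(*b)
        # integer corners make the fine-grid count exact up to discretization
        assert iou(box_a, box_b) == pytest.approx(
            rasterized_iou(box_a, box_b), abs=1e-3)


def test_gradients_match_central_differences(rng):
    for name in LOSS_NAMES:
        for _ in range(100):
            gt = random_box(rng)
            rp = random_box(rng)
            analytic = loss_gradient(name, gt, rp)
            num = np.zeros(4)
            h = 1e-6
            for i in range(4):
                e = np.zeros(4)
                e[i] = h
                f = lambda r: batched_loss(name, gt[None], r[None], "sum").value
                num[i] = (f(rp + e) - f(rp - e)) / (2 * h)
            denom = np.maximum(np.abs(num), 1e-3)
            assert np.max(np.abs(analytic - num) / denom) < 1e-4


def test_vdiou_gradient_nonzero_on_disjoint_pairs():
    g = loss_gradient("vdiou", Box(0, 0, 10, 10), Box(30, 30, 40, 45))
    assert np.all(np.isfinite(g)) and np.linalg.norm(g) > 0
    g_iou = loss_gradient("iou", Box(0, 0, 10, 10), Box(30, 30, 40, 45))
    assert np.allclose(g_iou, 0.0)  # the IoU plateau


class TestBatchedAPI:
    def test_reduction_none_matches_scalar_calls(self, rng):
        gts = [Box(*random_box(rng)) for _ in range(10)]
        rps = [Box(*random_box(rng)) for _ in range(10)]
        for name in LOSS_NAMES:
            per_pair = batched_loss(name, gts, rps, "none")
            scalar = [batched_loss(name, [g], [r], "mean").value
                      for g, r in zip(gts, rps)]
            np.testing.assert_allclose(per_pair, scalar, atol=1e-12)

    def test_mean_of_two_known_pairs(self):
        gts = [GT, GT]
        rps = [RP_CONCENTRIC, Box(10, 0, 20, 10)]
        assert batched_loss("diou", gts, rps, "mean").value == pytest.approx(
            (0.64 + 1.2) / 2, abs=1e-12)
        assert batched_loss("diou", gts, rps, "sum").value == pytest.approx(
            0.64 + 1.2, abs=1e-12)

    def test_identical_pairs_mean_zero(self):
        gts = [GT] * 5
        assert batched_loss("vdiou", gts, gts, "mean").value == 0.0

    def test_errors(self):
        with pytest.raises(ValueError, match="length mismatch"):
            batched_loss("iou", [GT], [GT, GT], "mean")
        with pytest.raises(ValueError, match="unknown loss"):
            batched_loss("smooth_l1", [GT], [GT], "mean")
        with pytest.raises(ValueError, match="reduction"):
            batched_loss("iou", [GT], [GT], "avg")


class TestValidation:
    @pytest.mark.parametrize("bad", [(0, 0, 0, 10), (0, 0, 10, 0),
                                     (5, 5, 2, 8), (0, 0, np.inf, 1)])
    def test_degenerate_boxes_rejected(self, bad):
        with pytest.raises(InvalidBoxError):
            Box(*bad)

    def test_degenerate_arrays_rejected_at_loss_api(self):
        with pytest.raises(InvalidBoxError):
            batched_loss("iou", np.array([[0, 0, 0, 10.0]]),
                         np.array([[0, 0, 5, 5.0]]), "mean")

    def test_float32_batch_close_to_float64_reference(self, rng):
        from pacdet.autodiff import Tensor
        g = np.stack([random_box(rng) for _ in range(50)])
        r = np.stack([random_box(rng) for _ in range(50)])
        for name in LOSS_NAMES:
            ref = batched_loss(name, g, r, "none")
            f32 = batched_loss(name, Tensor(g.astype(np.float32)),
                               Tensor(r.astype(np.float32)), "none").numpy()
            np.testing.assert_allclose(f32, ref, atol=5e-5)
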