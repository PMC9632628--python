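"""SIoU loss: component values, invariances, gradient agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dragoneye import autograd as ag
from dragoneye import siou
from dragoneye.siou import Box


def box_from_corners(x1, y1, x2, y2):
    return Box((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)


finite_box = st.builds(
    Box,
    cx=st.floats(-50, 50), cy=st.floats(-50, 50),
    w=st.floats(0.1, 40), h=st.floats(0.1, 40),
)


class TestIoU:
    def test_identical(self):
        b = Box(1, 2, 3, 4)
        assert siou.iou(b, b) == pytest.approx(1.0)

    def test_corner_overlap_one_seventh(self):
        a = box_from_corners(0, 0, 2, 2)
        b = box_from_corners(1, 1, 3, 3)
        assert siou.iou(a, b) == pytest.approx(1 / 7)

    def test_disjoint(self):
        assert siou.iou(Box(0, 0, 1, 1), Box(10, 10, 1, 1)) == 0.0

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            Box(0, 0, 0, 1)


class TestAngleCost:
    def test_horizontal_alignment_is_zero(self):
        assert siou.angle_cost(Box(0, 0, 1, 1), Box(3, 0, 1, 1)) == pytest.approx(0.0)

    def test_vertical_alignment_is_zero(self):
        assert siou.angle_cost(Box(0, 0, 1, 1), Box(0, 5, 1, 1)) == pytest.approx(0.0, abs=1e-7)

    def test_diagonal_is_maximal(self):
        assert siou.angle_cost(Box(0, 0, 1, 1), Box(2, 2, 1, 1)) == pytest.approx(1.0)

    def test_coincident_centers_defined_zero(self):
        assert siou.angle_cost(Box(0, 0, 1, 1), Box(0, 0, 2, 2)) == 0.0

    @given(st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_arcsin_form(self, x):
        """2 x sqrt(1-x^2) == cos(2 (arcsin x - pi/4)) for x in [0, 1]."""
        direct = 2.0 * x * np.sqrt(1 - x * x)
        trig = np.cos(2 * (np.arcsin(x) - np.pi / 4))
        assert direct == pytest.approx(trig, abs=1e-12)

    @given(finite_box, finite_box)
    @settings(max_examples=300, deadline=None)
    def test_bounded_unit_interval(self, a, b):
        lam = siou.angle_cost(a, b)
        assert -1e-9 <= lam <= 1.0 + 1e-9


class TestDistanceCost:
    def test_coincident_centers(self):
        assert siou.distance_cost(Box(0, 0, 2, 2), Box(0, 0, 4, 4), 4, 4, 0.0) == 0.0

    def test_unit_normalized_offsets(self):
        # rho_x = rho_y = 1 with Lambda = 0 gives 2 - 2 e^-2
        d = siou.distance_cost(Box(0, 0, 1, 1), Box(2, 3, 1, 1), 2.0, 3.0, 0.0)
        assert d == pytest.approx(2 - 2 * np.exp(-2), rel=1e-9)

    def test_monotone_in_offset(self):
        prev = -1.0
        for dx in np.linspace(0, 3, 10):
            d = siou.distance_cost(Box(dx, 0, 1, 1), Box(0, 0, 1, 1), 4.0, 4.0, 0.5)
            assert d > prev
            prev = d

    def test_zero_enclosing_raises(self):
        with pytest.raises(ValueError):
            siou.distance_cost(Box(0, 0, 1, 1), Box(0, 0, 1, 1), 0.0, 1.0, 0.0)

    def test_fixed_angle_limit_is_distance_penalized_iou(self):
        """With the angle term frozen and the shape term dropped, the loss
        degenerates to 1 - IoU + Delta/2 — a plain distance-penalized IoU."""
        a, b = Box(0, 0, 2, 2), Box(1, 0.5, 2, 2)
        comp = siou.siou_components(b, a)
        frozen = siou.distance_cost(a, b, comp.cw1, comp.ch1, 0.0)
        reduced = 1 - siou.iou(a, b) + frozen / 2
        assert reduced >= 1 - siou.iou(a, b)
        assert reduced == pytest.approx(1 - comp.iou + frozen / 2)


class TestShapeCost:
    def test_identical_shapes(self):
        assert siou.shape_cost((3, 4), (3, 4)) == 0.0

    def test_double_width(self):
        got = siou.shape_cost((2, 1), (1, 1), theta=4)
        assert got == pytest.approx((1 - np.exp(-0.5)) ** 4, rel=1e-9)
        assert got == pytest.approx(0.02399, abs=5e-5)

    @given(st.floats(0.1, 20), st.floats(0.1, 20), st.floats(0.1, 20), st.floats(0.1, 20))
    @settings(max_examples=100, deadline=None)
    def test_symmetric(self, w1, h1, w2, h2):
        assert siou.shape_cost((w1, h1), (w2, h2)) == pytest.approx(
            siou.shape_cost((w2, h2), (w1, h1))
        )

    def test_nonpositive_extent_raises(self):
        with pytest.raises(ValueError):
            siou.shape_cost((0, 1), (1, 1))


class TestTotalLoss:
    def test_identical_boxes_zero(self):
        b = Box(3, 4, 5, 6)
        assert siou.siou_loss(b, b) == pytest.approx(0.0)

    @given(finite_box, finite_box)
    @settings(max_examples=200, deadline=None)
    def test_lower_bounded_by_iou_complement(self, a, b):
        assert siou.siou_loss(a, b) >= 1 - siou.iou(a, b) - 1e-9

    @given(finite_box, finite_box, st.floats(-30, 30), st.floats(-30, 30))
    @settings(max_examples=200, deadline=None)
    def test_translation_invariant(self, a, b, tx, ty):
        base = siou.siou_loss(a, b)
        moved = siou.siou_loss(
            Box(a.cx + tx, a.cy + ty, a.w, a.h), Box(b.cx + tx, b.cy + ty, b.w, b.h)
        )
        assert moved == pytest.approx(base, abs=1e-7)

    @given(finite_box, finite_box, st.floats(0.01, 100))
    @settings(max_examples=200, deadline=None)
    def test_scale_invariant(self, a, b, s):
        base = siou.siou_loss(a, b)
        scaled = siou.siou_loss(
            Box(a.cx * s, a.cy * s, a.w * s, a.h * s),
            Box(b.cx * s, b.cy * s, b.w * s, b.h * s),
        )
        assert scaled == pytest.approx(base, rel=1e-5, abs=1e-6)


class TestTensorForm:
    def test_agrees_with_scalar_components(self, rng):
        pred = np.abs(rng.normal(2, 1, size=(20, 4))) + 0.2
        gt = np.abs(rng.normal(2, 1, size=(20, 4))) + 0.2
        got = siou.siou_loss_tensor(ag.Tensor(pred.astype(np.float32)), gt).data
        for i in range(20):
            want = siou.siou_loss(Box(*pred[i]), Box(*gt[i]))
            assert got[i] == pytest.approx(want, rel=2e-3, abs=2e-3)

    def test_gradients_match_central_differences(self, rng, monkeypatch):
        """Backprop gradients vs numeric central differences on 100 random
        box pairs: per-pair relative error below 1e-3 (evaluated at double
        precision so finite-difference noise does not mask a real defect)."""
        monkeypatch.setattr(ag, "DTYPE", np.float64)
        n = 100
        pred0 = np.abs(rng.normal(4, 1.5, size=(n, 4))) + 0.5
        gt = np.abs(rng.normal(4, 1.5, size=(n, 4))) + 0.5
        t = ag.Tensor(pred0, requires_grad=True)
        ag.tsum(siou.siou_loss_tensor(t, gt)).backward()
        ana = t.grad.copy()
        eps = 1e-6
        num = np.zeros_like(ana)
        for j in range(4):
            xp, xm = pred0.copy(), pred0.copy()
            xp[:, j] += eps
            xm[:, j] -= eps
            num[:, j] = (
                siou.siou_loss_tensor(ag.Tensor(xp), gt).data
                - siou.siou_loss_tensor(ag.Tensor(xm), gt).data
            ) / (2 * eps)
        rel = np.linalg.norm(ana - num, axis=1) / np.maximum(
            np.linalg.norm(num, axis=1), 1e-9
        )
        assert rel.max() < 1e-3
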