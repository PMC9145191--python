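"""Bounding-box losses: worked examples, the rasterization oracle, gradients."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thromboseg.box_losses import (
    BoundingBox,
    DegenerateBoxWarning,
    SCIoUConfig,
    batch_loss,
    ciou_components,
    ciou_loss,
    diou_loss,
    enclosing_box,
    giou_loss,
    iou,
    loss_and_grad,
    sciou_loss,
    smooth_l1,
    smooth_l1_box,
)

from conftest import random_box_pair, raster_areas

UNNORM = SCIoUConfig(normalize_coords=False)

# frozen independent-oracle value: (4/pi^2)(atan 1 - atan 2)^2, sympy 20 digits
V_2TO1 = 0.041956461494290571


@st.composite
def boxes(draw, lo=0.0, hi=40.0):
    x1 = draw(st.floats(lo, hi - 1))
    y1 = draw(st.floats(lo, hi - 1))
    w = draw(st.floats(0.5, hi - x1))
    h = draw(st.floats(0.5, hi - y1))
    return BoundingBox(x1, y1, x1 + w, y1 + h)


class TestIoUGeometry:
    @pytest.mark.parametrize(
        "b1, b2, expected",
        [
            ((0, 0, 4, 4), (0, 0, 4, 4), 1.0),
            ((0, 0, 1, 1), (5, 5, 6, 6), 0.0),
            ((0, 0, 2, 2), (1, 1, 3, 3), 1.0 / 7.0),
        ],
    )
    def test_overlap_fraction(self, b1, b2, expected):
        assert iou(BoundingBox(*b1), BoundingBox(*b2)) == pytest.approx(expected, abs=1e-12)

    def test_both_degenerate_warns_and_returns_zero(self):
        with pytest.warns(DegenerateBoxWarning):
            assert iou(BoundingBox(1, 1, 1, 1), BoundingBox(3, 3, 3, 3)) == 0.0

    def test_invalid_box_rejected(self):
        with pytest.raises(ValueError):
            BoundingBox(2, 0, 1, 1)
        with pytest.raises(ValueError):
            BoundingBox(0, 0, float("nan"), 1)

    @pytest.mark.parametrize(
        "b1, b2, expected",
        [
            ((0, 0, 1, 1), (2, 0, 3, 1), (0, 0, 3, 1)),
            ((1, 1, 2, 2), (0, 0, 4, 4), (0, 0, 4, 4)),
            ((0, 0, 2, 3), (0, 0, 2, 3), (0, 0, 2, 3)),
        ],
    )
    def test_enclosing_box(self, b1, b2, expected):
        e = enclosing_box(BoundingBox(*b1), BoundingBox(*b2))
        assert (e.x_min, e.y_min, e.x_max, e.y_max) == expected

    @settings(max_examples=60, derandomize=True)
    @given(b1=boxes(), b2=boxes())
    def test_iou_bounds_and_symmetry(self, b1, b2):
        v = iou(b1, b2)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(iou(b2, b1), abs=1e-14)
        assert iou(b1, b1) == pytest.approx(1.0, abs=1e-12)

    def test_rasterization_oracle_500_pairs(self, rng):
        """Analytic areas match cell counting on random integer boxes."""
        for _ in range(500):
            c1 = np.sort(rng.integers(0, 65, 2))
            r1 = np.sort(rng.integers(0, 65, 2))
            c2 = np.sort(rng.integers(0, 65, 2))
            r2 = np.sort(rng.integers(0, 65, 2))
            b1 = np.array([c1[0], r1[0], c1[1], r1[1]], float)
            b2 = np.array([c2[0], r2[0], c2[1], r2[1]], float)
            inter_o, union_o, enc_o = raster_areas(b1, b2)
            bb1, bb2 = BoundingBox(*b1), BoundingBox(*b2)
            inter = (
                max(0.0, min(b1[2], b2[2]) - max(b1[0], b2[0]))
                * max(0.0, min(b1[3], b2[3]) - max(b1[1], b2[1]))
            )
            union = bb1.area + bb2.area - inter
            assert abs(inter - inter_o) < 1e-9
            assert abs(union - union_o) < 1e-9
            assert abs(enclosing_box(bb1, bb2).area - enc_o) < 1e-9


class TestSmoothL1:
    @pytest.mark.parametrize("x, expected", [(0.0, 0.0), (0.5, 0.125), (2.0, 1.5), (-2.0, 1.5)])
    def test_kernel(self, x, expected):
        assert smooth_l1(x) == pytest.approx(expected)

    def test_continuity_at_one(self):
        assert smooth_l1(1 - 1e-9) == pytest.approx(smooth_l1(1 + 1e-9), abs=1e-8)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            smooth_l1(float("inf"))

    @pytest.mark.parametrize(
        "pred, target, expected",
        [
            ((1, 2, 3, 4), (1, 2, 3, 4), 0.0),
            ((0.5, 0, 2, 3), (0, 0, 2, 3), 0.125),
            ((2, 2, 4, 4), (0, 0, 2, 2), 6.0),
        ],
    )
    def test_box_sum_unnormalized(self, pred, target, expected):
        assert smooth_l1_box(BoundingBox(*pred), BoundingBox(*target), UNNORM) == pytest.approx(
            expected
        )

    def test_normalization_divides_residuals(self):
        cfg = SCIoUConfig(image_width=10.0, image_height=20.0)
        val = smooth_l1_box(BoundingBox(1, 2, 3, 4), BoundingBox(0, 0, 3, 4), cfg)
        assert val == pytest.approx(0.5 * 0.1**2 + 0.5 * 0.1**2)

    def test_missing_image_dims_rejected(self):
        cfg = SCIoUConfig(image_width=None, image_height=None)
        with pytest.raises(ValueError, match="image_width"):
            smooth_l1_box(BoundingBox(0, 0, 1, 1), BoundingBox(0, 0, 2, 2), cfg)


class TestIoUFamilyLosses:
    def test_giou_disjoint_example(self):
        assert giou_loss(BoundingBox(0, 0, 1, 1), BoundingBox(2, 0, 3, 1)) == pytest.approx(
            4.0 / 3.0
        )

    def test_giou_contained_equals_one_minus_iou(self):
        inner, outer = BoundingBox(1, 1, 2, 2), BoundingBox(0, 0, 4, 4)
        assert giou_loss(inner, outer) == pytest.approx(1.0 - iou(inner, outer), abs=1e-12)

    def test_giou_degenerate_enclosing_rejected(self):
        with pytest.raises(ValueError, match="enclosing"):
            giou_loss(BoundingBox(0, 1, 2, 1), BoundingBox(1, 1, 3, 1))

    def test_diou_disjoint_example(self):
        assert diou_loss(BoundingBox(0, 0, 1, 1), BoundingBox(2, 0, 3, 1)) == pytest.approx(1.4)

    def test_diou_concentric_equals_one_minus_iou(self):
        a, b = BoundingBox(1, 1, 3, 3), BoundingBox(0, 0, 4, 4)
        assert diou_loss(a, b) == pytest.approx(1.0 - iou(a, b), abs=1e-12)

    def test_diou_point_boxes_rejected(self):
        with pytest.raises(ValueError, match="c\\^2"):
            diou_loss(BoundingBox(1, 1, 1, 1), BoundingBox(1, 1, 1, 1))

    def test_ciou_components_aspect_mismatch(self):
        comp = ciou_components(BoundingBox(0, 0, 2, 1), BoundingBox(0, 0, 1, 1))
        assert comp.v == pytest.approx(V_2TO1, rel=1e-12)
        assert comp.alpha == pytest.approx(comp.v / ((1 - comp.iou) + comp.v))
        assert 0.0 <= comp.v <= 1.0
        assert comp.rho_sq <= comp.c_sq

    def test_ciou_components_identity(self):
        comp = ciou_components(BoundingBox(0, 0, 2, 2), BoundingBox(0, 0, 2, 2))
        assert comp.iou == 1.0 and comp.v == 0.0 and comp.alpha == 0.0

    def test_ciou_composes_diou_and_aspect_term(self):
        a, b = BoundingBox(0, 0, 2, 1), BoundingBox(0, 0, 1, 1)
        comp = ciou_components(a, b)
        assert ciou_loss(a, b) == pytest.approx(diou_loss(a, b) + comp.alpha * comp.v, abs=1e-12)

    def test_ciou_matching_aspect_reduces_to_diou(self):
        a, b = BoundingBox(0, 0, 2, 2), BoundingBox(3, 3, 5, 5)
        assert ciou_loss(a, b) == pytest.approx(diou_loss(a, b), abs=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(b1=boxes(), b2=boxes())
    def test_loss_ordering(self, b1, b2):
        one_minus = 1.0 - iou(b1, b2)
        assert giou_loss(b1, b2) >= one_minus - 1e-12
        d = diou_loss(b1, b2)
        assert d >= one_minus - 1e-12
        assert ciou_loss(b1, b2) >= d - 1e-12

    @settings(max_examples=40, derandomize=True)
    @given(b=boxes())
    def test_zero_iff_coincident(self, b):
        assert giou_loss(b, b) == pytest.approx(0.0, abs=1e-12)
        assert diou_loss(b, b) == pytest.approx(0.0, abs=1e-12)
        assert ciou_loss(b, b) == pytest.approx(0.0, abs=1e-12)


class TestSCIoU:
    def test_delta_boundaries(self, rng):
        for _ in range(20):
            p, t = random_box_pair(rng)
            bp, bt = BoundingBox(*p), BoundingBox(*t)
            assert sciou_loss(bp, bt, SCIoUConfig(delta=1.0, normalize_coords=False)) == (
                pytest.approx(smooth_l1_box(bp, bt, UNNORM), abs=1e-12)
            )
            assert sciou_loss(bp, bt, SCIoUConfig(delta=0.0, normalize_coords=False)) == (
                pytest.approx(ciou_loss(bp, bt), abs=1e-12)
            )

    def test_linear_in_delta(self, rng):
        p, t = random_box_pair(rng)
        bp, bt = BoundingBox(*p), BoundingBox(*t)
        l_s = smooth_l1_box(bp, bt, UNNORM)
        l_c = ciou_loss(bp, bt)
        for d in np.linspace(0, 1, 11):
            cfg = SCIoUConfig(delta=float(d), normalize_coords=False)
            assert sciou_loss(bp, bt, cfg) == pytest.approx(d * l_s + (1 - d) * l_c, abs=1e-12)

    def test_default_delta(self):
        assert SCIoUConfig().delta == 0.2

    def test_delta_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SCIoUConfig(delta=1.5)

    def test_zero_iff_identical(self):
        b = BoundingBox(3, 4, 10, 9)
        assert sciou_loss(b, b) == 0.0
        assert sciou_loss(BoundingBox(3, 4, 10, 9.5), b) > 0.0


class TestGradients:
    @pytest.mark.parametrize("name", ["smooth_l1", "iou", "giou", "diou", "ciou", "sciou"])
    def test_matches_central_finite_differences(self, name, rng):
        cfg = SCIoUConfig(image_width=64.0, image_height=64.0)
        h = 1e-6
        for _ in range(30):
            p, t = random_box_pair(rng)
            _, g = loss_and_grad(name, p, t, cfg)
            for i in range(4):
                pp, pm = p.copy(), p.copy()
                pp[i] += h
                pm[i] -= h
                fd = (
                    loss_and_grad(name, pp, t, cfg)[0] - loss_and_grad(name, pm, t, cfg)[0]
                ) / (2 * h)
                assert g[i] == pytest.approx(fd, abs=5e-5)

    def test_disjoint_iou_gradient_vanishes_but_penalized_losses_do_not(self):
        p = np.array([0.0, 0.0, 1.0, 1.0])
        t = np.array([3.0, 3.0, 5.0, 5.0])
        _, g_iou = loss_and_grad("iou", p, t)
        assert np.all(g_iou == 0.0)
        for name in ("giou", "diou", "ciou", "sciou"):
            _, g = loss_and_grad(name, p, t, SCIoUConfig(image_width=8.0, image_height=8.0))
            assert np.linalg.norm(g) > 0.0

    def test_unknown_loss_rejected(self):
        with pytest.raises(KeyError, match="unknown loss"):
            loss_and_grad("dice", np.zeros(4), np.ones(4))


class TestBatchReducer:
    def test_mean_and_sum(self, rng):
        preds = np.stack([random_box_pair(rng)[0] for _ in range(5)])
        targets = np.stack([random_box_pair(rng)[0] for _ in range(5)])
        s = batch_loss("ciou", preds, targets, reduction="sum")
        m = batch_loss("ciou", preds, targets, reduction="mean")
        assert s == pytest.approx(5 * m)
        assert batch_loss("ciou", np.empty((0, 4)), np.empty((0, 4))) == 0.0

    def test_shape_and_reduction_validation(self):
        with pytest.raises(ValueError):
            batch_loss("ciou", np.zeros((2, 4)), np.zeros((3, 4)))
        with pytest.raises(ValueError):
            batch_loss("ciou", np.zeros((2, 4)), np.zeros((2, 4)), reduction="max")
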