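"""Loss components vs scalar-loop oracles on toy prior grids."""

import math

import numpy as np
import pytest

from earcount.losses import (LossBreakdown, assemble_masks,
                             classification_loss, density_branch_loss,
                             detection_loss, mask_loss, match_priors,
                             total_loss)
from earcount.nn import Tensor


class Outputs:
    """Hand-built HeadOutputs stand-in for toy loss tests."""

    def __init__(self, obj=None, cls=None, box=None, protos=None, coefs=None,
                 density=None):
        self.objectness_logits = Tensor(obj) if obj is not None else None
        self.class_logits = Tensor(cls) if cls is not None else None
        self.box_offsets = Tensor(box) if box is not None else None
        self.prototypes = Tensor(protos) if protos is not None else None
        self.mask_coefficients = Tensor(coefs) if coefs is not None else None
        self.density = ([Tensor(d) for d in density]
                        if density is not None else None)


def toy_priors():
    # 8 priors on a 2x2x2 toy grid
    out = []
    for cx in (0.25, 0.75):
        for cy in (0.25, 0.75):
            for s in (0.3, 0.5):
                out.append((cx, cy, s, s))
    return np.array(out)


class TestMatchPriors:
    def test_exact_match_positive(self):
        priors = toy_priors()
        gt = priors[2:3].copy()
        a = match_priors(priors, gt)
        assert a[2] == 0

    def test_no_gt_all_negative(self):
        a = match_priors(toy_priors(), np.zeros((0, 4)))
        assert np.all(a == -1)

    def test_best_prior_guarantee_below_threshold(self):
        # gt far smaller than any prior: max IoU < 0.4, still one positive
        priors = toy_priors()
        gt = np.array([[0.25, 0.25, 0.05, 0.05]])
        from earcount.losses import box_iou_cxcywh
        assert box_iou_cxcywh(priors, gt).max() < 0.4
        a = match_priors(priors, gt)
        assert (a >= 0).sum() == 1

    def test_band_is_ignored(self):
        priors = np.array([[0.5, 0.5, 0.4, 0.4], [0.5, 0.5, 0.28, 0.28],
                           [0.9, 0.9, 0.1, 0.1]])
        gt = np.array([[0.5, 0.5, 0.4, 0.4]])
        a = match_priors(priors, gt)
        # prior 1 IoU = (0.28/0.4)^2 = 0.49 -> ignored band
        assert a[0] == 0 and a[1] == -2 and a[2] == -1


class TestDetectionLoss:
    def test_perfect_prediction_near_zero(self):
        priors = toy_priors()
        gt = priors[5:6].copy()
        a = match_priors(priors, gt)
        obj = np.where(a >= 0, 30.0, -30.0)
        from earcount.model import encode_boxes
        box = np.zeros((8, 4))
        box[a >= 0] = encode_boxes(gt[a[a >= 0]], priors[a >= 0])
        l_obj, l_box = detection_loss(Outputs(obj=obj, box=box), a, gt, priors)
        assert float(l_obj.data) == pytest.approx(0.0, abs=1e-8)
        assert float(l_box.data) == pytest.approx(0.0, abs=1e-6)

    def test_smooth_l1_half_offset(self):
        priors = toy_priors()
        gt = priors[0:1].copy()
        a = np.full(8, -1)
        a[0] = 0
        from earcount.model import encode_boxes
        box = np.zeros((8, 4))
        box[0] = encode_boxes(gt, priors[0:1])[0]
        box[0, 0] += 0.5  # one coordinate off by 0.5 -> 0.5 * 0.5^2
        obj = np.where(a >= 0, 30.0, -30.0)
        _, l_box = detection_loss(Outputs(obj=obj, box=box), a, gt, priors)
        assert float(l_box.data) == pytest.approx(0.125, abs=1e-9)

    def test_uniform_objectness_ln2(self):
        priors = toy_priors()
        gt = priors[3:4].copy()
        a = match_priors(priors, gt)
        l_obj, _ = detection_loss(
            Outputs(obj=np.zeros(8), box=np.zeros((8, 4))), a, gt, priors)
        assert float(l_obj.data) == pytest.approx(math.log(2), abs=1e-12)

    def test_no_positives_box_zero(self):
        priors = toy_priors()
        a = np.full(8, -1)
        l_obj, l_box = detection_loss(
            Outputs(obj=np.zeros(8), box=np.zeros((8, 4))), a,
            np.zeros((0, 4)), priors)
        assert float(l_box.data) == 0.0
        assert float(l_obj.data) > 0

    def test_matches_scalar_loop_oracle(self, rng):
        priors = toy_priors()
        gt = np.array([[0.25, 0.25, 0.3, 0.3], [0.75, 0.75, 0.45, 0.45]])
        a = match_priors(priors, gt)
        obj = rng.normal(size=8)
        box = rng.normal(size=(8, 4))
        l_obj, l_box = detection_loss(Outputs(obj=obj, box=box), a, gt, priors)
        # oracle: BCE over positives + 3:1 hardest negatives
        pos = [i for i in range(8) if a[i] >= 0]
        neg = [i for i in range(8) if a[i] == -1]
        neg = sorted(neg, key=lambda i: -obj[i])[: 3 * len(pos)]
        acc = 0.0
        for i in pos:
            acc += math.log(1 + math.exp(-obj[i]))
        for i in neg:
            acc += math.log(1 + math.exp(obj[i]))
        assert float(l_obj.data) == pytest.approx(
            acc / (len(pos) + len(neg)), abs=1e-8)
        from earcount.model import encode_boxes
        acc_box = 0.0
        for i in pos:
            t = encode_boxes(gt[a[i]:a[i] + 1], priors[i:i + 1])[0]
            for d in box[i] - t:
                acc_box += 0.5 * d * d if abs(d) < 1 else abs(d) - 0.5
        assert float(l_box.data) == pytest.approx(
            acc_box / len(pos), abs=1e-8)


class TestClassificationLoss:
    def test_one_hot_correct_near_zero(self):
        a = np.array([0, -1, -1, 0])
        cls = np.array([[0.0, 30.0], [30.0, 0.0], [30.0, 0.0], [0.0, 30.0]])
        l = classification_loss(Outputs(cls=cls), a)
        assert float(l.data) == pytest.approx(0.0, abs=1e-8)

    def test_uniform_scores_ln2(self):
        a = np.array([0, -1])
        cls = np.zeros((2, 2))
        l = classification_loss(Outputs(cls=cls), a)
        assert float(l.data) == pytest.approx(math.log(2), abs=1e-12)

    def test_permutation_invariance(self, rng):
        a = np.array([0, -1, 1, -1])
        cls = rng.normal(size=(4, 2))
        l1 = classification_loss(Outputs(cls=cls), a)
        perm = np.array([2, 0, 3, 1])
        l2 = classification_loss(Outputs(cls=cls[perm]), a[perm])
        assert float(l1.data) == pytest.approx(float(l2.data), abs=1e-12)

    def test_matches_scalar_oracle(self, rng):
        a = np.array([0, -1, -2, 1, -1])
        cls = rng.normal(size=(5, 2))
        l = classification_loss(Outputs(cls=cls), a)
        counted = [i for i in range(5) if a[i] >= -1]
        acc = 0.0
        for i in counted:
            label = 1 if a[i] >= 0 else 0
            z = cls[i] - cls[i].max()
            log_probs = z - math.log(np.exp(z).sum())
            acc -= log_probs[label]
        assert float(l.data) == pytest.approx(acc / len(counted), abs=1e-8)


class TestAssembleMasks:
    def test_zero_coefficients_half_inside_bbox(self):
        protos = np.random.default_rng(0).normal(size=(3, 8, 8)) * 0.0
        out = assemble_masks(protos, np.zeros(3), bbox=(0.25, 0.25, 0.5, 0.5))
        assert np.all(out.data[2:6, 2:6] == 0.5)
        assert out.data[0, 0] == 0.0

    def test_saturating_prototype(self):
        protos = np.full((1, 4, 4), 50.0)
        out = assemble_masks(protos, np.ones(1))
        assert np.all(out.data > 0.999)

    @pytest.mark.parametrize("k", [1, 3, 8])
    def test_matches_per_pixel_oracle(self, k, rng):
        protos = rng.normal(size=(k, 6, 5))
        coefs = rng.normal(size=k)
        out = assemble_masks(protos, coefs).data
        for i in range(6):
            for j in range(5):
                lin = sum(coefs[t] * protos[t, i, j] for t in range(k))
                assert out[i, j] == pytest.approx(
                    1 / (1 + math.exp(-lin)), abs=1e-6)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            assemble_masks(np.zeros((2, 4, 4)), np.zeros(3))

    def test_sign_flip_invariance_of_product(self, rng):
        protos = rng.normal(size=(1, 5, 5))
        coefs = np.array([1.3])
        a = assemble_masks(protos, coefs).data
        b = assemble_masks(-protos, -coefs).data
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestMaskLoss:
    def test_perfect_mask_near_zero(self):
        protos = np.zeros((1, 8, 8))
        gt = np.zeros((1, 8, 8))
        gt[0, 2:6, 2:6] = 1.0
        protos[0] = np.where(gt[0] > 0, 40.0, -40.0)
        a = np.array([0, -1])
        out = Outputs(protos=protos, coefs=np.array([[1.0], [0.0]]))
        boxes = np.array([[0.5, 0.5, 0.5, 0.5]])
        l = mask_loss(out, a, gt, boxes)
        assert float(l.data) == pytest.approx(0.0, abs=1e-8)

    def test_half_probability_ln2(self):
        protos = np.zeros((1, 8, 8))
        gt = np.ones((1, 8, 8))
        a = np.array([0])
        out = Outputs(protos=protos, coefs=np.zeros((1, 1)))
        boxes = np.array([[0.5, 0.5, 1.0, 1.0]])
        l = mask_loss(out, a, gt, boxes)
        assert float(l.data) == pytest.approx(math.log(2), abs=1e-12)

    def test_no_positives_zero(self):
        out = Outputs(protos=np.zeros((1, 4, 4)), coefs=np.zeros((2, 1)))
        l = mask_loss(out, np.array([-1, -1]), np.zeros((0, 4, 4)),
                      np.zeros((0, 4)))
        assert float(l.data) == 0.0


class TestDensityBranchLoss:
    def test_exact_targets_zero(self, rng):
        maps = [rng.uniform(0, 1, (8, 8)), rng.uniform(0, 1, (4, 4))]
        out = Outputs(density=maps)
        assert float(density_branch_loss(out, maps).data) == 0.0

    def test_two_levels_mean(self):
        pred = [np.zeros((10, 10)), np.zeros((10, 10))]
        t1 = np.zeros((10, 10)); t1.flat[:2] = 1.0   # mse 2/100
        t2 = np.zeros((10, 10)); t2.flat[:4] = 1.0   # mse 4/100
        out = Outputs(density=pred)
        l = density_branch_loss(out, [t1, t2])
        assert float(l.data) == pytest.approx(0.03, abs=1e-12)

    def test_level_count_mismatch(self):
        out = Outputs(density=[np.zeros((4, 4))])
        with pytest.raises(ValueError, match="levels"):
            density_branch_loss(out, [np.zeros((4, 4)), np.zeros((2, 2))])


class TestTotalLoss:
    def test_weighted_arithmetic(self):
        b = total_loss(1.0, 0.5, 0.5, 1.0, 1.0, w_density=1.0)
        assert b.total == pytest.approx(9.625, abs=1e-12)

    def test_all_zero(self):
        assert total_loss(0, 0, 0, 0, 0).total == 0.0

    def test_zero_density_weight_recovers_plain_objective(self):
        b = total_loss(0.3, 0.2, 0.1, 0.4, 5.0, w_density=0.0)
        assert b.total == pytest.approx(0.3 + 1.5 * 0.3 + 6.125 * 0.4, abs=1e-12)

    def test_identity_holds(self, rng):
        vals = rng.uniform(0, 2, 5)
        b = total_loss(*vals, w_density=0.7)
        expected = (1.0 * vals[0] + 1.5 * (vals[1] + vals[2])
                    + 6.125 * vals[3] + 0.7 * vals[4])
        assert b.total == pytest.approx(expected, abs=1e-10)

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            LossBreakdown(l_cla=-0.1, l_obj=0, l_box=0, l_seg=0, l_density=0)
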