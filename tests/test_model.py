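"""Model assembly, determinism, ablation toggles, NMS, training mechanics."""

from dataclasses import replace

import numpy as np
import pytest

from earcount import (AttentionSettings, Detection, ModelConfig, SceneConfig,
                      build_model, count_instances, generate_scene, greedy_nms,
                      predict)
from earcount.model import decode_boxes, encode_boxes, make_priors
from earcount.nn import Tensor
from earcount.train import (TrainConfig, load_checkpoint, prepare_sample,
                            save_checkpoint, train)


def small_config(**kw):
    return ModelConfig(input_size=(64, 64), **kw)


@pytest.fixture(scope="module")
def small_model():
    return build_model(small_config(), seed=0)


@pytest.fixture(scope="module")
def tiny_samples():
    cfg = small_config()
    samples = []
    for i in range(4):
        scene = generate_scene(SceneConfig(image_size=(64, 64),
                                           count_range=(3, 6), seed=50 + i))
        samples.append(prepare_sample(scene.image, list(scene.annotations), cfg))
    return samples


class TestPriorsAndBoxes:
    def test_prior_count(self):
        cfg = small_config()
        priors = make_priors(cfg)
        expected = sum((64 // s) ** 2 * 3 for s in cfg.fpn_levels)
        assert priors.shape == (expected, 4)
        assert np.all(priors >= 0) and np.all(priors <= 1)

    def test_priors_position_major_layout(self):
        # the head emits (position, aspect) blocks; priors must match
        cfg = small_config()
        priors = make_priors(cfg)
        a = cfg.priors_per_position
        first_pos = priors[:a]
        assert np.all(first_pos[:, 0] == first_pos[0, 0])
        assert np.all(first_pos[:, 1] == first_pos[0, 1])
        assert len({(w, h) for w, h in first_pos[:, 2:].round(6).tolist()}) == a
        # next block moves one grid step at the finest stride
        second_pos = priors[a:2 * a]
        step = cfg.fpn_levels[0] / cfg.input_size[1]
        assert second_pos[0, 0] - first_pos[0, 0] == pytest.approx(step)

    def test_encode_decode_round_trip(self, rng):
        priors = make_priors(small_config())[::7]
        gt = np.stack([
            rng.uniform(0.2, 0.8, len(priors)),
            rng.uniform(0.2, 0.8, len(priors)),
            rng.uniform(0.05, 0.3, len(priors)),
            rng.uniform(0.05, 0.3, len(priors)),
        ], axis=1)
        np.testing.assert_allclose(
            decode_boxes(encode_boxes(gt, priors), priors), gt, atol=1e-12)


class TestBuildModel:
    def test_forward_shapes(self, small_model):
        out = small_model(Tensor(np.zeros((1, 3, 64, 64))))
        p = len(small_model.priors)
        assert out.objectness_logits.shape == (1, p)
        assert out.class_logits.shape == (1, p, 2)
        assert out.box_offsets.shape == (1, p, 4)
        assert out.mask_coefficients.shape == (1, p, 8)
        assert out.prototypes.shape[1] == 8
        assert len(out.density) == 3
        for d, s in zip(out.density, (4, 8, 16)):
            assert d.shape[-2:] == (64 // s, 64 // s)
            assert np.all(d.data >= 0)  # softplus output

    def test_seeded_initialization_bitwise_identical(self):
        a = build_model(small_config(), seed=3)
        b = build_model(small_config(), seed=3)
        for (ka, pa), (kb, pb) in zip(sorted(a.state_dict().items()),
                                      sorted(b.state_dict().items())):
            assert ka == kb
            np.testing.assert_array_equal(pa, pb)

    def test_disabling_density_branch(self):
        model = build_model(small_config(density_branch=False), seed=0)
        out = model(Tensor(np.zeros((1, 3, 64, 64))))
        assert out.density is None

    def test_ablation_parameter_sets(self):
        base = build_model(small_config(), seed=0)
        no_att = build_model(small_config(
            attention=AttentionSettings(enabled=False)), seed=0)
        no_den = build_model(small_config(density_branch=False), seed=0)
        classic = build_model(small_config(
            attention=AttentionSettings(gem_pooling=False)), seed=0)
        base_keys = set(base.parameters())
        assert {k for k in base_keys if k.startswith("cbam")} \
            - set(no_att.parameters())
        assert {k for k in base_keys if k.startswith("density_heads")} \
            - set(no_den.parameters())
        # classic CBAM keeps the block weights but freezes p at 1
        assert any(k.endswith("p_channel") for k in base.parameters())
        assert not any(k.endswith("p_channel") for k in classic.parameters())
        assert float(classic.cbam[0].p_channel.data) == 1.0

    def test_gradients_reach_all_branches(self, small_model, tiny_samples):
        model = build_model(small_config(), seed=1)
        sample = tiny_samples[0]
        hist = train(model, [sample], TrainConfig(iterations=1, batch_size=1,
                                                  learning_rate=0.0, seed=0))
        assert len(hist) == 1
        grads = {k: p.grad for k, p in model.parameters().items()}
        assert all(g is not None and np.all(np.isfinite(g))
                   for g in grads.values())
        assert np.abs(grads["backbone.stem.conv.weight"]).sum() > 0
        assert any(np.abs(grads[k]).sum() > 0 for k in grads
                   if k.startswith("density_heads"))
        assert any(k.endswith("p_channel") and grads[k] is not None
                   for k in grads)


class TestNms:
    def test_keeps_higher_scoring_duplicate(self):
        boxes = np.array([[0.5, 0.5, 0.2, 0.2], [0.5, 0.5, 0.2, 0.2]])
        keep = greedy_nms(boxes, np.array([0.4, 0.9]), 0.5)
        assert keep == [1]

    def test_disjoint_boxes_all_kept(self):
        boxes = np.array([[0.2, 0.2, 0.1, 0.1], [0.8, 0.8, 0.1, 0.1]])
        keep = greedy_nms(boxes, np.array([0.9, 0.8]), 0.5)
        assert sorted(keep) == [0, 1]

    def test_matches_brute_force_oracle(self, rng):
        boxes = np.stack([
            rng.uniform(0.3, 0.7, 20), rng.uniform(0.3, 0.7, 20),
            rng.uniform(0.1, 0.3, 20), rng.uniform(0.1, 0.3, 20),
        ], axis=1)
        scores = rng.uniform(0, 1, 20)
        keep = greedy_nms(boxes, scores, 0.5)
        # oracle: explicit loop
        from earcount.losses import box_iou_cxcywh
        order = list(np.argsort(-scores))
        expected = []
        suppressed = set()
        for i in order:
            if i in suppressed:
                continue
            expected.append(i)
            for j in order:
                if j not in suppressed and j != i and \
                        box_iou_cxcywh(boxes[i], boxes[j])[0, 0] >= 0.5:
                    suppressed.add(j)
        assert keep == expected


class TestPredict:
    def test_untrained_contract(self, small_model):
        image = np.random.default_rng(0).uniform(0, 1, (64, 64, 3))
        detections, density = predict(small_model, image, score_threshold=0.3)
        assert isinstance(detections, list)
        assert density is not None and density.shape == (16, 16)
        for d in detections:
            assert 0 <= d.score <= 1
            assert d.mask.shape == (64, 64)

    def test_alpha_zero_is_plain_score(self, small_model):
        image = np.random.default_rng(1).uniform(0, 1, (64, 64, 3))
        d0, _ = predict(small_model, image, score_threshold=0.0,
                        density_alpha=0.0)
        d1, _ = predict(small_model, image, score_threshold=0.0,
                        density_alpha=1.0)
        # same candidate set, possibly different scores
        assert len(d0) > 0
        assert all(a.score <= 1 for a in d0 + d1)

    def test_count_instances_thresholding(self):
        dets = [Detection(bbox=(0, 0, 5, 5), score=s) for s in (0.9, 0.4)]
        assert count_instances([], 0.5) == 0
        assert count_instances(dets, 0.0) == 2
        assert count_instances(dets, 0.5) == 1


class TestTraining:
    def test_zero_lr_keeps_parameters(self, tiny_samples):
        model = build_model(small_config(), seed=2)
        before = model.state_dict()
        train(model, tiny_samples, TrainConfig(iterations=1, batch_size=2,
                                               learning_rate=0.0, seed=0))
        after = model.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_loss_history_deterministic(self, tiny_samples):
        h1 = train(build_model(small_config(), seed=4), tiny_samples,
                   TrainConfig(iterations=3, batch_size=2, seed=9,
                               learning_rate=0.01))
        h2 = train(build_model(small_config(), seed=4), tiny_samples,
                   TrainConfig(iterations=3, batch_size=2, seed=9,
                               learning_rate=0.01))
        assert [b.as_dict() for b in h1] == [b.as_dict() for b in h2]

    def test_loss_decomposition_identity_every_step(self, tiny_samples):
        model = build_model(small_config(), seed=5)
        hist = train(model, tiny_samples,
                     TrainConfig(iterations=3, batch_size=2, seed=1,
                                 learning_rate=0.01, w_density=0.7))
        for b in hist:
            expected = (b.w_cla * b.l_cla + b.w_det * (b.l_obj + b.l_box)
                        + b.w_seg * b.l_seg + b.w_density * b.l_density)
            assert abs(b.total - expected) <= 1e-10
            assert min(b.l_cla, b.l_obj, b.l_box, b.l_seg, b.l_density) >= 0

    def test_checkpoint_round_trip(self, tiny_samples, tmp_path):
        model = build_model(small_config(), seed=6)
        train(model, tiny_samples, TrainConfig(iterations=1, batch_size=2,
                                               learning_rate=0.01, seed=0))
        path = tmp_path / "model.npz"
        save_checkpoint(model, str(path), seed=6)
        restored = load_checkpoint(str(path))
        assert restored.config == model.config
        for k, v in model.state_dict().items():
            np.testing.assert_array_equal(restored.state_dict()[k], v)
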