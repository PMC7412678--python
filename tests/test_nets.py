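"""Architectures, receptive fields, prediction assembly and training mechanics."""

import numpy as np
import pytest

from ceseg.nets import (
    NetConfig,
    TrainConfig,
    build_swnet,
    build_unet,
    load_model,
    predict_swnet,
    predict_unet,
    receptive_field,
    receptive_field_probe,
    sample_patches,
    save_model,
    train,
)
from ceseg.nets import engine as eng


class TestReceptiveField:
    @pytest.mark.parametrize(
        "kernel,steps,convs,expected",
        [
            (3, 4, 2, 61),
            (4, 4, 2, 91),
            (5, 4, 2, 121),
            (4, 3, 2, 43),
            (4, 5, 2, 187),
            (3, 5, 2, 125),
            (5, 4, (2, 2, 2, 1), 89),  # last contraction conv removed
            (1, 4, 2, 1),              # pointwise network
        ],
    )
    def test_known_values(self, kernel, steps, convs, expected):
        assert receptive_field(kernel, steps, convs) == expected

    def test_netconfig_interface(self):
        assert receptive_field(NetConfig.unet()) == 91
        assert receptive_field(NetConfig.swnet()) == 61

    @pytest.mark.parametrize(
        "cfg",
        [
            NetConfig.unet(kernel=3, steps=2, base_channels=2, dropout=0.0),
            NetConfig.unet(kernel=4, steps=2, base_channels=2, dropout=0.0),
            NetConfig.unet(kernel=5, steps=2, convs_per_step=(2, 1), base_channels=2, dropout=0.0),
            NetConfig.unet(kernel=3, steps=3, convs_per_step=1, base_channels=2, dropout=0.0),
        ],
    )
    def test_gradient_probe_agrees_with_calculator(self, cfg):
        assert receptive_field_probe(cfg) == receptive_field(cfg)


class TestUNet:
    CFG = NetConfig.unet(kernel=3, steps=2, base_channels=4)

    def test_output_shape_and_softmax_conservation(self, rng):
        model = build_unet(self.CFG, seed=0)
        x = rng.random((1, 16, 24, 1))
        logits = model.forward(x)
        assert logits.shape == (1, 16, 24, 2)
        probs = eng.softmax(logits)
        assert np.allclose(probs.sum(axis=-1), 1.0)

    def test_parameter_count_monotone_in_width(self):
        n_small = sum(p.value.size for p in build_unet(self.CFG).parameters())
        wide = NetConfig.unet(kernel=3, steps=2, base_channels=8)
        n_big = sum(p.value.size for p in build_unet(wide).parameters())
        assert n_big > n_small

    def test_indivisible_input_rejected(self, rng):
        model = build_unet(self.CFG, seed=0)
        with pytest.raises(ValueError):
            model.forward(rng.random((1, 18, 24, 1)))

    def test_inference_deterministic_despite_dropout(self, rng):
        model = build_unet(self.CFG, seed=0)
        img = rng.random((16, 16))
        assert np.array_equal(predict_unet(model, img), predict_unet(model, img))

    def test_save_load_roundtrip(self, rng, tmp_path):
        model = build_unet(self.CFG, seed=3)
        img = rng.random((16, 16))
        ref = predict_unet(model, img)
        save_model(model, tmp_path / "m.npz")
        clone = load_model(tmp_path / "m.npz")
        assert np.array_equal(predict_unet(clone, img), ref)


class TestSWNet:
    CFG = NetConfig.swnet(steps=2, base_channels=4, patch_size=16)

    def test_single_patch_probabilities(self, rng):
        model = build_swnet(self.CFG, seed=0)
        out = eng.softmax(model.forward(rng.random((1, 16, 16, 1))))
        assert out.shape == (1, 2)
        assert out.sum() == pytest.approx(1.0)

    def test_batch_output_shape(self, rng):
        model = build_swnet(self.CFG, seed=0)
        assert model.forward(rng.random((8, 16, 16, 1))).shape == (8, 2)

    def test_patch_size_mismatch_rejected(self, rng):
        model = build_swnet(self.CFG, seed=0)
        with pytest.raises(ValueError):
            model.forward(rng.random((1, 12, 12, 1)))

    def test_dropout_defaults(self):
        assert NetConfig.swnet().dropout == 0.0   # diverged with dropout in training
        assert NetConfig.unet().dropout == 0.5
        assert NetConfig.swnet(dropout=0.5).dropout == 0.5  # allowed, off by default

    def test_prediction_assembly_matches_per_pixel_oracle(self, rng):
        model = build_swnet(self.CFG, seed=5)
        img = rng.random((12, 12))
        padded = np.pad(img, 8, mode="reflect")
        oracle = np.zeros((12, 12))
        for y in range(12):
            for x in range(12):
                patch = padded[y : y + 16, x : x + 16][None, ..., None]
                oracle[y, x] = eng.softmax(model.forward(patch))[0, 1]
        assert np.allclose(predict_swnet(model, img, batch=37), oracle)


class TestSamplePatches:
    def test_exact_class_balance_and_center_classes(self, small_mosaic, rng):
        from ceseg.labels import binarize_labels, make_probabilistic_labels

        _, gold = small_mosaic
        label = make_probabilistic_labels(gold)
        img = rng.random(label.shape)
        patches, p_c, cls, centers = sample_patches(img, label, 128, patch=32, rng=rng)
        assert patches.shape == (128, 32, 32, 1)
        assert (cls == 1).sum() == 64 and (cls == 0).sum() == 64
        b = binarize_labels(label)
        for (y, x), c in zip(centers, cls):
            assert b[y, x] == c

    def test_corner_patch_uses_mirrored_content(self, rng):
        img = rng.random((10, 10))
        label = np.zeros((10, 10))
        label[0, 0] = 1.0  # force an edge-class centre at the corner
        patches, _, cls, centers = sample_patches(
            img, label, 2, patch=8, rng=np.random.default_rng(0)
        )
        padded = np.pad(img, 4, mode="reflect")
        for patch, (y, x) in zip(patches, centers):
            assert np.array_equal(patch[..., 0], padded[y : y + 8, x : x + 8])

    def test_odd_count_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_patches(rng.random((8, 8)), rng.random((8, 8)), 7, patch=4, rng=rng)


class TestTraining:
    def test_learning_rate_schedule_closed_form(self, rng):
        img = rng.random((16, 16))
        label = np.zeros((16, 16))
        label[8, :] = 1.0
        model = build_unet(NetConfig.unet(kernel=3, steps=2, base_channels=2), seed=0)
        hist = train(model, [(img, label)], TrainConfig(iterations=20, batch_images=1, seed=0))
        lr = 1e-3
        for i in range(1, 21):
            lr = lr / (1.0 + 1e-3 * i)
            assert hist["lr"].iloc[i - 1] == pytest.approx(lr, rel=1e-14)
        assert (np.diff(hist["lr"]) < 0).all()

    def test_swnet_batches_are_class_balanced(self, small_mosaic, rng):
        # the balance contract is enforced by sample_patches inside train
        from ceseg.labels import make_probabilistic_labels

        _, gold = small_mosaic
        label = make_probabilistic_labels(gold)
        img = rng.random(label.shape)
        _, _, cls, _ = sample_patches(img, label, 128, patch=64, rng=rng)
        assert (cls == 1).sum() == (cls == 0).sum() == 64

    def test_empty_dataset_rejected(self):
        model = build_unet(NetConfig.unet(kernel=3, steps=2, base_channels=2), seed=0)
        with pytest.raises(ValueError):
            train(model, [], TrainConfig(iterations=1))


def test_numerical_gradients_of_both_architectures(rng):
    """Backprop matches a central-difference directional derivative.

    The directional form averages over every parameter, so isolated ReLU
    kink or max-pool tie coordinates cannot dominate the comparison.
    """

    def directional_rel_err(model, x, t, eps=1e-5):
        probe_rng = np.random.default_rng(0)
        _, g = eng.cross_entropy_soft(model.forward(x), t)
        params = model.parameters()
        for p in params:
            p.zero_grad()
        model.backward(g)
        direction = [probe_rng.normal(size=p.value.shape) for p in params]
        analytic = sum(np.sum(p.grad * d) for p, d in zip(params, direction))
        for p, d in zip(params, direction):
            p.value += eps * d
        lp, _ = eng.cross_entropy_soft(model.forward(x), t)
        for p, d in zip(params, direction):
            p.value -= 2 * eps * d
        lm, _ = eng.cross_entropy_soft(model.forward(x), t)
        for p, d in zip(params, direction):
            p.value += eps * d
        numeric = (lp - lm) / (2 * eps)
        return abs(numeric - analytic) / max(abs(numeric), abs(analytic), 1e-12)

    # ReLU kinks crossed inside the finite-difference step bound the
    # attainable agreement; indexing/transposition bugs would show as O(1)
    unet = build_unet(NetConfig.unet(kernel=3, steps=2, base_channels=3, dropout=0.0), seed=2)
    assert directional_rel_err(unet, rng.random((1, 8, 8, 1)), rng.random((1, 8, 8))) < 5e-2
    swnet = build_swnet(NetConfig.swnet(steps=2, base_channels=3, patch_size=8), seed=3)
    assert directional_rel_err(swnet, rng.random((2, 8, 8, 1)), rng.random(2)) < 5e-2


def test_exact_gradients_of_linear_contraction(rng):
    """With identity activations the stack is piecewise-linear in its
    weights, so backprop through conv, pool and the quadratic loss must
    match finite differences to near machine precision."""
    from ceseg.nets.models import _Contraction

    cfg = NetConfig.unet(kernel=3, steps=2, base_channels=3, dropout=0.0)
    probe = _Contraction(cfg, np.random.default_rng(1), activation="identity", pool="max")
    x = rng.random((1, 8, 8, 1))

    def loss_of():
        out, _ = probe.forward(x)
        return 0.5 * float(np.sum(out**2)), out

    _, out = loss_of()
    for p in probe.params():
        p.zero_grad()
    probe.backward(out)
    direction = [np.random.default_rng(2).normal(size=p.value.shape) for p in probe.params()]
    analytic = sum(np.sum(p.grad * d) for p, d in zip(probe.params(), direction))
    eps = 1e-6
    for p, d in zip(probe.params(), direction):
        p.value += eps * d
    lp, _ = loss_of()
    for p, d in zip(probe.params(), direction):
        p.value -= 2 * eps * d
    lm, _ = loss_of()
    numeric = (lp - lm) / (2 * eps)
    assert abs(numeric - analytic) / max(abs(analytic), 1e-12) < 1e-7
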