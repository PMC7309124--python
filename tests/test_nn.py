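"""Multi-resolution ASPP network: shapes, gradients, training contracts."""

import numpy as np
import pytest

from echotex.nn import (
    CNNConfig,
    TrainConfig,
    build_model,
    patches_to_arrays,
    predict_proba,
    setup_filter_counts,
    shape_report,
    train,
)
from echotex.nn.layers import (
    BatchNorm2d,
    Conv2d,
    MaxPool2x2,
    softmax_cross_entropy,
)


def small_config(**kw):
    defaults = dict(nf1=4, nf2=4, nf3=4, input_size=36, dropout_rate=0.0)
    defaults.update(kw)
    return CNNConfig(**defaults)


class TestShapes:
    def test_volume_chain_small(self):
        shapes = dict(shape_report(CNNConfig(nf1=16, nf2=16, nf3=16)))
        assert (shapes["block1 output"].channels, shapes["block1 output"].height) == (48, 56)
        assert shapes["block1 concat"].channels == 3 * 16 + 1
        assert shapes["after first max-pooling"].height == 28
        assert shapes["block2 concat"].channels == 3 * (16 + 16) + 1
        assert shapes["after second max-pooling"].height == 14
        assert shapes["aspp concat"].channels == 5 * 16
        assert shapes["aspp output"].channels == 16

    @pytest.mark.parametrize("setup", [1, 2, 3])
    @pytest.mark.parametrize("nf1", [16, 32])
    def test_setups_build_and_follow_chain(self, setup, nf1):
        nf1, nf2, nf3 = setup_filter_counts(setup, nf1)
        shapes = dict(shape_report(CNNConfig(nf1=nf1, nf2=nf2, nf3=nf3)))
        assert shapes["block1 output"].channels == 3 * nf1
        assert shapes["block2 concat"].channels == 3 * (nf1 + nf2) + 1
        assert shapes["aspp concat"].channels == 5 * nf3

    def test_exactly_two_spatial_halvings(self):
        shapes = dict(shape_report(CNNConfig(nf1=8, nf2=8, nf3=8)))
        assert shapes["input"].height == 56
        assert shapes["after first max-pooling"].height == 28
        assert shapes["after second max-pooling"].height == 14
        assert shapes["aspp output"].height == 14

    def test_setup_relations(self):
        assert setup_filter_counts(1, 128) == (128, 64, 32)
        assert setup_filter_counts(2, 16) == (16, 32, 128)
        assert setup_filter_counts(3, 64) == (64, 64, 64)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CNNConfig(nf1=0)
        with pytest.raises(ValueError):
            CNNConfig(kernel_set=(3, 4))


class TestForward:
    def test_softmax_rows_sum_to_one(self, rng):
        model = build_model(small_config(), seed=0)
        x = rng.random((2, 1, 36, 36)).astype(np.float32)
        probs = predict_proba(model, x)
        assert probs.shape == (2, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicated_patch_identical_rows(self, rng):
        model = build_model(small_config(dropout_rate=0.5), seed=0)
        patch = rng.random((1, 36, 36)).astype(np.float32)
        batch = np.stack([patch, patch])
        probs = predict_proba(model, batch)  # evaluation mode: no dropout
        assert np.array_equal(probs[0], probs[1])

    def test_aspp_too_small_input_rejected(self):
        model = build_model(small_config(input_size=16), seed=0)
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 1, 16, 16), np.float32))


class TestGradients:
    def _layer_grad_check(self, layer, x, n_checks=5):
        w_out = None

        def loss(xv):
            nonlocal w_out
            y = layer.forward(xv, train=True)
            if w_out is None:
                w_out = np.random.default_rng(1).random(y.shape).astype(np.float32)
            return float((y.astype(np.float64) * w_out).sum())

        rng = np.random.default_rng(2)
        loss(x)
        for p in layer.params():
            p.zero_grad()
        dx = layer.backward(w_out.copy())
        for _ in range(n_checks):
            i = rng.integers(x.size)
            eps = 1e-3
            xf = x.ravel()
            old = xf[i]
            xf[i] = old + eps
            lp = loss(x)
            xf[i] = old - eps
            lm = loss(x)
            xf[i] = old
            num = (lp - lm) / (2 * eps)
            ana = dx.ravel()[i]
            assert abs(num - ana) <= 0.03 * max(abs(num), abs(ana), 1e-3)

    def test_conv_backward_im2col_path(self, rng):
        self._layer_grad_check(
            Conv2d(1, 3, 7, rng=np.random.default_rng(0)),
            rng.random((2, 12, 12, 1)).astype(np.float32),
        )

    def test_conv_backward_tap_path(self, rng):
        conv = Conv2d(40, 3, 3, dilation=2, rng=np.random.default_rng(0))
        # 40 channels * 9 taps exceeds the im2col threshold: tap-loop path
        self._layer_grad_check(conv, rng.random((1, 9, 9, 40)).astype(np.float32))

    def test_batchnorm_backward(self, rng):
        self._layer_grad_check(BatchNorm2d(3), rng.random((4, 6, 6, 3)).astype(np.float32))

    def test_maxpool_backward(self, rng):
        self._layer_grad_check(MaxPool2x2(), rng.random((2, 8, 8, 3)).astype(np.float32))

    def test_full_model_directional_derivative(self, rng):
        """The loss change along the analytic gradient direction must match
        the squared gradient norm (verifies the whole backward graph,
        shortcuts and all five ASPP branches included)."""
        model = build_model(small_config(nf1=2, nf2=2, nf3=2), seed=0)
        x = rng.random((4, 1, 36, 36)).astype(np.float32)
        y = rng.integers(0, 2, 4)

        def loss_fn():
            return softmax_cross_entropy(model.forward(x, train=True), y)

        _, dl = loss_fn()
        model.zero_grad()
        model.backward(dl)
        g = [p.grad.copy() for p in model.params()]
        gnorm2 = sum(float((gi**2).sum()) for gi in g)
        t = 1e-5
        for p, gi in zip(model.params(), g):
            p.value += t * gi
        lp, _ = loss_fn()
        for p, gi in zip(model.params(), g):
            p.value -= 2 * t * gi
        lm, _ = loss_fn()
        num = (lp - lm) / (2 * t)
        assert num == pytest.approx(gnorm2, rel=0.05)

    def test_gradient_flow_reaches_every_parameter(self, rng):
        """After one step on one batch every trainable tensor must move:
        no dead branch in the blocks, shortcuts or ASPP."""
        from echotex.nn.train import SGD

        model = build_model(small_config(dropout_rate=0.0), seed=0)
        x = rng.random((8, 1, 36, 36)).astype(np.float32)
        y = rng.integers(0, 2, 8)
        before = [p.value.copy() for p in model.params()]
        logits = model.forward(x, train=True)
        _, dl = softmax_cross_entropy(logits, y)
        model.zero_grad()
        model.backward(dl)
        SGD(model.params(), learning_rate=1e-2, momentum=0.0).step()
        for p, b in zip(model.params(), before):
            assert np.linalg.norm(p.value - b) > 0, p.name


def make_blob_patches(n, size=36, seed=0):
    """Trivially separable data: bright-left vs bright-right patches."""
    rng = np.random.default_rng(seed)
    x = rng.random((n, 1, size, size)).astype(np.float32) * 0.2
    y = rng.integers(0, 2, n)
    half = size // 2
    for i in range(n):
        if y[i]:
            x[i, 0, :, :half] += 0.6
        else:
            x[i, 0, :, half:] += 0.6
    return x, y


class TestTraining:
    def test_history_structure_and_finiteness(self):
        x, y = make_blob_patches(96)
        model = build_model(small_config(), seed=0)
        tc = TrainConfig(epochs=2, batch_size=32, learning_rate=1e-3, momentum=0.1, seed=0)
        model, hist = train(model, (x[:64], y[:64]), (x[64:], y[64:]), tc)
        assert len(hist["train_loss"]) == 2
        assert len(hist["val_accuracy"]) == 2
        assert all(np.isfinite(v) for v in hist["train_loss"])

    def test_same_seed_reproduces_history(self):
        x, y = make_blob_patches(64, seed=1)
        tc = TrainConfig(epochs=2, batch_size=32, learning_rate=1e-3, momentum=0.1, seed=3)
        hists = []
        for _ in range(2):
            model = build_model(small_config(dropout_rate=0.5), seed=5)
            _, hist = train(model, (x[:48], y[:48]), (x[48:], y[48:]), tc)
            hists.append(hist)
        assert hists[0]["train_loss"] == hists[1]["train_loss"]
        assert hists[0]["val_accuracy"] == hists[1]["val_accuracy"]

    def test_loss_decreases_on_easy_task(self):
        x, y = make_blob_patches(128, seed=2)
        model = build_model(small_config(), seed=0)
        tc = TrainConfig(epochs=6, batch_size=32, learning_rate=3e-3, momentum=0.1, seed=0)
        model, hist = train(model, (x[:96], y[:96]), (x[96:], y[96:]), tc)
        losses = hist["train_loss"]
        assert np.mean(losses[-2:]) < np.mean(losses[:2])

    def test_empty_training_data_rejected(self):
        model = build_model(small_config(), seed=0)
        with pytest.raises(ValueError):
            train(model, (np.zeros((0, 1, 36, 36), np.float32), np.zeros(0, int)),
                  (np.zeros((1, 1, 36, 36), np.float32), np.zeros(1, int)))

    def test_non_binary_labels_rejected(self):
        model = build_model(small_config(), seed=0)
        x = np.zeros((4, 1, 36, 36), np.float32)
        with pytest.raises(ValueError):
            train(model, (x, np.array([0, 1, 2, 1])), (x, np.array([0, 1, 0, 1])))

    def test_patch_conversion(self, labeled_patch):
        x, y = patches_to_arrays([labeled_patch])
        assert x.shape == (1, 1, 56, 56)
        assert x.max() <= 1.0
        assert y[0] == 1  # HCC is the positive class
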