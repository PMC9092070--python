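import numpy as np
import pytest

from retinaquant.nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    MaxPool2d,
    ReLU,
    SegModelConfig,
    SegUNet,
    SGEBlock,
)
from retinaquant.nn.model import load_checkpoint, save_checkpoint
from retinaquant.nn.sge import sge_forward

SIG1 = 1.0 / (1.0 + np.exp(-1.0))

TINY = SegModelConfig(encoder_widths=(8, 8, 16, 16, 16), sge_groups=4, seed=3)


def numeric_grad(fn, x, dy, eps=1e-6):
    """Central-difference gradient of sum(fn(x) * dy) w.r.t. x."""
    g = np.zeros_like(x)
    for idx in np.ndindex(x.shape):
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        g[idx] = ((fn(xp) - fn(xm)) * dy).sum() / (2 * eps)
    return g


class TestSGEBlock:
    def test_init_closed_form(self, rng):
        x = rng.normal(size=(2, 16, 5, 7))
        blk = SGEBlock(16, 8)
        y = blk.forward(x)
        assert np.allclose(y, SIG1 * x, atol=1e-12)
        assert y.shape == x.shape

    def test_zeros_in_zeros_out(self):
        blk = SGEBlock(8, 4)
        assert not blk.forward(np.zeros((1, 8, 4, 4))).any()

    def test_uniform_input_eps_guard(self):
        # zero-variance attention map: gate = sigmoid(shift) uniformly
        blk = SGEBlock(4, 2)
        blk.scale.data[:] = 0.7
        blk.shift.data[:] = 0.2
        x = np.full((1, 4, 3, 3), 2.0)
        y = blk.forward(x)
        expected = 1.0 / (1.0 + np.exp(-0.2)) * 2.0
        assert np.allclose(y, expected, atol=1e-9)

    def test_parameter_overhead_is_two_per_group(self):
        for groups in (2, 4, 8):
            blk = SGEBlock(16, groups)
            assert sum(p.size for p in blk.params()) == 2 * groups

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            SGEBlock(10, 4)

    def test_gradcheck(self, rng):
        blk = SGEBlock(4, 2)
        blk.scale.data[:] = [0.4, -0.3]
        blk.shift.data[:] = [1.2, 0.8]
        x = rng.normal(size=(2, 4, 3, 3))
        dy = rng.normal(size=x.shape)
        blk.forward(x)
        dx = blk.backward(dy)

        def f(xx):
            return sge_forward(xx, 2, blk.scale.data, blk.shift.data)[0]

        assert np.allclose(dx, numeric_grad(f, x, dy), atol=1e-7)


class TestLayerGradients:
    def test_conv2d(self, rng):
        layer = Conv2d(2, 3, 3, rng)
        x = rng.normal(size=(2, 2, 5, 5))
        dy = rng.normal(size=(2, 3, 5, 5))
        layer.forward(x)
        dx = layer.backward(dy)

        def f(xx):
            return Conv2dForward(layer, xx)

        assert np.allclose(dx, numeric_grad(f, x, dy), atol=1e-7)
        # weight gradient
        w0 = layer.weight.data.copy()
        gw = layer.weight.grad.copy()
        num_gw = np.zeros_like(w0)
        eps = 1e-6
        for idx in np.ndindex(w0.shape):
            layer.weight.data = w0.copy()
            layer.weight.data[idx] += eps
            yp = layer.forward(x)
            layer.weight.data = w0.copy()
            layer.weight.data[idx] -= eps
            ym = layer.forward(x)
            num_gw[idx] = ((yp - ym) * dy).sum() / (2 * eps)
        layer.weight.data = w0
        assert np.allclose(gw, num_gw, atol=1e-6)

    def test_conv_transpose(self, rng):
        layer = ConvTranspose2d(3, 2, rng)
        x = rng.normal(size=(2, 3, 4, 4))
        dy = rng.normal(size=(2, 2, 8, 8))
        layer.forward(x)
        dx = layer.backward(dy)
        assert np.allclose(dx, numeric_grad(
            lambda xx: ConvTForward(layer, xx), x, dy), atol=1e-7)

    def test_batchnorm(self, rng):
        layer = BatchNorm2d(3)
        layer.gamma.data[:] = [1.1, 0.9, 1.3]
        x = rng.normal(size=(2, 3, 4, 4))
        dy = rng.normal(size=x.shape)
        layer.forward(x, train=True)
        dx = layer.backward(dy)

        def f(xx):
            l2 = BatchNorm2d(3)
            l2.gamma.data[:] = layer.gamma.data
            return l2.forward(xx, train=True)

        assert np.allclose(dx, numeric_grad(f, x, dy), atol=1e-6)

    def test_maxpool(self, rng):
        layer = MaxPool2d()
        x = rng.normal(size=(2, 3, 6, 6))
        dy = rng.normal(size=(2, 3, 3, 3))
        layer.forward(x)
        dx = layer.backward(dy)
        assert np.allclose(dx, numeric_grad(
            lambda xx: MaxPool2d().forward(xx), x, dy), atol=1e-7)

    def test_relu(self, rng):
        layer = ReLU()
        x = rng.normal(size=(2, 3, 4, 4))
        dy = rng.normal(size=x.shape)
        layer.forward(x)
        assert np.array_equal(layer.backward(dy), dy * (x > 0))


def Conv2dForward(layer, x):
    out = layer.forward(x)
    layer._xp = None
    return out


def ConvTForward(layer, x):
    out = layer.forward(x)
    layer._x = None
    return out


class TestModel:
    def test_encode_scales(self, rng):
        model = SegUNet(TINY)
        feats = model.encode(rng.normal(size=(1, 3, 64, 64)), train=False)
        assert [f.values.shape[-1] for f in feats] == [64, 32, 16, 8, 4]
        assert [f.scale for f in feats] == [0, 1, 2, 3, 4]

    def test_indivisible_input_rejected(self, rng):
        model = SegUNet(TINY)
        with pytest.raises(ValueError, match="pad"):
            model.encode(rng.normal(size=(1, 3, 63, 64)))

    def test_score_shape_and_classes(self, rng):
        model = SegUNet(TINY)
        scores = model.forward(rng.normal(size=(2, 3, 32, 48)), train=False)
        assert scores.shape == (2, 6, 32, 48)

    def test_forward_deterministic(self, rng):
        x = rng.normal(size=(1, 3, 32, 32))
        a = SegUNet(TINY).forward(x, train=False)
        b = SegUNet(TINY).forward(x, train=False)
        assert np.array_equal(a, b)

    def test_argmax_tie_break_lowest_id(self):
        from retinaquant.nn.model import ScoreMap
        scores = np.zeros((6, 4, 4))
        assert (ScoreMap(scores).argmax_labels == 0).all()

    def test_perfect_scores_roundtrip(self, rng):
        from retinaquant.nn.model import ScoreMap
        labels = rng.integers(0, 6, size=(8, 8))
        scores = np.zeros((6, 8, 8))
        for c in range(6):
            scores[c] = labels == c
        assert np.array_equal(ScoreMap(scores).argmax_labels, labels)

    def test_sge_neutrality_vs_baseline(self, rng):
        """At init the SGE net equals the baseline scaled by sigmoid(1) per
        stage (eval mode, zero-initialized biases, identity BN)."""
        cfg_sge = TINY
        cfg_plain = SegModelConfig(encoder_widths=TINY.encoder_widths,
                                   sge_groups=4, sge_enabled=False, seed=3)
        m_sge, m_plain = SegUNet(cfg_sge), SegUNet(cfg_plain)
        x = rng.normal(size=(1, 3, 32, 32))
        f_sge = m_sge.encode(x, train=False)
        f_plain = m_plain.encode(x, train=False)
        for s in range(5):
            factor = SIG1 ** (s + 1)
            assert np.allclose(f_sge[s].values, factor * f_plain[s].values,
                               atol=1e-8), f"scale {s}"

    def test_parameter_overhead_exact(self):
        plain = SegUNet(SegModelConfig(encoder_widths=TINY.encoder_widths,
                                       sge_groups=4, sge_enabled=False, seed=3))
        sge = SegUNet(TINY)
        # one SGE block per encoder stage, 2 params per group each
        assert sge.n_parameters() - plain.n_parameters() == 5 * 2 * 4

    def test_translation_covariance(self, rng):
        """Shifting a zero-margin input by the total pooling stride (16 px)
        shifts the output correspondingly.  At initialization biases are
        zero and BN (eval mode) is the identity, so background activations
        stay exactly zero and coincide with the convolution padding,
        making the covariance exact as long as content does not wrap."""
        model = SegUNet(TINY)
        # wide zero margins keep the content's receptive-field spread away
        # from the seam at every scale
        base = np.zeros((1, 3, 32, 256))
        base[..., :, 112:144] = rng.normal(size=(1, 3, 32, 32))
        shifted = np.roll(base, 16, axis=3)
        ya = model.forward(base, train=False)
        yb = model.forward(shifted, train=False)
        assert np.allclose(np.roll(ya, 16, axis=3), yb, atol=1e-8)

    def test_decode_requires_five_scales(self, rng):
        model = SegUNet(TINY)
        feats = model.encode(rng.normal(size=(1, 3, 32, 32)), train=False)
        with pytest.raises(ValueError):
            model.decode(feats[:4])

    def test_config_validation(self):
        with pytest.raises(ValueError, match="5 scales"):
            SegModelConfig(encoder_widths=(8, 16, 32, 64))
        with pytest.raises(ValueError, match="divisible"):
            SegModelConfig(encoder_widths=(6, 16, 32, 64, 64), sge_groups=4)

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        model = SegUNet(TINY)
        x = rng.normal(size=(1, 3, 32, 32))
        before = model.forward(x, train=False)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        assert restored.config == model.config
        assert np.array_equal(restored.forward(x, train=False), before)

    def test_whole_model_gradient_descends(self, rng):
        """A few Adam steps on a fixed batch must reduce the loss."""
        from retinaquant.training import cross_entropy
        model = SegUNet(TINY)
        opt = Adam(model.params())
        x = rng.normal(size=(2, 3, 16, 16))
        y = rng.integers(0, 6, size=(2, 16, 16))
        losses = []
        for _ in range(5):
            scores = model.forward(x, train=True)
            loss, dscores = cross_entropy(scores, y)
            losses.append(loss)
            opt.zero_grad()
            model.backward(dscores)
            opt.step(1e-2)
        assert losses[-1] < losses[0]
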