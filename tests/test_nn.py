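"""Numerical-gradient verification of every layer and of the full nets.

Parameters are upcast to float64 for the checks; the production dtype is
float32, but the backward formulas are dtype-agnostic.
"""

import numpy as np
import pytest

from ecgdann import nn
from ecgdann.adversarial_training import _bce_grad_logits, _focal_grad_logits
from ecgdann.model import build_model

rng = np.random.default_rng(7)


def _num_grad(fn, arr, eps=1e-6):
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = arr[i]
        arr[i] = orig + eps
        lp = fn()
        arr[i] = orig - eps
        lm = fn()
        arr[i] = orig
        g[i] = (lp - lm) / (2 * eps)
    return g


def _check_layer(layer, x, train=True):
    w = rng.normal(size=layer.forward(x.copy(), train).shape)

    def loss():
        return float(np.sum(layer.forward(x, train) * w))

    layer.forward(x, train)
    dx = layer.backward(w.copy())
    assert np.allclose(dx, _num_grad(loss, x), rtol=1e-5, atol=1e-7)
    for p in layer.params:
        layer.forward(x, train)
        layer.backward(w.copy())
        ana = layer.grads[p].copy()
        assert np.allclose(ana, _num_grad(loss, layer.params[p]),
                           rtol=1e-5, atol=1e-7), p


def _upcast(*nets):
    for net in nets:
        for layer in nn._iter_layers(net):
            for k in layer.params:
                layer.params[k] = layer.params[k].astype(np.float64)
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean = layer.running_mean.astype(np.float64)
                layer.running_var = layer.running_var.astype(np.float64)


def _f64_conv(c_in, c_out, k):
    layer = nn.Conv1d(c_in, c_out, k, rng)
    layer.params["W"] = layer.params["W"].astype(np.float64)
    layer.params["b"] = layer.params["b"].astype(np.float64)
    return layer


class TestLayerGradients:
    def test_conv_multichannel(self):
        _check_layer(_f64_conv(3, 4, 5), rng.normal(size=(2, 17, 3)))

    def test_conv_single_channel(self):
        _check_layer(_f64_conv(1, 6, 8), rng.normal(size=(2, 30, 1)))

    def test_maxpool_even_and_odd_lengths(self):
        _check_layer(nn.MaxPool1d(2, 2), rng.normal(size=(2, 12, 3)))
        _check_layer(nn.MaxPool1d(2, 2), rng.normal(size=(2, 13, 3)))
        _check_layer(nn.MaxPool1d(3, 2), rng.normal(size=(2, 11, 2)))

    def test_fused_relu_maxpool_matches_separate_layers(self):
        x = rng.normal(size=(3, 21, 4))
        fused = nn.ReLUMaxPool2()
        relu, pool = nn.ReLU(), nn.MaxPool1d(2, 2)
        y_f = fused.forward(x.copy())
        y_s = pool.forward(relu.forward(x.copy()))
        assert np.allclose(y_f, y_s)
        g = rng.normal(size=y_f.shape)
        assert np.allclose(fused.backward(g.copy()),
                           relu.backward(pool.backward(g.copy())))
        _check_layer(nn.ReLUMaxPool2(), rng.normal(size=(2, 14, 3)))

    def test_linear(self):
        layer = nn.Linear(7, 5, rng)
        layer.params["W"] = layer.params["W"].astype(np.float64)
        layer.params["b"] = layer.params["b"].astype(np.float64)
        _check_layer(layer, rng.normal(size=(4, 7)))

    @pytest.mark.parametrize("shape", [(6, 5), (3, 9, 4)])
    def test_batchnorm_train_mode(self, shape):
        layer = nn.BatchNorm(shape[-1])
        layer.params["gamma"] = 1.0 + 0.1 * rng.normal(size=shape[-1])
        layer.params["beta"] = 0.1 * rng.normal(size=shape[-1])
        layer.running_mean = layer.running_mean.astype(np.float64)
        layer.running_var = layer.running_var.astype(np.float64)
        _check_layer(layer, rng.normal(size=shape))

    def test_batchnorm_eval_uses_running_statistics(self):
        layer = nn.BatchNorm(4)
        x = rng.normal(2.0, 3.0, size=(200, 4)).astype(np.float32)
        for _ in range(300):
            layer.forward(x, train=True)
        y = layer.forward(x, train=False)
        assert abs(float(y.mean())) < 0.05 and abs(float(y.std()) - 1.0) < 0.05

    def test_dropout_scaling_preserves_expectation(self):
        layer = nn.Dropout(0.4, seed=0)
        x = np.ones((200, 500), dtype=np.float32)
        y = layer.forward(x, train=True)
        kept = y[y > 0]
        assert np.allclose(kept, 1.0 / 0.6, atol=1e-6)
        assert abs(float(y.mean()) - 1.0) < 0.01
        assert np.array_equal(layer.forward(x, train=False), x)


class TestFullModelGradients:
    @pytest.mark.parametrize("variant,D", [("model_a", 40), ("multi_scale", 60)])
    def test_joint_objective_gradients(self, variant, D):
        m = build_model(D=D, variant=variant, lambda_=0.2, dropout=0.0, seed=3)
        _upcast(m.F, m.C, m.D)
        B = 4
        x = rng.normal(size=(B, D))
        y = rng.integers(0, 4, size=B)
        rr = rng.normal(size=(B, 6))
        d = np.array([0.0, 0.0, 1.0, 1.0])
        use_rr = variant != "model_a"

        def loss_c():
            f = m.F.forward(x, train=True)
            logits = m.C.forward(f, rr if use_rr else None, train=True)
            return _focal_grad_logits(logits, y, 2.0)[0]

        def loss_d():
            f = m.F.forward(x, train=True)
            return _bce_grad_logits(m.D.forward(f, train=True), d)[0]

        for loss, nets, backprop in (
            (loss_c, (m.F, m.C),
             lambda f: m.F.backward(m.C.backward(
                 _focal_grad_logits(m.C.forward(f, rr if use_rr else None,
                                                train=True), y, 2.0)[1]))),
            (loss_d, (m.F, m.D),
             lambda f: m.F.backward(m.D.backward(
                 _bce_grad_logits(m.D.forward(f, train=True), d)[1]))),
        ):
            f = m.F.forward(x, train=True)
            backprop(f)
            for layer, p in nn.collect_params(*nets):
                arr = layer.params[p]
                ana = layer.grads[p].copy()
                flat = rng.choice(arr.size, size=min(4, arr.size), replace=False)
                idxs = [np.unravel_index(k, arr.shape) for k in flat]
                num = []
                for i in idxs:
                    orig = arr[i]
                    arr[i] = orig + 1e-6
                    lp = loss()
                    arr[i] = orig - 1e-6
                    lm = loss()
                    arr[i] = orig
                    num.append((lp - lm) / 2e-6)
                assert np.allclose([ana[i] for i in idxs], num,
                                   rtol=1e-4, atol=1e-7), (type(layer).__name__, p)


class TestSgdAndState:
    def test_sgd_step_and_momentum(self):
        layer = nn.Linear(3, 2, rng)
        layer.grads["W"] = np.ones_like(layer.params["W"])
        layer.grads["b"] = np.ones_like(layer.params["b"])
        w0 = layer.params["W"].copy()
        opt = nn.SGD(nn.collect_params(layer), lr=0.5, momentum=0.9)
        opt.step()
        assert np.allclose(layer.params["W"], w0 - 0.5)
        opt.step()  # velocity: 1 + 0.9 = 1.9
        assert np.allclose(layer.params["W"], w0 - 0.5 - 0.95, atol=1e-6)

    def test_state_roundtrip_and_param_hash(self):
        a = build_model(D=40, variant="model_a", seed=1)
        b = build_model(D=40, variant="model_a", seed=2)
        assert nn.param_hash(a.F) != nn.param_hash(b.F)
        nn.set_state(nn.get_state(a.F, a.C, a.D), b.F, b.C, b.D)
        assert nn.param_hash(a.F, a.C, a.D) == nn.param_hash(b.F, b.C, b.D)
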