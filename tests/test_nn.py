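"""Gradient and oracle checks for the numpy network toolkit."""

import numpy as np
import pytest

from chd_phonoscreen.nn import (
    Tensor, concat, Conv2d, DepthwiseSeparableConv2d, BatchNorm2d,
    CoordinateAttention, MixedPool2d,
)
from chd_phonoscreen.lcacnn import mixed_pool

from oracles import depthwise_separable_brute, mixed_pool_brute


def _numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        hi = f()
        x[i] = orig - eps
        lo = f()
        x[i] = orig
        g[i] = (hi - lo) / (2 * eps)
        it.iternext()
    return g


def _check_grads(build_loss, tensors, tol=1e-5):
    loss = build_loss()
    loss.backward()
    for t in tensors:
        num = _numeric_grad(lambda: float(build_loss().data), t.data)
        assert np.allclose(t.grad, num, atol=tol), "analytic vs numeric gradient"


def test_conv2d_gradients_match_finite_differences():
    rng = np.random.default_rng(0)
    x = Tensor(rng.standard_normal((2, 3, 5, 5)), requires_grad=True)
    conv = Conv2d(3, 4, 3, rng)
    _check_grads(lambda: (x.conv2d(conv.w, conv.b) ** 2.0).sum(),
                 [x, conv.w, conv.b])


def test_depthwise_separable_gradients_and_oracle():
    rng = np.random.default_rng(1)
    x = Tensor(rng.standard_normal((1, 3, 4, 4)), requires_grad=True)
    layer = DepthwiseSeparableConv2d(3, 5, 3, rng)
    _check_grads(lambda: (layer(x) ** 2.0).sum(), [x, layer.dw, layer.pw, layer.b])
    out = layer(x).data[0]
    brute = depthwise_separable_brute(x.data[0], layer.dw.data,
                                      layer.pw.data[:, :, 0, 0], layer.b.data)
    assert np.max(np.abs(out - brute)) < 1e-9


def test_batchnorm_gradients_and_normalization():
    rng = np.random.default_rng(2)
    x = Tensor(rng.standard_normal((4, 3, 2, 2)), requires_grad=True)
    bn = BatchNorm2d(3)
    out = bn(x)
    assert np.allclose(out.data.mean(axis=(0, 2, 3)), 0, atol=1e-9)
    assert np.allclose(out.data.std(axis=(0, 2, 3)), 1, atol=1e-2)
    _check_grads(lambda: (bn(x) ** 2.0).sum() + (bn(x) * 0.3).sum(),
                 [x, bn.gamma, bn.beta], tol=1e-4)


def test_coordinate_attention_gradients_flow():
    rng = np.random.default_rng(3)
    x = Tensor(rng.standard_normal((2, 4, 3, 5)), requires_grad=True)
    ca = CoordinateAttention(4, 2, rng)
    _check_grads(lambda: (ca(x) ** 2.0).sum(), [x] + ca.parameters(), tol=1e-4)


def test_coordinate_attention_shape_and_contraction():
    rng = np.random.default_rng(4)
    for shape in [(1, 8, 4, 4), (3, 4, 2, 7)]:
        x = Tensor(rng.standard_normal(shape))
        out = CoordinateAttention(shape[1], 2, rng)(x)
        assert out.shape == shape
        assert np.all(np.abs(out.data) <= np.abs(x.data) + 1e-12)


def test_coordinate_attention_constant_input_pools_to_constant():
    rng = np.random.default_rng(5)
    x = Tensor(np.full((1, 4, 3, 5), 1.7))
    mh = x.mean(axis=3, keepdims=True)
    mw = x.mean(axis=2, keepdims=True)
    assert np.allclose(mh.data, 1.7) and np.allclose(mw.data, 1.7)
    with pytest.raises(ValueError):
        CoordinateAttention(4, 8, rng)


def test_mixed_pool_extremes_and_oracle():
    block = np.array([[1.0, 2.0], [3.0, 4.0]])
    assert mixed_pool(block, 2, 1.0) == pytest.approx(4.0)
    assert mixed_pool(block, 2, 0.0) == pytest.approx(2.5)
    assert mixed_pool(np.full((4, 4), 7.0), 2, 0.37) == pytest.approx(np.full((2, 2), 7.0))
    rng = np.random.default_rng(6)
    for lam in (0.0, 0.5, 1.0):
        x = rng.standard_normal((6, 7))  # odd width exercises edge padding
        assert np.allclose(mixed_pool(x, 2, lam), mixed_pool_brute(x, 2, lam))


def test_mixed_pool_gradients():
    rng = np.random.default_rng(7)
    x = Tensor(rng.standard_normal((1, 2, 4, 4)), requires_grad=True)
    pool = MixedPool2d(2)
    pool.lam = 0.5
    _check_grads(lambda: (pool(x) ** 2.0).sum(), [x])


def test_concat_and_slice_round_trip_gradients():
    rng = np.random.default_rng(8)
    a = Tensor(rng.standard_normal((2, 3)), requires_grad=True)
    b = Tensor(rng.standard_normal((2, 5)), requires_grad=True)
    _check_grads(lambda: (concat([a, b], axis=1)[:, 2:6] ** 2.0).sum(), [a, b])
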