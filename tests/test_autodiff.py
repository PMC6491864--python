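"""Gradient and semantic checks of the NumPy backprop backend."""

import numpy as np
import pytest

from hippseg import autodiff as ad
from hippseg.neural_ops import DilatedKernel3D, DiscreteSignal3D, dilated_conv3d


def numeric_grad(f, x, eps=1e-3):
    g = np.zeros(x.shape)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


def rel_err(a, b):
    return np.abs(a - b).max() / (np.abs(b).max() + 1e-8)


def test_conv3d_gradients(rng):
    # Param rather than plain Tensor: input gradients are pruned for raw leaves
    x = ad.Param(rng.standard_normal((1, 2, 6, 5, 6)).astype(np.float32))
    conv = ad.Conv3d(2, 3, k=3, dilation=2, rng=rng)
    w = rng.standard_normal(conv(x).data.shape).astype(np.float32)

    def scalar():
        return float((conv(ad.Tensor(x.data)).data.astype(np.float64) * w).sum())

    out = conv(x)
    out.backward(w)
    assert rel_err(x.grad, numeric_grad(scalar, x.data)) < 2e-2
    assert rel_err(conv.weight.grad, numeric_grad(scalar, conv.weight.data)) < 2e-2
    assert rel_err(conv.bias.grad, numeric_grad(scalar, conv.bias.data)) < 2e-2


def test_conv3d_matches_reference_semantics(rng):
    """im2col backend equals the textbook dilated convolution after kernel mirror."""
    F = rng.standard_normal((7, 7, 7))
    h = rng.standard_normal((3, 3, 3))
    for rate in (1, 2):
        ref = dilated_conv3d(DiscreteSignal3D(F), DilatedKernel3D(h, rate=rate)).values
        conv = ad.Conv3d(1, 1, k=3, dilation=rate, pad=0, rng=rng)
        conv.weight.data = h[::-1, ::-1, ::-1][None, None].astype(np.float32)
        conv.bias.data[:] = 0.0
        out = conv(ad.Tensor(F[None, None].astype(np.float32))).data[0, 0]
        np.testing.assert_allclose(out, ref, atol=1e-5)


def test_conv_transpose_gradients_and_shape(rng):
    x = ad.Tensor(rng.standard_normal((1, 2, 3, 4, 3)).astype(np.float32))
    ct = ad.ConvTranspose3d(2, 2, rng=rng)
    out = ct(x)
    assert out.data.shape == (1, 2, 6, 8, 6)  # exact doubling
    w = rng.standard_normal(out.data.shape).astype(np.float32)

    def scalar():
        return float((ct(ad.Tensor(x.data)).data.astype(np.float64) * w).sum())

    out.backward(w)
    assert rel_err(x.grad, numeric_grad(scalar, x.data)) < 2e-2
    assert rel_err(ct.weight.grad, numeric_grad(scalar, ct.weight.data)) < 2e-2


def test_batchnorm_gradients(rng):
    x = ad.Tensor(rng.standard_normal((2, 3, 4, 3, 4)).astype(np.float32))
    bn = ad.BatchNorm3d(3)
    w = rng.standard_normal(x.data.shape).astype(np.float32)

    def scalar():
        fresh = ad.BatchNorm3d(3)
        fresh.gamma, fresh.beta = bn.gamma, bn.beta
        return float((fresh(ad.Tensor(x.data), training=True).data
                      .astype(np.float64) * w).sum())

    out = bn(x, training=True)
    out.backward(w)
    assert rel_err(x.grad, numeric_grad(scalar, x.data)) < 2e-2
    assert rel_err(bn.gamma.grad, numeric_grad(scalar, bn.gamma.data)) < 2e-2


def test_maxpool_gradient_routes_to_argmax(rng):
    x = ad.Tensor(rng.standard_normal((1, 1, 4, 4, 4)).astype(np.float32))
    mp = ad.MaxPool3d()
    out = mp(x)
    assert out.data.shape == (1, 1, 2, 2, 2)
    out.backward(np.ones_like(out.data))
    # exactly one gradient unit per pooling cell, at the max location
    assert x.grad.sum() == 8.0
    assert ((x.grad == 1.0).sum()) == 8


def test_softmax_cross_entropy_gradient(rng):
    x = ad.Tensor(rng.standard_normal((2, 4, 2, 2, 2)).astype(np.float32))
    labels = rng.integers(0, 4, (2, 2, 2, 2))

    def scalar():
        return float(ad.softmax_cross_entropy(ad.Tensor(x.data), labels, "sum").data)

    loss = ad.softmax_cross_entropy(x, labels, "sum")
    loss.backward()
    assert rel_err(x.grad, numeric_grad(scalar, x.data)) < 2e-2


def test_softmax_cross_entropy_rejects_bad_labels(rng):
    x = ad.Tensor(rng.standard_normal((1, 3, 2, 2, 2)).astype(np.float32))
    with pytest.raises(ValueError):
        ad.softmax_cross_entropy(x, np.full((1, 2, 2, 2), 3))


def test_concat_and_add_backward(rng):
    a = ad.Tensor(rng.standard_normal((1, 2, 3, 3, 3)).astype(np.float32))
    b = ad.Tensor(rng.standard_normal((1, 3, 3, 3, 3)).astype(np.float32))
    cat = ad.concat([a, b])
    assert cat.data.shape == (1, 5, 3, 3, 3)
    g = rng.standard_normal(cat.data.shape).astype(np.float32)
    cat.backward(g)
    np.testing.assert_array_equal(a.grad, g[:, :2])
    np.testing.assert_array_equal(b.grad, g[:, 2:])

    c = ad.Tensor(a.data.copy())
    d = ad.Tensor(a.data.copy())
    s = ad.add(c, d)
    s.backward(np.ones_like(s.data))
    assert np.all(c.grad == 1.0) and np.all(d.grad == 1.0)


def test_dropout_train_eval_semantics(rng):
    x = ad.Tensor(np.ones((1, 4, 8, 8, 8), dtype=np.float32))
    drop = ad.Dropout(0.5, rng=np.random.default_rng(0))
    eval_out = drop(x, training=False).data
    np.testing.assert_array_equal(eval_out, x.data)
    train_out = drop(x, training=True).data
    assert set(np.unique(train_out)) == {0.0, 2.0}  # inverted scaling
    assert abs((train_out > 0).mean() - 0.5) < 0.05


def test_adam_converges_on_quadratic():
    p = ad.Param(np.array([5.0, -3.0], dtype=np.float32))
    opt = ad.Adam([p], lr=0.1)
    for _ in range(300):
        p.grad = 2 * p.data
        opt.step()
    assert np.abs(p.data).max() < 1e-2
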