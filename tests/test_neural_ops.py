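"""The dilated-convolution reference and receptive-field arithmetic."""

import numpy as np
import pytest
from scipy import ndimage

from hippseg.neural_ops import (DilatedKernel3D, DiscreteSignal3D,
                                ReceptiveFieldReport, dilated_conv3d,
                                receptive_field)


def brute_force_dilated_conv(F, h, rate):
    """Literal evaluation of (F *_l h)(p) = sum_{s + l*t = p} F(s) h(t), valid region."""
    r = h.shape[0] // 2
    m = rate * r
    out_shape = tuple(n - 2 * m for n in F.shape)
    out = np.zeros(out_shape)
    for p0 in range(out_shape[0]):
        for p1 in range(out_shape[1]):
            for p2 in range(out_shape[2]):
                acc = 0.0
                for t0 in range(-r, r + 1):
                    for t1 in range(-r, r + 1):
                        for t2 in range(-r, r + 1):
                            s = (p0 + m - rate * t0, p1 + m - rate * t1,
                                 p2 + m - rate * t2)
                            acc += F[s] * h[t0 + r, t1 + r, t2 + r]
                out[p0, p1, p2] = acc
    return out


def test_identity_kernel_at_rate_one(rng):
    F = rng.standard_normal((6, 6, 6))
    h = np.zeros((3, 3, 3))
    h[1, 1, 1] = 1.0
    out = dilated_conv3d(DiscreteSignal3D(F), DilatedKernel3D(h, rate=1))
    np.testing.assert_allclose(out.values, F[1:-1, 1:-1, 1:-1], atol=1e-12)


def test_zero_signal_gives_zero_output(rng):
    F = np.zeros((7, 7, 7))
    h = rng.standard_normal((3, 3, 3))
    out = dilated_conv3d(DiscreteSignal3D(F), DilatedKernel3D(h, rate=2))
    assert np.all(out.values == 0.0)


@pytest.mark.parametrize("rate", [1, 2, 3])
def test_matches_bruteforce_sum(rng, rate):
    F = rng.standard_normal((9, 8, 9))
    h = rng.standard_normal((3, 3, 3))
    out = dilated_conv3d(DiscreteSignal3D(F), DilatedKernel3D(h, rate=rate))
    expected = brute_force_dilated_conv(F, h, rate)
    np.testing.assert_allclose(out.values, expected, atol=1e-6)


def test_rate_one_equals_standard_convolution(rng):
    """Eq.-style (flip) convolution at rate 1 agrees with scipy's convolve."""
    for _ in range(10):
        F = rng.standard_normal((7, 7, 7))
        h = rng.standard_normal((3, 3, 3))
        ours = dilated_conv3d(DiscreteSignal3D(F), DilatedKernel3D(h, rate=1),
                              pad=True)
        ref = ndimage.convolve(F, h, mode="constant", cval=0.0)
        np.testing.assert_allclose(ours.values, ref, atol=1e-9)


def test_linearity(rng):
    F1 = rng.standard_normal((7, 7, 7))
    F2 = rng.standard_normal((7, 7, 7))
    h = DilatedKernel3D(rng.standard_normal((3, 3, 3)), rate=2)
    a, b = 1.7, -0.4
    lhs = dilated_conv3d(DiscreteSignal3D(a * F1 + b * F2), h).values
    rhs = (a * dilated_conv3d(DiscreteSignal3D(F1), h).values
           + b * dilated_conv3d(DiscreteSignal3D(F2), h).values)
    np.testing.assert_allclose(lhs, rhs, atol=1e-6)


def test_padding_preserves_shape(rng):
    F = rng.standard_normal((7, 7, 7))
    h = DilatedKernel3D(rng.standard_normal((3, 3, 3)), rate=2)
    assert dilated_conv3d(DiscreteSignal3D(F), h, pad=True).values.shape == (7, 7, 7)


def test_invalid_rate_rejected(rng):
    with pytest.raises(ValueError):
        DilatedKernel3D(rng.standard_normal((3, 3, 3)), rate=0)
    with pytest.raises(ValueError):
        DilatedKernel3D(rng.standard_normal((3, 3, 3)), rate=-2)


def test_signal_too_small_raises(rng):
    F = DiscreteSignal3D(rng.standard_normal((3, 3, 3)))
    h = DilatedKernel3D(rng.standard_normal((3, 3, 3)), rate=2)
    with pytest.raises(ValueError):
        dilated_conv3d(F, h)


def perturbation_support_side(forward, in_shape, rng, delta=10.0):
    """Side length of the output region affected by a center-voxel perturbation."""
    x = rng.standard_normal(in_shape).astype(np.float32)
    base = forward(x)
    xp = x.copy()
    center = tuple(s // 2 for s in in_shape[2:])
    xp[(0, slice(None)) + center] += delta
    diff = np.abs(forward(xp) - base).sum(axis=(0, 1))
    changed = np.nonzero(diff > 1e-4)
    return max(c.max() - c.min() + 1 for c in changed)


def test_receptive_field_closed_forms():
    assert receptive_field([(1, 1, 1)]).side == 1
    assert receptive_field([(3, 1, 1)]).side == 3
    rep = receptive_field([(3, 1, 1), (3, 2, 1), (3, 4, 1)])
    assert rep.side == 15
    assert rep.sides == [3, 7, 15]  # non-decreasing, odd
    assert rep.strides == [1, 1, 1]


def test_receptive_field_with_stride():
    # one 3^3 conv then a stride-2 layer doubles later jumps
    rep = receptive_field([(3, 1, 1), (2, 1, 2), (3, 1, 1)])
    assert rep.side == 3 + 1 + 2 * 2
    assert rep.strides[-1] == 2


def test_receptive_field_empty_raises():
    with pytest.raises(ValueError):
        receptive_field([])


@pytest.mark.parametrize("rates,expected", [((1,), 3), ((1, 2), 7), ((1, 2, 4), 15)])
def test_receptive_field_matches_perturbation_oracle(rng, rates, expected):
    from hippseg import autodiff as ad

    convs = []
    ch = 1
    for rate in rates:
        convs.append(ad.Conv3d(ch, 2, k=3, dilation=rate, rng=rng))
        ch = 2

    def forward(x):
        t = ad.Tensor(x)
        for c in convs:
            t = c(t)
        return t.data

    side = perturbation_support_side(forward, (1, 1, 21, 21, 21), rng)
    assert side == expected
    assert receptive_field([(3, r, 1) for r in rates]).side == expected
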