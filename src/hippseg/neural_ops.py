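"""Reference semantics for the dilated 3D convolution and receptive-field
arithmetic.

This module is a correctness oracle, not a fast path: the segmentation
networks delegate to an optimized im2col backend (``hippseg.autodiff``) which
must agree with the definitions here.

The dilated convolution of a discrete signal ``F`` with a filter ``h``
supported on the cube ``[-r, r]^3`` at dilation rate ``l`` is

    (F *_l h)(p) = sum_{s + l*t = p} F(s) h(t),

i.e. the output at ``p`` gathers ``F(p - l*t) h(t)`` over all kernel offsets
``t``.  With ``l = 1`` this is the ordinary (flip) convolution.  Machine
learning "convolutions" are correlations; they coincide with this definition
after mirroring the kernel, since the support is symmetric about the origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DiscreteSignal3D",
    "DilatedKernel3D",
    "ReceptiveFieldReport",
    "dilated_conv3d",
    "receptive_field",
]


@dataclass
class DiscreteSignal3D:
    """Real-valued map on a finite box of the 3D integer lattice."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("signal must be 3D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal has non-finite entries")


@dataclass
class DilatedKernel3D:
    """Discrete filter on [-r, r]^3 with a positive integer dilation rate."""

    weights: np.ndarray
    rate: int = 1

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 3:
            raise ValueError("kernel must be 3D")
        if any(n % 2 == 0 for n in self.weights.shape):
            raise ValueError("kernel sides must be odd (support [-r, r]^3)")
        if len(set(self.weights.shape)) != 1:
            raise ValueError("kernel support must be cubic")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("kernel has non-finite entries")
        if int(self.rate) != self.rate or self.rate < 1:
            raise ValueError(f"dilation rate must be a positive integer, got {self.rate}")
        self.rate = int(self.rate)

    @property
    def radius(self) -> int:
        return self.weights.shape[0] // 2


def dilated_conv3d(
    signal: DiscreteSignal3D,
    kernel: DilatedKernel3D,
    pad: bool = False,
) -> DiscreteSignal3D:
    """Dilated convolution (F *_l h)(p) = sum_{s + l*t = p} F(s) h(t).

    With ``pad=False`` only positions ``p`` where every sampled lattice point
    lies inside the signal support are produced ("valid" output); with
    ``pad=True`` the signal is zero-padded by ``rate * r`` per side so the
    output grid equals the input grid.

    Parameters
    ----------
    signal
        The input signal ``F``.
    kernel
        The filter ``h`` with its dilation rate ``l``.
    pad
        Zero-pad to preserve the spatial dimensions.
    """
    F = signal.values
    h = kernel.weights
    l = kernel.rate
    r = kernel.radius
    m = l * r  # margin consumed per side

    if pad:
        F = np.pad(F, m)
    out_shape = tuple(n - 2 * m for n in F.shape)
    if any(n < 1 for n in out_shape):
        raise ValueError(
            f"signal support {signal.values.shape} too small for kernel radius {r} "
            f"at rate {l}; request padding or enlarge the signal"
        )

    out = np.zeros(out_shape, dtype=np.float64)
    k = 2 * r + 1
    # Output index q maps to lattice position p = q + m (in the padded frame);
    # the term for offset t is F(p - l*t) h(t) = F[q + m - l*t] h(t).
    for ti in range(k):
        for tj in range(k):
            for tk in range(k):
                w = h[ti, tj, tk]
                if w == 0.0:
                    continue
                # offset t = (ti - r, tj - r, tk - r); start = m - l*(ti - r)
                si = m - l * (ti - r)
                sj = m - l * (tj - r)
                sk = m - l * (tk - r)
                out += w * F[
                    si : si + out_shape[0],
                    sj : sj + out_shape[1],
                    sk : sk + out_shape[2],
                ]
    return DiscreteSignal3D(out)


@dataclass
class ReceptiveFieldReport:
    """Per-layer cubic receptive-field side (in input voxels) and cumulative stride."""

    sides: list[int]
    strides: list[int]

    @property
    def side(self) -> int:
        """Receptive-field side after the last layer."""
        return self.sides[-1]


def receptive_field(layers: Sequence[tuple[int, int, int]]) -> ReceptiveFieldReport:
    """Receptive-field arithmetic for a stack of (kernel size, rate, stride) layers.

    For a stride-1 stack the side after n layers is
    ``1 + sum_i rate_i * (k_i - 1)``; a stride multiplies the index jump of
    every later layer.
    """
    layers = list(layers)
    if not layers:
        raise ValueError("layer list is empty")
    sides: list[int] = []
    strides: list[int] = []
    side = 1
    jump = 1
    for k, rate, stride in layers:
        if k < 1 or rate < 1 or stride < 1:
            raise ValueError(f"invalid layer parameters (k={k}, rate={rate}, stride={stride})")
        side += rate * (k - 1) * jump
        jump *= stride
        sides.append(side)
        strides.append(jump)
    return ReceptiveFieldReport(sides=sides, strides=strides)
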