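"""Minimal reverse-mode automatic differentiation for 3D segmentation nets.

Implements exactly the operations the U-net family needs — im2col-based
dilated 3D convolution, stride-2 transposed convolution, 2x2x2 max pooling,
batch normalization, ReLU, dropout, channel concatenation, elementwise
addition, and a fused softmax cross-entropy — each with an analytic backward
pass, plus an Adam optimizer with L2 weight decay.

Arrays are (batch, channels, depth, height, width) float32 throughout.  The
convolution follows the machine-learning correlation convention
``out(p) = sum_t x(p + dilation*t) w(t)``; mirroring the kernel recovers the
textbook dilated convolution implemented in :mod:`hippseg.neural_ops`, which
serves as this backend's oracle.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Param",
    "Module",
    "Conv3d",
    "ConvTranspose3d",
    "BatchNorm3d",
    "ReLU",
    "Dropout",
    "MaxPool3d",
    "concat",
    "add",
    "softmax_cross_entropy",
    "softmax",
    "Adam",
]


# ---------------------------------------------------------------------------
# Tape
# ---------------------------------------------------------------------------

class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None):
        """Reverse-accumulate gradients from this node through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape})"


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=False)
    else:
        t.grad = t.grad + g


def _needs_grad(t: Tensor) -> bool:
    """Plain leaf tensors (raw inputs) need no gradient; params and op outputs do."""
    return bool(t._parents) or isinstance(t, Param)


class Param(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data)

    def zero_grad(self):
        self.grad = None


# ---------------------------------------------------------------------------
# im2col plumbing
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, k: int, stride: int, dilation: int):
    """Unfold a padded (N, C, D, H, W) array into (N, C*k^3, L) columns.

    Filled offset-by-offset with strided slice copies, which is far cheaper
    than reshaping a sliding-window view.
    """
    n, c = xp.shape[:2]
    eff = dilation * (k - 1) + 1
    do, ho, wo = ((s - eff) // stride + 1 for s in xp.shape[2:])
    cols = np.empty((n, c, k, k, k, do, ho, wo), dtype=xp.dtype)
    for a in range(k):
        ia = a * dilation
        for b in range(k):
            ib = b * dilation
            for cc in range(k):
                ic = cc * dilation
                cols[:, :, a, b, cc] = xp[
                    :, :,
                    ia : ia + stride * do : stride,
                    ib : ib + stride * ho : stride,
                    ic : ic + stride * wo : stride,
                ]
    return cols.reshape(n, c * k ** 3, do * ho * wo), (do, ho, wo)


def _col2im(dcols: np.ndarray, xp_shape, k: int, stride: int, dilation: int, out_sp):
    """Adjoint of :func:`_im2col`: scatter-add columns back onto the grid."""
    n, c = xp_shape[:2]
    do, ho, wo = out_sp
    d6 = dcols.reshape(n, c, k, k, k, do, ho, wo)
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    for a in range(k):
        ia = a * dilation
        for b in range(k):
            ib = b * dilation
            for cc in range(k):
                ic = cc * dilation
                dxp[
                    :, :,
                    ia : ia + stride * do : stride,
                    ib : ib + stride * ho : stride,
                    ic : ic + stride * wo : stride,
                ] += d6[:, :, a, b, cc]
    return dxp


def _pad5(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))


def _unpad5(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return x[:, :, p:-p, p:-p, p:-p]


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Module:
    """Base class: recursive parameter collection over attributes."""

    def parameters(self) -> list[Param]:
        out: list[Param] = []
        seen: set[int] = set()
        self._collect(out, seen)
        return out

    def _collect(self, out: list[Param], seen: set[int]) -> None:
        for v in self.__dict__.values():
            if isinstance(v, Param) and id(v) not in seen:
                seen.add(id(v))
                out.append(v)
            elif isinstance(v, Module):
                v._collect(out, seen)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item._collect(out, seen)
                    elif isinstance(item, Param) and id(item) not in seen:
                        seen.add(id(item))
                        out.append(item)

    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Flat name -> array map of parameters and buffers (for checkpoints)."""
        out: dict[str, np.ndarray] = {}
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Param):
                out[key] = v.data
            elif isinstance(v, Module):
                out.update(v.state_arrays(key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(f"{key}.{i}."))
                    elif isinstance(item, Param):
                        out[f"{key}.{i}"] = item.data
            elif isinstance(v, np.ndarray) and name.startswith("running_"):
                out[key] = v
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Param):
                v.data = np.asarray(state[key], dtype=np.float32)
            elif isinstance(v, Module):
                v.load_state_arrays(state, key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_arrays(state, f"{key}.{i}.")
                    elif isinstance(item, Param):
                        item.data = np.asarray(state[f"{key}.{i}"], dtype=np.float32)
            elif isinstance(v, np.ndarray) and name.startswith("running_"):
                setattr(self, name, np.asarray(state[key], dtype=np.float32))

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return self.forward(x, training)


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv3d(Module):
    """Padded dilated 3D convolution, stride 1 or more, cubic kernel."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, stride: int = 1,
                 dilation: int = 1, pad: int | None = None,
                 rng: np.random.Generator | None = None):
        if dilation < 1:
            raise ValueError(f"dilation rate must be >= 1, got {dilation}")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.stride, self.dilation = stride, dilation
        # default padding keeps stride-1 spatial dims: dilation*(k-1)/2 per side
        self.pad = dilation * (k - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng()
        self.weight = Param(he_normal(rng, (out_ch, in_ch, k, k, k), in_ch * k ** 3))
        self.bias = Param(np.zeros(out_ch, dtype=np.float32))

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        if x.data.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.data.shape[1]}")
        xp = _pad5(x.data, self.pad)
        cols, out_sp = _im2col(xp, self.k, self.stride, self.dilation)
        w2 = self.weight.data.reshape(self.out_ch, -1)
        out = np.matmul(w2, cols) + self.bias.data[:, None]
        n = x.data.shape[0]
        out = out.reshape(n, self.out_ch, *out_sp)

        weight, bias, pad, k, stride, dil = (
            self.weight, self.bias, self.pad, self.k, self.stride, self.dilation)
        xp_shape = xp.shape

        def backward(g: np.ndarray) -> None:
            gf = g.reshape(n, self.out_ch, -1)
            dw = np.matmul(gf, cols.transpose(0, 2, 1)).sum(axis=0)
            _accum(weight, dw.reshape(weight.data.shape))
            _accum(bias, gf.sum(axis=(0, 2)))
            if _needs_grad(x):
                dcols = np.matmul(w2.T, gf)
                dxp = _col2im(dcols, xp_shape, k, stride, dil, out_sp)
                _accum(x, _unpad5(dxp, pad))

        return Tensor(out, (x,), backward)


class ConvTranspose3d(Module):
    """Transposed 3D convolution; kernel 4, stride 2, pad 1 doubles dims exactly."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 4, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None):
        self.in_ch, self.out_ch, self.k, self.stride, self.pad = in_ch, out_ch, k, stride, pad
        rng = rng or np.random.default_rng()
        self.weight = Param(he_normal(rng, (in_ch, out_ch, k, k, k), in_ch * k ** 3))
        self.bias = Param(np.zeros(out_ch, dtype=np.float32))

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        if x.data.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.data.shape[1]}")
        n, _, d, h, w = x.data.shape
        k, s, p = self.k, self.stride, self.pad
        out_sp = tuple((m - 1) * s - 2 * p + k for m in (d, h, w))
        padded_sp = tuple(m + 2 * p for m in out_sp)  # = (m-1)*s + k
        xf = x.data.reshape(n, self.in_ch, -1)
        w2 = self.weight.data.reshape(self.in_ch, -1)  # (Ci, Co*k^3)
        cols = np.matmul(w2.T, xf)  # (N, Co*k^3, L)
        outp = _col2im(cols, (n, self.out_ch, *padded_sp), k, s, 1, (d, h, w))
        out = _unpad5(outp, p) + self.bias.data[None, :, None, None, None]

        weight, bias = self.weight, self.bias

        def backward(g: np.ndarray) -> None:
            gp = _pad5(g, p)
            gcols, sp2 = _im2col(gp, k, s, 1)  # sp2 == (d, h, w)
            gf = g.reshape(n, self.out_ch, -1)
            _accum(bias, gf.sum(axis=(0, 2)))
            dw = np.matmul(xf, gcols.transpose(0, 2, 1)).sum(axis=0)
            _accum(weight, dw.reshape(weight.data.shape))
            dx = np.matmul(w2, gcols).reshape(x.data.shape)
            _accum(x, dx)

        return Tensor(out, (x,), backward)


class BatchNorm3d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.gamma = Param(np.ones(ch, dtype=np.float32))
        self.beta = Param(np.zeros(ch, dtype=np.float32))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        axes = (0, 2, 3, 4)
        if training:
            mean = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        bshape = (1, self.ch, 1, 1, 1)
        xhat = (x.data - mean.reshape(bshape)) * inv.reshape(bshape)
        out = self.gamma.data.reshape(bshape) * xhat + self.beta.data.reshape(bshape)

        gamma, beta = self.gamma, self.beta

        def backward(g: np.ndarray) -> None:
            _accum(gamma, (g * xhat).sum(axis=axes))
            _accum(beta, g.sum(axis=axes))
            gm = gamma.data.reshape(bshape) * inv.reshape(bshape)
            if training:
                m = g.shape[0] * g.shape[2] * g.shape[3] * g.shape[4]
                gs = g.sum(axis=axes).reshape(bshape)
                gxs = (g * xhat).sum(axis=axes).reshape(bshape)
                dx = gm * (g - gs / m - xhat * gxs / m)
            else:
                dx = gm * g
            _accum(x, dx.astype(np.float32))

        return Tensor(out, (x,), backward)


class ReLU(Module):
    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        mask = x.data > 0
        out = np.where(mask, x.data, 0.0).astype(np.float32)

        def backward(g: np.ndarray) -> None:
            _accum(x, g * mask)

        return Tensor(out, (x,), backward)


class Dropout(Module):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        if not training or self.rate == 0.0:
            def backward_id(g: np.ndarray) -> None:
                _accum(x, g)
            return Tensor(x.data, (x,), backward_id)
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.data.shape) < keep).astype(np.float32) / keep

        def backward(g: np.ndarray) -> None:
            _accum(x, g * mask)

        return Tensor(x.data * mask, (x,), backward)


class MaxPool3d(Module):
    """2x2x2 max pooling with stride 2 (the only pooling the nets use)."""

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        n, c, d, h, w = x.data.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x pooling, got {(d, h, w)}")
        xr = (x.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
              .transpose(0, 1, 2, 4, 6, 3, 5, 7)
              .reshape(n, c, d // 2, h // 2, w // 2, 8))
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

        def backward(g: np.ndarray) -> None:
            gr = np.zeros_like(xr)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            dx = (gr.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
                  .transpose(0, 1, 2, 5, 3, 6, 4, 7)
                  .reshape(n, c, d, h, w))
            _accum(x, dx)

        return Tensor(out, (x,), backward)


# ---------------------------------------------------------------------------
# Functional ops
# ---------------------------------------------------------------------------

def concat(tensors: list[Tensor]) -> Tensor:
    """Channel concatenation (axis 1)."""
    out = np.concatenate([t.data for t in tensors], axis=1)
    sizes = [t.data.shape[1] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            _accum(t, g[:, a:b])

    return Tensor(out, tuple(tensors), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise sum of same-shape tensors (residual connection)."""
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch in add: {a.data.shape} vs {b.data.shape}")

    def backward(g: np.ndarray) -> None:
        _accum(a, g)
        _accum(b, g)

    return Tensor(a.data + b.data, (a, b), backward)


def softmax(scores: np.ndarray, axis: int = 1) -> np.ndarray:
    """Numerically stable softmax over class scores (plain array in/out)."""
    z = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(scores: Tensor, labels: np.ndarray,
                          reduction: str = "mean") -> Tensor:
    """Fused softmax + cross-entropy over (N, K, ...) scores and int labels.

    Labels are 0-based class ids in {0, ..., K-1}.  ``reduction='sum'`` gives
    the plain negative log-likelihood summed over voxels; ``'mean'`` divides
    by the voxel count.
    """
    k = scores.data.shape[1]
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must lie in [0, {k - 1}]")
    z = scores.data
    zmax = z.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z - zmax).sum(axis=1, keepdims=True)) + zmax
    logp = z - lse  # (N, K, ...)
    lab = labels[:, None]
    picked = np.take_along_axis(logp, lab, axis=1)[:, 0]
    n_vox = picked.size
    loss = -picked.sum(dtype=np.float64)
    if reduction == "mean":
        loss = loss / n_vox
    elif reduction != "sum":
        raise ValueError(f"unknown reduction {reduction!r}")

    def backward(g: np.ndarray) -> None:
        p = np.exp(logp)
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, lab, 1.0, axis=1)
        scale = float(g) / (n_vox if reduction == "mean" else 1.0)
        _accum(scores, ((p - onehot) * scale).astype(np.float32))

    return Tensor(np.float32(loss), (scores,), backward)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with L2 weight decay added to the raw gradient (classic coupling)."""

    def __init__(self, params: list[Param], lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1 - b1 ** self.t
        c2 = 1 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * (g * g)
            p.data = p.data - lr * (self.m[i] / c1) / (np.sqrt(self.v[i] / c2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
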