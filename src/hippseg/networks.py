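"""The dilated-dense U-net family for volumetric multi-class segmentation.

Three variants share one encoder/decoder skeleton with three 2x2x2 max
poolings and three stride-2 transposed convolutions:

* ``unet3d``   — classic 3D U-net: all three skip connections concatenate the
  contracting-path features directly into the expanding path.
* ``dunet``    — the middle skip (level 2) is routed through a dilated dense
  block that aggregates multi-scale context at full level-2 resolution before
  concatenation; levels 1 and 3 concatenate directly.
* ``resdunet`` — DUnet with every pair of path convolutions wrapped in a
  post-activation residual unit (identity shortcut, or a 1x1x1 projection
  when the channel counts differ).

Every 3x3x3 convolution is padded, followed by batch normalization and a
ReLU; the dense block additionally applies dropout after each of its dilated
convolutions.  A final 1x1x1 convolution maps to K class scores at the input
resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Module, Param, Tensor

__all__ = ["NetworkSpec", "SegNet", "build_network", "save_checkpoint", "load_checkpoint"]

VARIANTS = ("unet3d", "dunet", "resdunet")


@dataclass
class NetworkSpec:
    """Architecture hyperparameters for one segmentation network.

    ``channel_schedule`` gives the feature-map count at the three resolution
    levels plus the bottleneck; by default it doubles from ``base_channels``
    (e.g. 32/64/128/256).  ``dense_layers``/``growth``/``dilation_schedule``
    configure the dilated dense block on the level-2 skip; growth defaults to
    the level-2 channel count.
    """

    variant: str = "resdunet"
    in_channels: int = 2
    num_classes: int = 6
    base_channels: int = 32
    channel_schedule: tuple[int, int, int, int] | None = None
    dense_layers: int = 3
    growth: int | None = None
    dilation_schedule: tuple[int, ...] = (1, 2, 4)
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.channel_schedule is None:
            b = self.base_channels
            self.channel_schedule = (b, 2 * b, 4 * b, 8 * b)
        self.channel_schedule = tuple(int(c) for c in self.channel_schedule)
        if len(self.channel_schedule) != 4:
            raise ValueError("channel_schedule needs 4 entries (3 levels + bottleneck)")
        self.dilation_schedule = tuple(int(r) for r in self.dilation_schedule)
        if len(self.dilation_schedule) != self.dense_layers:
            raise ValueError(
                f"dilation_schedule length {len(self.dilation_schedule)} != "
                f"dense_layers {self.dense_layers}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        for name in ("in_channels", "num_classes", "base_channels", "dense_layers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.growth is None:
            self.growth = self.channel_schedule[1]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channel_schedule"] = list(self.channel_schedule)
        d["dilation_schedule"] = list(self.dilation_schedule)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        if d.get("channel_schedule") is not None:
            d["channel_schedule"] = tuple(d["channel_schedule"])
        if d.get("dilation_schedule") is not None:
            d["dilation_schedule"] = tuple(d["dilation_schedule"])
        return cls(**d)


class ConvBNReLU(Module):
    def __init__(self, in_ch, out_ch, k=3, dilation=1, rng=None):
        self.conv = ad.Conv3d(in_ch, out_ch, k=k, dilation=dilation, rng=rng)
        self.bn = ad.BatchNorm3d(out_ch)
        self.relu = ad.ReLU()

    def forward(self, x, training=False):
        return self.relu(self.bn(self.conv(x, training), training), training)


class ConvPair(Module):
    """Two 3x3x3 conv+BN+ReLU layers, optionally grouped by a residual connection.

    The residual form is post-activation: the shortcut is added after the
    second convolution's batch norm and the final ReLU follows the sum.  A
    1x1x1 projection stands in for the identity when channel counts differ.
    """

    def __init__(self, in_ch, out_ch, residual=False, rng=None):
        self.residual = residual
        self.conv1 = ad.Conv3d(in_ch, out_ch, k=3, rng=rng)
        self.bn1 = ad.BatchNorm3d(out_ch)
        self.conv2 = ad.Conv3d(out_ch, out_ch, k=3, rng=rng)
        self.bn2 = ad.BatchNorm3d(out_ch)
        self.relu = ad.ReLU()
        self.proj = None
        if residual and in_ch != out_ch:
            self.proj = ad.Conv3d(in_ch, out_ch, k=1, rng=rng)

    def forward(self, x, training=False):
        h = self.relu(self.bn1(self.conv1(x, training), training), training)
        h = self.bn2(self.conv2(h, training), training)
        if self.residual:
            shortcut = self.proj(x, training) if self.proj is not None else x
            h = ad.add(h, shortcut)
            return self.relu(h, training)
        return self.relu(h, training)


class DilatedDenseBlock(Module):
    """Dense stack of dilated 3x3x3 convolutions on the level-2 skip.

    Layer ``i`` consumes the channel-concatenation of the block input and all
    earlier layer outputs and emits ``growth`` channels through
    conv -> BN -> ReLU -> dropout; the block output concatenates the input
    with every layer output, so C input channels become C + L*growth.
    """

    def __init__(self, in_ch, layers, growth, rates, dropout_rate, rng=None,
                 dropout_rng=None):
        if len(rates) != layers:
            raise ValueError("dilation schedule length must equal the layer count")
        self.in_ch, self.growth, self.n_layers = in_ch, growth, layers
        self.convs, self.bns, self.drops = [], [], []
        ch = in_ch
        for rate in rates:
            self.convs.append(ad.Conv3d(ch, growth, k=3, dilation=rate, rng=rng))
            self.bns.append(ad.BatchNorm3d(growth))
            self.drops.append(ad.Dropout(dropout_rate, rng=dropout_rng))
            ch += growth
        self.relu = ad.ReLU()
        self.out_channels = in_ch + layers * growth

    def forward(self, x, training=False):
        feats = [x]
        for conv, bn, drop in zip(self.convs, self.bns, self.drops):
            h = concat_or_single(feats)
            h = self.relu(bn(conv(h, training), training), training)
            h = drop(h, training)
            feats.append(h)
        return ad.concat(feats)


def concat_or_single(tensors):
    return tensors[0] if len(tensors) == 1 else ad.concat(tensors)


class SegNet(Module):
    """Configurable 3D segmentation network (unet3d / dunet / resdunet)."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(seed + 1)
        res = spec.variant == "resdunet"
        c1, c2, c3, c4 = spec.channel_schedule
        g, L = spec.growth, spec.dense_layers

        self.enc1 = ConvPair(spec.in_channels, c1, res, rng)
        self.enc2 = ConvPair(c1, c2, res, rng)
        self.enc3 = ConvPair(c2, c3, res, rng)
        self.bottom = ConvPair(c3, c4, res, rng)
        self.pool = ad.MaxPool3d()

        self.dense = None
        skip2_ch = c2
        if spec.variant in ("dunet", "resdunet"):
            self.dense = DilatedDenseBlock(c2, L, g, spec.dilation_schedule,
                                           spec.dropout_rate, rng, self.dropout_rng)
            skip2_ch = self.dense.out_channels

        self.up3 = ad.ConvTranspose3d(c4, c3, rng=rng)
        self.dec3 = ConvPair(c3 + c3, c3, res, rng)
        self.up2 = ad.ConvTranspose3d(c3, c2, rng=rng)
        self.dec2 = ConvPair(skip2_ch + c2, c2, res, rng)
        self.up1 = ad.ConvTranspose3d(c2, c1, rng=rng)
        self.dec1 = ConvPair(c1 + c1, c1, res, rng)
        self.head = ad.Conv3d(c1, spec.num_classes, k=1, rng=rng)

        # channel bookkeeping at every concatenation, audited at build time
        self.channel_audit = {
            "skip3_concat": c3 + c3,
            "skip2_concat": skip2_ch + c2,
            "skip1_concat": c1 + c1,
        }
        assert self.dec3.conv1.in_ch == self.channel_audit["skip3_concat"]
        assert self.dec2.conv1.in_ch == self.channel_audit["skip2_concat"]
        assert self.dec1.conv1.in_ch == self.channel_audit["skip1_concat"]

    def seed_dropout(self, seed: int) -> None:
        self.dropout_rng = np.random.default_rng(seed)
        if self.dense is not None:
            for d in self.dense.drops:
                d.rng = self.dropout_rng

    def forward(self, x, training: bool = False) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.data.ndim != 5:
            raise ValueError("input must be (batch, channels, depth, height, width)")
        if x.data.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} channels, got {x.data.shape[1]}")
        if any(s % 8 for s in x.data.shape[2:]):
            raise ValueError(
                f"spatial dims {x.data.shape[2:]} must be divisible by 8 "
                "(three stride-2 poolings)")

        s1 = self.enc1(x, training)                       # level 1, c1
        s2 = self.enc2(self.pool(s1, training), training)  # level 2, c2
        s3 = self.enc3(self.pool(s2, training), training)  # level 3, c3
        b = self.bottom(self.pool(s3, training), training)

        skip2 = self.dense(s2, training) if self.dense is not None else s2

        h = self.dec3(ad.concat([self.up3(b, training), s3]), training)
        h = self.dec2(ad.concat([self.up2(h, training), skip2]), training)
        h = self.dec1(ad.concat([self.up1(h, training), s1]), training)
        return self.head(h, training)

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def build_network(spec: NetworkSpec, seed: int = 0) -> SegNet:
    return SegNet(spec, seed=seed)


def save_checkpoint(path, network: SegNet, extra: dict | None = None) -> None:
    """Write all weights, BN running statistics, and the spec to one .npz file."""
    state = network.state_arrays()
    meta = {"spec": network.spec.to_dict()}
    if extra:
        meta["extra"] = extra
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> SegNet:
    with np.load(path) as f:
        meta = json.loads(bytes(f["__meta__"]).decode())
        state = {k: f[k] for k in f.files if k != "__meta__"}
    spec = NetworkSpec.from_dict(meta["spec"])
    net = SegNet(spec)
    net.load_state_arrays(state)
    return net
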