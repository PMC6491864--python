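"""Softmax loss and the optimization schedule.

Training uses Adam with a step learning-rate decay: the rate starts at
``base_lr`` and is multiplied by ``gamma`` every ``step_size`` iterations
(defaults 1e-4, 0.1, 10,000).  "Momentum" maps onto Adam's first-moment
coefficient beta1 and weight decay is the classic L2 penalty added to the raw
gradient — the coupling used by Caffe-era solvers.  Batches are uniform
random patch draws with replacement across all training subjects; training
stops at a fixed iteration budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .networks import SegNet
from .sampling import PatchSet

__all__ = ["TrainConfig", "TrainResult", "softmax_loss", "lr_at", "train",
           "patch_dice"]


@dataclass
class TrainConfig:
    batch_size: int = 5
    base_lr: float = 1e-4
    gamma: float = 0.1
    step_size: int = 10_000
    weight_decay: float = 5e-4
    momentum: float = 0.9           # Adam beta1
    max_iterations: int = 60_000
    rng_seed: int = 0
    val_every: int = 1_000
    log_every: int = 10

    def __post_init__(self) -> None:
        for name in ("batch_size", "base_lr", "step_size", "max_iterations",
                     "val_every", "log_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")
        if self.weight_decay < 0 or not 0.0 <= self.momentum < 1.0:
            raise ValueError("invalid weight_decay or momentum")


def softmax_loss(scores: np.ndarray, labels: np.ndarray, reduction: str = "sum") -> float:
    """Negative log-likelihood of the per-voxel softmax over class scores.

    ``scores`` is (N, K, ...) final-layer output, ``labels`` (N, ...) int
    class ids in {0..K-1}.  Computed through a stable log-sum-exp; the sum
    form equals N_vox * ln K at uniform scores.
    """
    t = Tensor(np.asarray(scores, dtype=np.float32))
    return float(ad.softmax_cross_entropy(t, labels, reduction=reduction).data)


def lr_at(iteration: int, config: TrainConfig) -> float:
    """Step decay: base_lr * gamma ** floor(iteration / step_size)."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    return config.base_lr * config.gamma ** (iteration // config.step_size)


def patch_dice(network: SegNet, patches: np.ndarray, labels: np.ndarray,
               batch: int = 8) -> float:
    """Mean foreground Dice of eval-mode predictions over a patch array."""
    k = network.spec.num_classes
    inter = np.zeros(k)
    sa = np.zeros(k)
    sb = np.zeros(k)
    for i in range(0, len(patches), batch):
        pred = network.forward(patches[i:i + batch], training=False).data.argmax(axis=1)
        truth = labels[i:i + batch]
        for c in range(1, k):
            pm = pred == c
            tm = truth == c
            inter[c] += (pm & tm).sum()
            sa[c] += pm.sum()
            sb[c] += tm.sum()
    present = [c for c in range(1, k) if sa[c] + sb[c] > 0]
    if not present:
        return float("nan")
    return float(np.mean([2 * inter[c] / (sa[c] + sb[c]) for c in present]))


@dataclass
class TrainResult:
    log: pd.DataFrame                 # iteration, lr, loss (+ train/val dice rows)
    final_iteration: int
    best_val_dice: float | None = None
    best_state: dict | None = None    # weights at the best validation point
    stopped_early: bool = False


def train(network: SegNet, patchset: PatchSet, config: TrainConfig,
          val_patchset: PatchSet | None = None,
          stop_train_dice: float | None = None,
          dice_every: int | None = None) -> TrainResult:
    """Adam-train a network on a fixed patch set.

    ``stop_train_dice`` (with ``dice_every``) enables early exit once the
    eval-mode Dice on the training patches reaches a target — used by the
    reduced overfitting runs; full runs leave it unset and stop at
    ``max_iterations``.  Raises on NaN loss.
    """
    patches = np.asarray(patchset.patches, dtype=np.float32)
    labels = np.asarray(patchset.labels)
    if patches.shape[0] == 0:
        raise ValueError("empty patch set")
    if patches.shape[1] != network.spec.in_channels:
        raise ValueError("patch channels do not match the network input channels")

    rng = np.random.default_rng(config.rng_seed)
    network.seed_dropout(config.rng_seed + 1)
    opt = ad.Adam(network.parameters(), lr=config.base_lr, beta1=config.momentum,
                  weight_decay=config.weight_decay)

    rows = []
    best_val = None
    best_state = None
    stopped = False
    it = 0
    for it in range(config.max_iterations):
        lr = lr_at(it, config)
        idx = rng.integers(0, len(patches), size=config.batch_size)
        out = network.forward(patches[idx], training=True)
        loss = ad.softmax_cross_entropy(out, labels[idx], reduction="mean")
        loss_val = float(loss.data)
        if not np.isfinite(loss_val):
            raise RuntimeError(f"loss became non-finite at iteration {it}")
        opt.zero_grad()
        loss.backward()
        opt.step(lr)

        if it % config.log_every == 0 or it == config.max_iterations - 1:
            rows.append({"iteration": it, "lr": lr, "loss": loss_val,
                         "train_dice": np.nan, "val_dice": np.nan})

        if val_patchset is not None and (it + 1) % config.val_every == 0:
            vd = patch_dice(network, val_patchset.patches, val_patchset.labels)
            rows.append({"iteration": it, "lr": lr, "loss": loss_val,
                         "train_dice": np.nan, "val_dice": vd})
            if best_val is None or vd > best_val:
                best_val = vd
                best_state = {k: v.copy() for k, v in network.state_arrays().items()}

        if stop_train_dice is not None and dice_every and (it + 1) % dice_every == 0:
            td = patch_dice(network, patches, labels)
            rows.append({"iteration": it, "lr": lr, "loss": loss_val,
                         "train_dice": td, "val_dice": np.nan})
            if td >= stop_train_dice:
                stopped = True
                break

    return TrainResult(pd.DataFrame(rows), final_iteration=it,
                       best_val_dice=best_val, best_state=best_state,
                       stopped_early=stopped)
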