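"""Overlapped sliding-window prediction with majority-vote fusion.

A trained network is applied to every window on a stride lattice (plus
end-aligned windows so the whole volume is covered).  Each window casts one
hard-label vote per voxel from its own argmax; the fused label is the
per-voxel plurality.  Ties go to the smallest class index, so background
(class 0) wins any tie it is part of — the conservative choice against false
positives.  Probability averaging is available as an off-by-default
alternative.
"""

from __future__ import annotations

import itertools

import numpy as np

from .autodiff import softmax
from .volumes import ImageVolume, LabelVolume

__all__ = ["window_origins", "predict_volume", "argmax_label"]

DEFAULT_PATCH_SIZE = 24
DEFAULT_STRIDE = 8


def _axis_origins(dim: int, patch: int, stride: int) -> list[int]:
    if patch > dim:
        raise ValueError(f"patch size {patch} exceeds volume dim {dim}")
    origins = list(range(0, dim - patch + 1, stride))
    if origins[-1] != dim - patch:
        origins.append(dim - patch)  # end-aligned window for full coverage
    return origins


def window_origins(dims, patch_size: int = DEFAULT_PATCH_SIZE,
                   stride: int = DEFAULT_STRIDE) -> np.ndarray:
    """All window origins covering the volume: stride lattice + end alignment."""
    per_axis = [_axis_origins(d, patch_size, stride) for d in dims]
    return np.array(list(itertools.product(*per_axis)), dtype=np.int64)


def argmax_label(prob: np.ndarray) -> np.ndarray:
    """Per-voxel argmax class of a (K, ...) probability map; ties -> smallest index."""
    prob = np.asarray(prob)
    if np.isnan(prob).any():
        raise ValueError("probability map contains NaN")
    if not np.allclose(prob.sum(axis=0), 1.0, atol=1e-3):
        raise ValueError("probabilities do not sum to 1 per voxel")
    return prob.argmax(axis=0)


def predict_volume(network, channels: np.ndarray,
                   patch_size: int = DEFAULT_PATCH_SIZE,
                   stride: int = DEFAULT_STRIDE,
                   fusion: str = "majority") -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window segmentation of a (C, D, H, W) multi-modality volume.

    Returns ``(labels, votes)`` where ``votes`` is the per-voxel per-class
    integer vote grid (for ``fusion='majority'``) or the summed probability
    grid (for ``fusion='average'``).  Every voxel is covered by at least one
    window.
    """
    channels = np.asarray(channels, dtype=np.float32)
    if channels.ndim != 4:
        raise ValueError("channels must be (C, D, H, W)")
    if channels.shape[0] != network.spec.in_channels:
        raise ValueError(
            f"network expects {network.spec.in_channels} channels, got {channels.shape[0]}")
    dims = channels.shape[1:]
    k = network.spec.num_classes
    if fusion not in ("majority", "average"):
        raise ValueError(f"unknown fusion {fusion!r}")
    votes = np.zeros((k, *dims), dtype=np.int32 if fusion == "majority" else np.float64)
    r = patch_size
    for x, y, z in window_origins(dims, patch_size, stride):
        win = channels[None, :, x:x + r, y:y + r, z:z + r]
        scores = network.forward(win, training=False).data[0]  # (K, r, r, r)
        if fusion == "majority":
            lab = scores.argmax(axis=0)
            onehot = np.eye(k, dtype=np.int32)[lab].transpose(3, 0, 1, 2)
            votes[:, x:x + r, y:y + r, z:z + r] += onehot
        else:
            votes[:, x:x + r, y:y + r, z:z + r] += softmax(scores, axis=0)
    # argmax takes the first maximum: smallest class index wins ties, and
    # background participates first in any tie it reaches
    labels = votes.argmax(axis=0).astype(np.int16)
    return labels, votes
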