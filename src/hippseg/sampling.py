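"""Training-patch extraction.

Candidate patches are enumerated on a stride-2 lattice over the cropped
volume; only windows containing at least one foreground (hippocampal) voxel
qualify.  The candidates are numbered in raster order, the numbering is
randomly permuted, and the first half is kept as the training set for that
subject — so roughly a thousand patches per subject at typical crop
geometries.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np

from .volumes import ImageVolume, LabelVolume

__all__ = [
    "PatchSet",
    "enumerate_candidate_patches",
    "select_training_patches",
    "extract_patchset",
    "subject_seed",
]

DEFAULT_PATCH_SIZE = 24
DEFAULT_STRIDE = 2


@dataclass
class PatchSet:
    """Aligned multi-channel image patches and label patches with their origins."""

    patches: np.ndarray  # (n, channels, R, R, R) float32
    labels: np.ndarray   # (n, R, R, R) int
    origins: np.ndarray  # (n, 3) voxel coordinates in the source (cropped) volume
    rng_seed: int = 0

    def __len__(self) -> int:
        return len(self.origins)

    def manifest(self) -> dict:
        """Origins + seed only; patches are re-derivable from the volumes."""
        return {"rng_seed": int(self.rng_seed),
                "patch_size": int(self.patches.shape[-1]),
                "origins": self.origins.tolist()}

    def save_manifest(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.manifest(), f)


def subject_seed(global_seed: int, subject_id: str) -> int:
    """Stable per-subject RNG seed from the global seed and the subject id."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(subject_id.encode())) % (2 ** 31)


def enumerate_candidate_patches(labels: LabelVolume, patch_size: int = DEFAULT_PATCH_SIZE,
                                stride: int = DEFAULT_STRIDE) -> np.ndarray:
    """Origins (raster order) of stride-lattice windows holding >= 1 foreground voxel.

    Returns an (n, 3) int array.  All-background labels give an empty list.
    """
    lab = labels.data
    r = patch_size
    if any(r > s for s in lab.shape):
        raise ValueError(f"patch size {r} exceeds volume dims {lab.shape}")
    fg = (lab > 0).astype(np.int64)
    # integral image: window sum over [o, o+r) per axis
    c = fg
    for ax in range(3):
        c = np.cumsum(c, axis=ax)
    cp = np.pad(c, ((1, 0), (1, 0), (1, 0)))
    ox = np.arange(0, lab.shape[0] - r + 1, stride)
    oy = np.arange(0, lab.shape[1] - r + 1, stride)
    oz = np.arange(0, lab.shape[2] - r + 1, stride)
    X, Y, Z = np.meshgrid(ox, oy, oz, indexing="ij")

    def s(a, b, cc):
        return cp[a, b, cc]

    wsum = (s(X + r, Y + r, Z + r) - s(X, Y + r, Z + r) - s(X + r, Y, Z + r)
            - s(X + r, Y + r, Z) + s(X, Y, Z + r) + s(X, Y + r, Z)
            + s(X + r, Y, Z) - s(X, Y, Z))
    keep = wsum > 0
    origins = np.stack([X[keep], Y[keep], Z[keep]], axis=1)
    return origins  # meshgrid 'ij' + boolean mask preserves raster order


def select_training_patches(candidates: np.ndarray, rng_seed: int) -> np.ndarray:
    """Randomly reorder the candidate numbering and keep the first half.

    With n candidates, floor(n/2) origins are retained.  Deterministic under
    a fixed seed.
    """
    n = len(candidates)
    if n == 0:
        raise ValueError("no candidate patches (all-background labels?)")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    return np.asarray(candidates)[perm[: n // 2]]


def foreground_rich_origins(labels: LabelVolume, patch_size: int, n: int,
                            stride: int = DEFAULT_STRIDE) -> np.ndarray:
    """The n candidate origins whose windows contain the most foreground.

    Used by the reduced overfitting benchmark, where class imbalance would
    otherwise dominate a small iteration budget; the full pipeline uses the
    random-half selection instead.
    """
    cands = enumerate_candidate_patches(labels, patch_size, stride)
    if len(cands) == 0:
        raise ValueError("no candidate patches")
    fg = (labels.data > 0).astype(np.int64)
    c = fg
    for ax in range(3):
        c = np.cumsum(c, axis=ax)
    cp = np.pad(c, ((1, 0), (1, 0), (1, 0)))
    r = patch_size
    X, Y, Z = cands[:, 0], cands[:, 1], cands[:, 2]
    wsum = (cp[X + r, Y + r, Z + r] - cp[X, Y + r, Z + r] - cp[X + r, Y, Z + r]
            - cp[X + r, Y + r, Z] + cp[X, Y, Z + r] + cp[X, Y + r, Z]
            + cp[X + r, Y, Z] - cp[X, Y, Z])
    order = np.argsort(-wsum, kind="stable")
    return cands[order[:n]]


def extract_patchset(images: list[ImageVolume], labels: LabelVolume,
                     origins: np.ndarray, patch_size: int,
                     rng_seed: int = 0) -> PatchSet:
    """Cut aligned multi-modality image patches and label patches at the origins."""
    r = patch_size
    chans = np.stack([im.data for im in images])  # (C, D, H, W)
    n = len(origins)
    patches = np.empty((n, chans.shape[0], r, r, r), dtype=np.float32)
    labs = np.empty((n, r, r, r), dtype=labels.data.dtype)
    for i, (x, y, z) in enumerate(np.asarray(origins)):
        patches[i] = chans[:, x:x + r, y:y + r, z:z + r]
        labs[i] = labels.data[x:x + r, y:y + r, z:z + r]
    return PatchSet(patches, labs, np.asarray(origins, dtype=np.int64), rng_seed)
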