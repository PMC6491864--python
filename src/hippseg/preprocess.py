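"""Bounding-box localization, cropping, histogram matching, and flip augmentation.

The pipeline crops every volume to a box computed once over the training
labels (foreground extent plus a 32-voxel safety margin per direction), maps
intensities onto a reference subject's histogram, and doubles the training
set by left-right mirroring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .volumes import ImageVolume, LabelVolume

__all__ = [
    "BoundingBox3D",
    "compute_bounding_box",
    "crop",
    "uncrop",
    "histogram_match",
    "flip_lr",
]

DEFAULT_MARGIN = 32  # voxels added in each direction around the foreground


@dataclass(frozen=True)
class BoundingBox3D:
    """Per-axis inclusive [min, max] voxel indices."""

    mins: tuple[int, int, int]
    maxs: tuple[int, int, int]

    def __post_init__(self):
        if any(a > b for a, b in zip(self.mins, self.maxs)):
            raise ValueError(f"degenerate box: mins {self.mins} > maxs {self.maxs}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(b - a + 1 for a, b in zip(self.mins, self.maxs))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b + 1) for a, b in zip(self.mins, self.maxs))

    def to_dict(self) -> dict:
        return {"mins": list(self.mins), "maxs": list(self.maxs)}

    @classmethod
    def from_dict(cls, d) -> "BoundingBox3D":
        return cls(tuple(d["mins"]), tuple(d["maxs"]))


def compute_bounding_box(labels: list[LabelVolume], margin: int = DEFAULT_MARGIN) -> BoundingBox3D:
    """Foreground extent over all training label volumes, padded and clamped.

    Scans every volume for nonzero voxels, takes the per-axis union min/max,
    adds ``margin`` voxels in each direction, and clamps to the image extent.
    """
    if not labels:
        raise ValueError("no label volumes given")
    shape = labels[0].shape
    for lv in labels:
        if lv.shape != shape:
            raise ValueError("all label volumes must share one grid")
    mins = np.full(3, np.iinfo(np.int64).max)
    maxs = np.full(3, -1)
    for lv in labels:
        nz = np.nonzero(lv.data)
        if nz[0].size == 0:
            continue
        for ax in range(3):
            mins[ax] = min(mins[ax], nz[ax].min())
            maxs[ax] = max(maxs[ax], nz[ax].max())
    if maxs[0] < 0:
        raise ValueError("all label volumes are background; cannot locate foreground")
    mins = np.maximum(mins - margin, 0)
    maxs = np.minimum(maxs + margin, np.array(shape) - 1)
    return BoundingBox3D(tuple(int(v) for v in mins), tuple(int(v) for v in maxs))


def crop(volume, box: BoundingBox3D):
    """Crop an ImageVolume or LabelVolume to the box (same type out).

    The affine is translated so the cropped volume stays in the same physical
    frame; :func:`uncrop` restores predictions onto the native grid.
    """
    shape = volume.shape
    if any(b >= s for b, s in zip(box.maxs, shape)) or any(a < 0 for a in box.mins):
        raise ValueError(f"box {box} exceeds volume extent {shape}")
    data = volume.data[box.slices()]
    affine = volume.affine.copy()
    affine[:3, 3] = affine[:3, 3] + affine[:3, :3] @ np.array(box.mins)
    if isinstance(volume, LabelVolume):
        return LabelVolume(data.copy(), affine)
    return ImageVolume(data.copy(), affine, volume.modality)


def uncrop(prediction: LabelVolume, box: BoundingBox3D, native_shape, native_affine=None) -> LabelVolume:
    """Place a cropped-grid prediction back on the native grid (background elsewhere)."""
    if prediction.shape != box.shape:
        raise ValueError(f"prediction shape {prediction.shape} != box shape {box.shape}")
    full = np.zeros(native_shape, dtype=prediction.data.dtype)
    full[box.slices()] = prediction.data
    affine = prediction.affine.copy()
    if native_affine is not None:
        affine = np.asarray(native_affine, dtype=float)
    else:
        affine[:3, 3] = affine[:3, 3] - affine[:3, :3] @ np.array(box.mins)
    return LabelVolume(full, affine)


def histogram_match(moving: ImageVolume, reference: ImageVolume,
                    n_quantiles: int = 256) -> ImageVolume:
    """Monotone intensity remap of ``moving`` onto the reference's quantiles.

    The mapping interpolates between ``n_quantiles`` matched empirical
    quantile levels, so voxel rank order is preserved and the output quantile
    function approximates the reference's.  A constant moving image cannot be
    remapped; it is shifted to the reference median with a warning.
    """
    mov = moving.data
    ref = reference.data
    if np.ptp(ref) == 0:
        raise ValueError("reference image is constant; cannot match histograms")
    if np.ptp(mov) == 0:
        warnings.warn("moving image is constant; shifting to the reference median")
        out = np.full_like(mov, np.median(ref))
        return moving.with_data(out)
    q = np.linspace(0.0, 1.0, n_quantiles)
    mov_q = np.quantile(mov, q)
    ref_q = np.quantile(ref, q)
    # np.interp requires strictly usable xp; collapse duplicate moving quantiles
    keep = np.concatenate([[True], np.diff(mov_q) > 0])
    out = np.interp(mov, mov_q[keep], ref_q[keep])
    return moving.with_data(out.astype(np.float32))


def _lr_axis(affine: np.ndarray) -> int | None:
    """Array axis aligned with the subject's left-right direction, if identifiable."""
    try:
        codes = nib.orientations.aff2axcodes(affine)
    except Exception:
        return None
    for ax, code in enumerate(codes):
        if code in ("L", "R"):
            return ax
    return None


def flip_lr(image: ImageVolume, labels: LabelVolume,
            default_axis: int = 0) -> tuple[ImageVolume, LabelVolume]:
    """Mirror image and labels along the left-right axis (augmentation).

    The axis is read from the affine's orientation codes; when the
    orientation is not identifiable the configured default axis is used with
    a warning.  Class ids are side-agnostic, so labels are not renumbered.
    """
    ax = _lr_axis(image.affine)
    if ax is None:
        warnings.warn(f"orientation not identifiable; flipping along axis {default_axis}")
        ax = default_axis
    flipped_img = image.with_data(np.flip(image.data, axis=ax).copy())
    flipped_lab = labels.with_data(np.flip(labels.data, axis=ax).copy())
    return flipped_img, flipped_lab
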