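"""In-memory containers for 3D scalar and label volumes, plus NIfTI I/O.

A volume couples a 3D array with the affine that maps voxel indices to
physical (mm) coordinates.  Axis order is the array order (x, y, z) as stored
by the reader; all voxel coordinates in the package are 0-based array
indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "LabelVolume", "load_image", "load_labels"]


def _default_affine() -> np.ndarray:
    return np.eye(4)


@dataclass
class ImageVolume:
    """One 3D scalar grid with its voxel-to-world affine and a modality tag."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=_default_affine)
    modality: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm per array axis, from the affine column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return replace(self, data=np.asarray(data, dtype=np.float32))

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))


@dataclass
class LabelVolume:
    """3D integer grid over {0, ..., K-1}; 0 is background."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("label volume has non-integer values")
            self.data = rounded
        self.data = self.data.astype(np.int16)
        if self.data.min() < 0:
            raise ValueError("label volume has negative class ids")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def classes(self) -> np.ndarray:
        return np.unique(self.data)

    def with_data(self, data: np.ndarray) -> "LabelVolume":
        return replace(self, data=data)

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.int16), self.affine), str(path))


def load_image(path, modality: str = "") -> ImageVolume:
    img = nib.load(str(path))
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float32), img.affine, modality)


def load_labels(path) -> LabelVolume:
    img = nib.load(str(path))
    return LabelVolume(np.asarray(img.dataobj), img.affine)
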