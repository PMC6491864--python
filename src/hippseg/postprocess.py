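"""Connected-component filtering of predicted label maps.

Patch-trained networks only see local context, so look-alike structures far
from the hippocampus (e.g. caudate patches) come out as isolated foreground
islands.  Binarizing the prediction, labeling its connected components, and
keeping the two largest (left + right hippocampus) removes those islands
while leaving the subfield classes inside the kept components untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume

__all__ = ["ComponentTable", "connected_components", "keep_largest_components"]


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


@dataclass
class ComponentTable:
    """Connected components of the binarized foreground."""

    component_map: np.ndarray          # 0 = background, 1..n component ids
    sizes: dict[int, int]              # id -> voxel count
    bboxes: dict[int, tuple]           # id -> per-axis slices
    classes: dict[int, list[int]]      # id -> label classes present
    first_index: dict[int, int]        # id -> min linear (raster) voxel index

    @property
    def n_components(self) -> int:
        return len(self.sizes)


def connected_components(labels: LabelVolume, connectivity: int = 26) -> ComponentTable:
    """Components of the any-nonzero-class mask under 6 or 26 connectivity."""
    fg = labels.data > 0
    comp, n = ndimage.label(fg, structure=_structure(connectivity))
    sizes, bboxes, classes, first = {}, {}, {}, {}
    if n:
        flat = comp.ravel()
        nz = np.flatnonzero(flat)
        ids, first_pos = np.unique(flat[nz], return_index=True)
        counts = np.bincount(flat[nz])
        objs = ndimage.find_objects(comp)
        for cid, fpos in zip(ids, first_pos):
            cid = int(cid)
            sizes[cid] = int(counts[cid])
            bboxes[cid] = objs[cid - 1]
            classes[cid] = sorted(int(c) for c in np.unique(labels.data[comp == cid]))
            first[cid] = int(nz[fpos])
    return ComponentTable(comp, sizes, bboxes, classes, first)


def keep_largest_components(labels: LabelVolume, n_keep: int = 2,
                            connectivity: int = 26) -> LabelVolume:
    """Zero out foreground outside the n_keep largest connected components.

    Component size ties at the cutoff are broken deterministically in favour
    of the component whose minimum linear (raster) voxel index is smaller.
    Subfield classes inside kept components are unchanged.
    """
    table = connected_components(labels, connectivity)
    if table.n_components <= n_keep:
        return labels.with_data(labels.data.copy())
    order = sorted(table.sizes, key=lambda cid: (-table.sizes[cid], table.first_index[cid]))
    keep = set(order[:n_keep])
    mask = np.isin(table.component_map, list(keep))
    out = np.where(mask, labels.data, 0)
    return labels.with_data(out.astype(labels.data.dtype))
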