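"""Segmentation evaluation: Dice overlap and Average Symmetric Surface Distance.

Dice measures relative volumetric overlap, 2|A∩B| / (|A| + |B|).  ASSD is the
symmetric mean of nearest boundary-to-boundary distances,

    ASSD = ( mean_{e in ∂A} min_{f in ∂B} d(e, f)
           + mean_{e in ∂B} min_{f in ∂A} d(e, f) ) / 2,

with d the Euclidean distance between voxel centers.  Boundary voxels are
foreground voxels with at least one background 6-neighbor (volume edges count
as background).  Distances default to physical millimetres via the voxel
spacing; voxel units are available for data without a trusted header.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import LabelVolume

__all__ = ["dice", "assd", "boundary_mask", "evaluate", "aggregate", "MetricReport"]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks; NaN when both are empty (undefined)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return float("nan")
    return 2.0 * int((a & b).sum()) / (na + nb)


def boundary_mask(mask: np.ndarray) -> np.ndarray:
    """Voxels of the mask with >= 1 background 6-neighbor (edges are background)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0)
    return mask & ~interior


def assd(a: np.ndarray, b: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Average symmetric surface distance between two masks, in spacing units.

    Raises when either mask is empty: the distance is undefined and the class
    must be reported as missing rather than zero.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if not a.any() or not b.any():
        raise ValueError("ASSD undefined: a mask is empty")
    spacing = np.asarray(spacing, dtype=float)
    ba = boundary_mask(a)
    bb = boundary_mask(b)
    # distance_transform_edt(~X) gives, at each voxel, the distance to the
    # nearest voxel of X, sampled in physical units
    d_to_b = ndimage.distance_transform_edt(~bb, sampling=spacing)
    d_to_a = ndimage.distance_transform_edt(~ba, sampling=spacing)
    return float((d_to_b[ba].mean() + d_to_a[bb].mean()) / 2.0)


@dataclass
class MetricReport:
    """Per-class Dice/ASSD rows plus the unweighted class average."""

    table: pd.DataFrame  # columns: subject, class_id, class_name, dice, assd
    notes: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {"notes": self.notes,
                   "rows": self.table.to_dict(orient="records")}
        with open(path, "w") as f:
            json.dump(payload, f, indent=1, default=float)


def evaluate(pred: LabelVolume, truth: LabelVolume, spacing=None,
             class_names: dict[int, str] | None = None,
             subject: str = "", voxel_units: bool = False) -> MetricReport:
    """Per-class Dice and ASSD for one subject, plus the unweighted 'Average' row.

    Classes absent from both volumes are reported as missing (NaN) and
    excluded from the average; a class empty in exactly one volume has
    Dice 0 and missing ASSD.
    """
    if pred.shape != truth.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {truth.shape}")
    if spacing is None:
        spacing = (1.0, 1.0, 1.0) if voxel_units else tuple(truth.spacing)
    classes = sorted(set(np.unique(truth.data)) | set(np.unique(pred.data)))
    classes = [int(c) for c in classes if c != 0]
    if class_names:
        classes = sorted(set(classes) | set(int(c) for c in class_names if int(c) != 0))
    rows = []
    for c in classes:
        am = truth.data == c
        bm = pred.data == c
        d = dice(am, bm)
        try:
            s = assd(am, bm, spacing)
        except ValueError:
            s = float("nan")
        rows.append({"subject": subject, "class_id": c,
                     "class_name": (class_names or {}).get(c, str(c)),
                     "dice": d, "assd": s})
    df = pd.DataFrame(rows)
    avg = {"subject": subject, "class_id": -1, "class_name": "Average",
           "dice": df["dice"].mean(skipna=True) if len(df) else float("nan"),
           "assd": df["assd"].mean(skipna=True) if len(df) else float("nan")}
    df = pd.concat([df, pd.DataFrame([avg])], ignore_index=True)
    notes = {"units": "voxel" if voxel_units else "mm",
             "spacing": list(np.asarray(spacing, dtype=float)),
             "boundary": "6-neighbor background test, voxel-center distances"}
    return MetricReport(df, notes)


def aggregate(reports: list[MetricReport]) -> pd.DataFrame:
    """Mean and STD of Dice/ASSD over subjects, per class row."""
    big = pd.concat([r.table for r in reports], ignore_index=True)
    g = big.groupby(["class_id", "class_name"], sort=True)
    out = g.agg(dice_mean=("dice", "mean"), dice_std=("dice", "std"),
                assd_mean=("assd", "mean"), assd_std=("assd", "std"),
                n_subjects=("dice", "count")).reset_index()
    return out
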