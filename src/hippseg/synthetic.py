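"""Deterministic two-modality phantoms with paired hippocampus-like targets.

Each phantom carries two intensity channels over one label volume:

* two mirrored ellipsoids ("left"/"right" hippocampus) partitioned into K-1
  nested shell compartments standing in for subfields;
* modality 1 with distinct per-class mean intensities (T1w-like, high
  contrast) and modality 2 with a partially degenerate contrast profile
  (T2w-like), Gaussian noise, and a smooth multiplicative bias field;
* small isolated distractor structures far from both hippocampi that share a
  subfield intensity profile but are labeled background — the look-alike
  islands that connected-component post-processing must remove.

Everything derives from one seed, so cohorts are bitwise reproducible.  This
is pipeline-test plumbing, not an MRI simulator: no partial-volume effects,
no k-space artifacts, and the background is homogeneous tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volumes import ImageVolume, LabelVolume

__all__ = ["PhantomSpec", "PhantomSubject", "generate_phantom", "generate_cohort",
           "ADULT_PRESET"]


def _default_means_m1() -> tuple:
    # background + 5 subfields; well separated (high-contrast modality)
    return (25.0, 70.0, 95.0, 120.0, 145.0, 170.0)


def _default_means_m2() -> tuple:
    # partially degenerate: classes 1/2 and 3/4 share a mean
    return (30.0, 90.0, 90.0, 130.0, 130.0, 170.0)


@dataclass
class PhantomSpec:
    """Geometry and intensity model of one synthetic subject."""

    shape: tuple[int, int, int] = (72, 56, 48)
    spacing: tuple[float, float, float] = (0.8, 0.8, 0.8)
    num_classes: int = 6
    centers: tuple[tuple, tuple] = ((22.0, 28.0, 24.0), (50.0, 28.0, 24.0))
    semi_axes: tuple[float, float, float] = (9.0, 7.0, 6.0)
    means_m1: tuple = field(default_factory=_default_means_m1)
    means_m2: tuple = field(default_factory=_default_means_m2)
    noise_sd: float = 4.0
    bias_amplitude: float = 0.15
    num_distractors: int = 3
    distractor_radius_range: tuple[float, float] = (2.0, 3.5)
    distractor_min_distance: float = 10.0  # voxels from hippocampal foreground
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ValueError("need at least background + one foreground class")
        if len(self.means_m1) != self.num_classes or len(self.means_m2) != self.num_classes:
            raise ValueError("per-class mean lists must have num_classes entries")
        for center in self.centers:
            for c, a, s in zip(center, self.semi_axes, self.shape):
                if c - a < 0 or c + a > s - 1:
                    raise ValueError(
                        f"ellipsoid at {center} with semi-axes {self.semi_axes} "
                        f"exceeds grid {self.shape}")

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        return aff


@dataclass
class PhantomSubject:
    subject_id: str
    images: list[ImageVolume]
    labels: LabelVolume
    distractor_mask: np.ndarray
    spec: PhantomSpec


def _ellipsoid_rho(shape, center, axes) -> np.ndarray:
    """Normalized ellipsoidal radius (<= 1 inside) on the voxel grid."""
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    rho2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return np.sqrt(rho2)


def _shell_labels(rho: np.ndarray, n_shells: int) -> np.ndarray:
    """Partition the ellipsoid interior into equal-volume nested shells.

    Shell thresholds follow rho = (i / n)^(1/3); the innermost shell is
    class 1, the outermost class n_shells.
    """
    lab = np.zeros(rho.shape, dtype=np.int16)
    edges = (np.arange(1, n_shells + 1) / n_shells) ** (1.0 / 3.0)
    inner = 0.0
    for cls, outer in enumerate(edges, start=1):
        lab[(rho >= inner) & (rho < outer)] = cls
        inner = outer
    lab[rho == 1.0] = n_shells
    return lab


def _bias_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * (low-order polynomial)."""
    coords = [np.linspace(-1.0, 1.0, s) for s in shape]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    c = rng.uniform(-1.0, 1.0, size=7)
    poly = (c[0] * X + c[1] * Y + c[2] * Z + c[3] * X * Y + c[4] * Y * Z
            + c[5] * X * Z + c[6] * X * Y * Z)
    peak = np.abs(poly).max()
    if peak > 0:
        poly = poly / peak
    return 1.0 + amplitude * poly


def generate_phantom(spec: PhantomSpec) -> PhantomSubject:
    """One two-modality phantom with labels and a distractor mask (seeded)."""
    rng = np.random.default_rng(spec.rng_seed)
    n_shells = spec.num_classes - 1

    labels = np.zeros(spec.shape, dtype=np.int16)
    for center in spec.centers:
        rho = _ellipsoid_rho(spec.shape, center, spec.semi_axes)
        inside = rho < 1.0
        shells = _shell_labels(np.where(inside, rho, 2.0), n_shells)
        labels = np.where(inside, shells, labels)

    # distractors: small ellipsoids far from the hippocampal foreground,
    # carrying a subfield intensity profile but labeled background
    dist_to_fg = ndimage.distance_transform_edt(labels == 0)
    distractor_mask = np.zeros(spec.shape, dtype=bool)
    distractor_class = np.zeros(spec.shape, dtype=np.int16)
    placed = 0
    attempts = 0
    while placed < spec.num_distractors and attempts < 2000:
        attempts += 1
        r = rng.uniform(*spec.distractor_radius_range)
        margin = int(np.ceil(r)) + 1
        center = [rng.uniform(margin, s - 1 - margin) for s in spec.shape]
        idx = tuple(int(round(c)) for c in center)
        if dist_to_fg[idx] < spec.distractor_min_distance + r:
            continue
        rho = _ellipsoid_rho(spec.shape, center, (r, r, r))
        blob = rho < 1.0
        if (blob & (distractor_mask | (labels > 0))).any():
            continue
        # keep the blob itself clear of the min-distance shell around foreground
        if dist_to_fg[blob].min() < spec.distractor_min_distance:
            continue
        distractor_mask |= blob
        distractor_class[blob] = int(rng.integers(1, spec.num_classes))
        placed += 1
    if placed < spec.num_distractors:
        raise ValueError("could not place all distractors; geometry infeasible")

    images = []
    for modality, means in (("T1w", spec.means_m1), ("T2w", spec.means_m2)):
        means = np.asarray(means, dtype=np.float64)
        intensity = means[labels]
        intensity = np.where(distractor_mask, means[distractor_class], intensity)
        bias = _bias_field(spec.shape, spec.bias_amplitude, rng)
        noisy = intensity * bias + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        images.append(ImageVolume(noisy.astype(np.float32), spec.affine(), modality))

    return PhantomSubject("sub-00", images,
                          LabelVolume(labels, spec.affine()), distractor_mask, spec)


def generate_cohort(n_subjects: int, base_spec: PhantomSpec | None = None,
                    rng_seed: int = 0) -> list[PhantomSubject]:
    """n phantoms with bounded jitter in geometry and intensity (seed-derived).

    Centers shift by up to ±2 voxels, semi-axes scale by ±12%, and class mean
    intensities by ±5%, emulating inter-subject variation while keeping the
    class-intensity structure learnable across subjects.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    base = base_spec or PhantomSpec()
    seeds = np.random.SeedSequence(rng_seed).generate_state(2 * n_subjects) % (2 ** 31)
    subjects = []
    for i in range(n_subjects):
        jit = np.random.default_rng(int(seeds[2 * i]))
        centers = tuple(
            tuple(float(c + jit.uniform(-2.0, 2.0)) for c in center)
            for center in base.centers)
        axes = tuple(float(a * jit.uniform(0.88, 1.12)) for a in base.semi_axes)
        m1 = tuple(float(m * jit.uniform(0.95, 1.05)) for m in base.means_m1)
        m2 = tuple(float(m * jit.uniform(0.95, 1.05)) for m in base.means_m2)
        spec = replace(base, centers=centers, semi_axes=axes, means_m1=m1,
                       means_m2=m2, rng_seed=int(seeds[2 * i + 1]))
        subj = generate_phantom(spec)
        subj.subject_id = f"sub-{i + 1:02d}"
        subjects.append(subj)
    return subjects


def write_cohort(subjects: list[PhantomSubject], out_dir) -> dict:
    """Write NIfTI volumes plus a JSON manifest; returns the manifest."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"subjects": []}
    for s in subjects:
        entry = {"subject_id": s.subject_id, "rng_seed": int(s.spec.rng_seed),
                 "num_classes": int(s.spec.num_classes), "files": {}}
        for im in s.images:
            p = out / f"{s.subject_id}_{im.modality}.nii"
            im.save(p)
            entry["files"][im.modality] = p.name
        p = out / f"{s.subject_id}_labels.nii"
        s.labels.save(p)
        entry["files"]["labels"] = p.name
        dm = out / f"{s.subject_id}_distractors.nii"
        LabelVolume(s.distractor_mask.astype(np.int16), s.spec.affine()).save(dm)
        entry["files"]["distractors"] = dm.name
        manifest["subjects"].append(entry)
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return manifest


# 4-class preset mirroring an adult labeling (background + CA1-3, SUB, CA4/DG)
ADULT_PRESET = PhantomSpec(
    num_classes=4,
    means_m1=(25.0, 80.0, 120.0, 160.0),
    means_m2=(30.0, 95.0, 95.0, 150.0),
)
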