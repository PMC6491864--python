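"""Desk-scale benchmark runs shared by the test suite and the results script.

The reduced overfitting benchmark trains a small ResDUnet (base 4 channels,
16^3 patches) on the foreground-richest windows of two phantoms and tracks
the eval-mode Dice on those training patches — a learnability property of the
architecture + training loop, not a segmentation-accuracy claim.  The holdout
benchmark then applies the trained model to a third, unseen phantom through
the full sliding-window + post-processing + evaluation path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import preprocess as pp
from . import sampling as sp
from .inference import predict_volume
from .metrics import evaluate
from .networks import NetworkSpec, SegNet, build_network
from .postprocess import keep_largest_components
from .synthetic import PhantomSubject, generate_cohort
from .training import TrainConfig, TrainResult, patch_dice, train
from .volumes import LabelVolume

__all__ = ["OverfitRun", "run_overfit_benchmark", "run_holdout_benchmark",
           "INTENSITY_SCALE"]

INTENSITY_SCALE = 100.0  # phantom intensities are O(100); the nets see O(1)

REDUCED_SPEC = dict(variant="resdunet", in_channels=2, num_classes=6,
                    base_channels=4, dropout_rate=0.5)
PATCH_SIZE = 16
PATCHES_PER_SUBJECT = 32


@dataclass
class OverfitRun:
    network: SegNet
    train_dice: float
    iterations: int
    result: TrainResult
    patchset: sp.PatchSet
    cohort: list[PhantomSubject]
    box: pp.BoundingBox3D


def _cohort_patches(cohort, box, seed: int) -> sp.PatchSet:
    all_p, all_l, all_o = [], [], []
    for subj in cohort:
        images = [pp.crop(im, box) for im in subj.images]
        labels = pp.crop(subj.labels, box)
        origins = sp.foreground_rich_origins(labels, PATCH_SIZE, PATCHES_PER_SUBJECT)
        ps = sp.extract_patchset(images, labels, origins, PATCH_SIZE,
                                 rng_seed=sp.subject_seed(seed, subj.subject_id))
        all_p.append(ps.patches)
        all_l.append(ps.labels)
        all_o.append(ps.origins)
    pset = sp.PatchSet(np.concatenate(all_p), np.concatenate(all_l),
                       np.concatenate(all_o), seed)
    pset.patches /= INTENSITY_SCALE
    return pset


def run_overfit_benchmark(seed: int = 7, max_iterations: int = 2000,
                          target_dice: float = 0.90,
                          n_train: int = 2) -> OverfitRun:
    """Train the reduced ResDUnet on two phantoms until it overfits.

    Stops as soon as the eval-mode Dice over the training patches reaches
    ``target_dice`` (checked every 100 iterations) or at ``max_iterations``.
    Fully determined by ``seed``.
    """
    cohort = generate_cohort(n_train, rng_seed=seed)
    box = pp.compute_bounding_box([s.labels for s in cohort], margin=32)
    pset = _cohort_patches(cohort, box, seed)

    net = build_network(NetworkSpec(**REDUCED_SPEC), seed=seed)
    cfg = TrainConfig(batch_size=4, base_lr=2e-3, max_iterations=max_iterations,
                      rng_seed=seed, log_every=100)
    result = train(net, pset, cfg, stop_train_dice=target_dice, dice_every=100)
    final_dice = patch_dice(net, pset.patches, pset.labels)
    return OverfitRun(net, final_dice, result.final_iteration + 1, result,
                      pset, cohort, box)


def run_holdout_benchmark(run: OverfitRun, seed: int = 7) -> dict:
    """Segment an unseen phantom end-to-end with the benchmark network.

    Generates one extra jittered subject (same cohort stream, next index),
    crops with the training bounding box, runs sliding-window majority-vote
    prediction, keeps the two largest components, and evaluates Dice/ASSD
    against the phantom truth.  Also reports how much of the distractor
    structure survived post-processing.
    """
    n_train = len(run.cohort)
    extended = generate_cohort(n_train + 1, rng_seed=seed)
    subj = extended[n_train]
    images = [pp.crop(im, run.box) for im in subj.images]
    truth = pp.crop(subj.labels, run.box)
    distractors = pp.crop(
        LabelVolume(subj.distractor_mask.astype(np.int16), subj.spec.affine()),
        run.box).data.astype(bool)

    channels = np.stack([im.data for im in images]) / INTENSITY_SCALE
    raw, _ = predict_volume(run.network, channels, patch_size=PATCH_SIZE, stride=8)
    raw_vol = LabelVolume(raw, truth.affine)
    cleaned = keep_largest_components(raw_vol, n_keep=2, connectivity=26)

    report = evaluate(cleaned, truth, subject=subj.subject_id)
    avg = report.table[report.table["class_name"] == "Average"].iloc[0]

    raw_distractor_fg = int(((raw > 0) & distractors).sum())
    kept_distractor_fg = int(((cleaned.data > 0) & distractors).sum())
    removal = (100.0 * (raw_distractor_fg - kept_distractor_fg) / raw_distractor_fg
               if raw_distractor_fg else float("nan"))
    return {
        "subject": subj.subject_id,
        "mean_dice": float(avg["dice"]),
        "mean_assd_mm": float(avg["assd"]),
        "report": report,
        "raw_distractor_fg": raw_distractor_fg,
        "kept_distractor_fg": kept_distractor_fg,
        "distractor_removal_pct": removal,
        "n_voxels": int(np.prod(truth.shape)),
    }
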