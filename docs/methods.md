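# Methods

## Problem and model

The package segments hippocampal subfields (e.g. CA1, CA2/3, SUB, CA4/DG,
Uncus; K classes including background) in co-registered multi-modality 3D MR
volumes. A fully convolutional network estimates per-voxel posteriors
p_k(x|θ); the label map is L(x) = argmax_k p_k(x|θ).

All three variants share one skeleton operating on inputs whose spatial
dimensions are divisible by 8:

* contracting path: 3 × [two 3×3×3 convolutions → 2×2×2 max-pool stride 2],
  then two more 3×3×3 convolutions at the bottleneck;
* expanding path: 3 × [4×4×4 transposed convolution stride 2 (padding 1, so
  dimensions exactly double) → two 3×3×3 convolutions], then a 1×1×1
  convolution to K channels;
* every 3×3×3 convolution is zero-padded by rate·(k−1)/2 per side so
  stride-1 layers preserve spatial dimensions, and is followed by batch
  normalization and ReLU (conv → BN → ReLU order).

Skip fusion: levels 1 and 3 concatenate the contracting features directly
into the expanding path. The level-2 skip distinguishes the variants —
`unet3d` concatenates directly; `dunet` and `resdunet` route it through the
dilated dense block. `resdunet` additionally wraps every pair of path
convolutions in a post-activation residual unit (sum after the second BN,
ReLU after the sum; identity shortcut, 1×1×1 projection on channel
mismatch), so a unit whose convolution weights are zero reduces to
ReLU∘shortcut.

### Dilated dense block

The block applies L = 3 dilated 3×3×3 convolutions with rates (1, 2, 4);
layer i consumes the channel-concatenation of the block input and all
previous layer outputs and emits `growth` channels through
conv → BN → ReLU → dropout (rate 0.5). The block output concatenates the
input with every layer output: C input channels become C + L·growth. With
rates (1, 2, 4) the composite receptive field is 1 + Σ rate·(k−1) = 15
voxels per side at undiminished resolution, verified in the tests by an
input-perturbation support oracle.

The dilated convolution is defined by (F *_l h)(p) = Σ_{s+l·t=p} F(s)h(t)
with h supported on [−r, r]³; `hippseg.neural_ops` implements this sum
literally (float64) and is the oracle for the optimized im2col backend in
`hippseg.autodiff` (float32; machine-learning correlation convention —
mirror the kernel to translate).

### Channel schedule

Figure-level kernel counts are configuration, not contract: the default
schedule doubles from `base_channels` per resolution level (32/64/128/256),
with dense-block growth defaulting to the level-2 channel count. Ablation
comparisons only require the same schedule across variants; the parameter
counts then order resdunet ≥ dunet > unet3d (projections add nothing when
channel counts already match, hence ≥). Whether the dense block should end
in a transition convolution is left open by the architecture description;
none is used here — the raw concatenation enters the decoder.

## Training

Softmax (cross-entropy) loss over all patch voxels, computed through a
stable log-sum-exp; labels are the 0-based class ids used everywhere in the
package. Optimization is Adam with β₁ = 0.9 (the "momentum" of the schedule)
and L2 weight decay 5e-4 added to the raw gradient — the classic Caffe-style
coupling. The learning rate is base_lr·γ^⌊it/step⌋ with defaults 1e-4,
γ = 0.1, step 10 000; training stops at a fixed 60 000 iterations. Batches
are uniform random patch draws with replacement across subjects (the
sampling is otherwise fixed once per subject, not re-drawn per epoch).
Validation Dice is logged every `val_every` iterations and both the final
and best-validation checkpoints are kept, since a fixed-iteration stop and a
held-out validation set are both part of the protocol.

Weight initialization is He-normal (zero biases), seedable; dropout and
batch assembly run off seeded generators, so a fixed seed reproduces the
loss trajectory bitwise on a given platform (NumPy/BLAS summation order can
differ across platforms; within one environment runs are bitwise equal, and
the suite asserts this).

## Patch sampling

Candidates are all windows on a stride-2 lattice of the cropped volume that
contain at least one foreground voxel, numbered in raster order; the
numbering is randomly permuted and the first ⌊n/2⌋ are kept (odd n rounds
down). Patch size defaults to 24 (a 32 preset suits higher-resolution data).
Per-subject RNG seeds derive from the global seed and a CRC of the subject
id, so subject order does not perturb sampling. With the default phantom
geometry this yields on the order of a thousand training patches per
subject.

## Inference and post-processing

Sliding windows (24³ default, stride 8³) plus end-aligned windows guarantee
full coverage. Each window votes its own per-voxel argmax; the fused label
is the plurality. Ties break to the smallest class index, so background wins
any tie it is part of — deliberately conservative against false positives.
Probability averaging exists behind `fusion="average"` but is off by
default: the fusion rule is stated as majority voting over window
predictions, read literally as hard labels.

Patch-trained networks mislabel look-alike structures far from the
hippocampus (e.g. caudate) as subfields, producing isolated islands. The
post-processor labels connected components of the binarized foreground
(26-connectivity by default — "non-zero neighbors" is read inclusively; 6 is
a flag) and keeps the `n_keep = 2` largest (left + right hippocampus).
Size ties at the cutoff keep the component with the smaller minimum raster
index. Classes inside kept components are untouched; the filter only ever
removes foreground.

## Evaluation

Dice = 2|A∩B|/(|A|+|B|) per class; classes absent from both volumes are
reported missing (NaN) and excluded from the unweighted "Average" row rather
than scored 0. ASSD is the symmetric mean of nearest boundary-to-boundary
Euclidean distances between voxel centers. Discretization choices the
formula leaves open: a boundary voxel is a foreground voxel with at least
one background 6-neighbor (volume edges count as background), and distances
are measured between voxel centers in physical mm via the header spacing
(`voxel_units=True` for data without a trusted header — the reporting unit
is a choice the caller should record). Production uses Euclidean distance
transforms; the tests pin it to an O(|∂A|·|∂B|) brute-force double loop.

## Synthetic phantoms

Each phantom has two intensity channels over one label volume on a
72×56×48 grid at 0.8 mm isotropic spacing: two mirrored ellipsoids
(semi-axes 9×7×6 voxels) partitioned into K−1 equal-volume nested shells
standing in for subfields (innermost = class 1), plus 2–4-voxel-radius
distractor blobs at least 10 voxels from the hippocampal foreground that
carry a subfield intensity profile but background labels. Modality 1
separates all classes (means 25…170, step 25); modality 2 is partially
degenerate (classes 1/2 and 3/4 share means), so multi-modality input
carries real information. Intensities get additive Gaussian noise (SD 4) and
a smooth ±15% multiplicative polynomial bias field. Cohorts jitter centers
(±2 voxels), semi-axes (±12%) and class means (±5%) per subject from
seed-derived streams; regeneration under the same seed is bitwise identical.

What the phantom is *not*: an MRI simulator. There is no partial-volume
mixing, no k-space artifact, and the background is homogeneous, so passing
tests demonstrate pipeline correctness and learnability of the intended
statistical structure — not clinical segmentation accuracy. Subfield class
ids are treated as side-agnostic under left-right flipping, an explicit
assumption of the augmentation.

## Desk-scale benchmarks and problem sizes

The environment has no GPU deep-learning stack, so the networks run on an
in-repo NumPy autodiff backend, and the standard benchmarks are sized for a
single CPU:

* **Overfitting benchmark** (`hippseg.benchmarks.run_overfit_benchmark`): a
  reduced ResDUnet (base 4 channels, dropout 0.5) trains on the 32
  foreground-richest 16³ windows from each of two phantoms (64 patches,
  batch 4, Adam lr 2e-3) and stops when eval-mode Dice on those training
  patches reaches 0.90, capped at 2000 iterations. Foreground-rich windows
  are used because at a 2000-iteration budget the ~8% foreground fraction of
  the standard random-half selection leaves the minority classes barely
  touched by plain cross-entropy; class-weighted losses are deliberately out
  of scope, so the fixture shifts the sampling instead. Typical runs reach
  Dice ≈ 0.95 in 600–800 iterations.
* **Holdout benchmark** (`run_holdout_benchmark`): the trained reduced model
  segments a third, unseen jittered phantom through the full
  sliding-window → majority-vote → keep-2-components → Dice/ASSD path and
  reports the distractor-removal percentage alongside the scores.

Full-protocol numbers on real MRI cohorts (60 000 iterations, base 32
channels, 5-fold cross-validation) are outside what these benchmarks claim;
the defaults encode that protocol for users with the data and the patience.

## Known limitations

* CPU-only: a full-scale training run is possible in principle but slow;
  the backend is written for correctness (oracle-checked) first.
* Histogram matching uses a quantile-interpolation mapping with 256 levels;
  exact histogram equality is not attempted, idempotence holds to one bin.
* The bounding box computed on training subjects is applied unchanged to
  unseen subjects, assuming consistent spatial normalization upstream
  (affine registration and bias correction are expected to have been done).
* The reference subject for histogram matching is the first training subject
  by sorted id; the choice is recorded in the run config rather than
  optimized.
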