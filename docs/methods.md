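# Methods

## Problem setting

Perivascular spaces (PVSs) on axial T2-weighted MRI are CSF-bright, thin
(sub-millimetre to ~1 mm radius) tubular structures: linear in-plane when the
penetrating vessel parallels the scan plane, dot-like when it is
perpendicular. Segmentation is a heavily imbalanced small-object problem with
two systematic confounders — CSF-filled sulci at the brain surface and
lacunes (small infarct cavities, larger and blob-like) — plus a population of
faint PVSs at reduced contrast. The package segments 2D axial slices (the
through-plane resolution, 2 mm, is far coarser than the 0.69 mm in-plane
grid, so 3D context is unreliable) and reassembles per-slice predictions into
a 3D mask.

## Network

The model is a densely nested encoder–decoder: a triangular grid of nodes
X(i, j), i = resolution row (0 finest), j = position along the skip pathway,
i + j ≤ L − 1. Encoder nodes X(i, 0) consume a 2×2 max-pooled copy of the row
above; interior nodes X(i, j>0) consume the channel concatenation of all
same-row predecessors X(i, 0..j−1) plus the output of X(i+1, j−1) after
bilinear 2× upsampling and a 1×1 channel-matching convolution. Each node is
two (3×3 convolution → batch norm → ReLU) stages with an optional
squeeze-and-excite channel gate (global average pool → bottleneck MLP →
sigmoid). Each row's final node feeds a 1×1 convolution + sigmoid head at its
native scale, so a forward pass yields L probability maps (sides input/2^s).

Design choices where the architecture family leaves freedom:

* wiring follows the densely nested (UNet++-style) topology — the standard
  realisation of "dense nesting";
* attention is per-node channel attention and is toggleable, so its effect is
  measurable;
* downsampling is 2×2 max pooling and upsampling bilinear + 1×1 convolution,
  the common small-object-preserving pair;
* channel widths are `base_channels · growth^row` (default 32·2^i);
  normalisation is batch norm (suited to the batch size of 4).

The compute core is a reverse-mode autodiff engine written on numpy
(`perivox.nn`): convolution by im2col + GEMM, exact adjoints for pooling
(ties share gradient equally), interpolation (transposed interpolation
matrices) and batch norm. Gradients are verified against central finite
differences in the test suite.

## Deep supervision

Label pyramids use foreground-highlighting downsampling: repeated 2×2 *max*
pooling, so a coarse pixel is foreground iff its fine-scale block contains
any foreground (recursively). This is the reading under which one-voxel PVSs
survive to the deepest supervision scale; mean-pool soft labels are available
behind a policy flag for comparison. Each head is trained with soft dice,
`1 − (2Σpy + s)/(Σp + Σy + s)`, smoothing `s = 1.0` by default (exposed in
`LossConfig`); per-scale losses are combined by weighted mean, uniform
weights by default. As `s → 0`, `1 − loss` on binarised predictions converges
to the evaluation Dice; the suite checks agreement at `s = 1e−6` within 1e−4.

## Training protocol

Five-fold cross-validation with age-balanced folds: subjects are sorted by
age and dealt round-robin, which bounds each fold's mean-age deviation by the
average within-quintile age range. Per round, one fold is the test set, one
fold is drawn from the seeded stream as validation, the rest train.
Optimisation: mini-batch 4 slices, Adagrad, learning rate 0.05, soft-dice
deep supervision; no augmentation or schedule. The deployed model is the
checkpoint at a fixed selection epoch (`select_epoch`), reflecting a
convergence-based choice rather than per-fold validation selection;
best-validation selection is available as an alternative policy. Validation
folds are re-drawn per round from the seeded stream. Inference uses the
finest-scale head thresholded strictly above 0.5 (a probability exactly at
the threshold stays background, a fixed tie rule for bit-reproducibility);
head fusion by averaging is available behind a flag.

Preprocessing is per-volume z-scoring (the minimal scanner-scale remover;
configurable), and slices are zero-padded symmetrically to a side multiple of
2^(L−1) — padding rather than resizing, because resizing blurs one-voxel
structures. All slices, including foreground-free ones, are used by default
(`slice_sampling="foreground-only"` is available).

## Evaluation

DSC/SEN/PPV from voxel confusion counts, computed over whole volumes per
subject. Degenerate 0/0 denominators (both masks empty) score 1.0 and set a
flag, so aggregation can exclude them. Aggregation reports the arithmetic
mean and the *population* standard deviation (divisor N); this is the
convention under which the bundled reference table's printed Std row is
reproduced exactly (sample std is not). Rounding to 3 decimals happens only
at display. The comparison table flags the per-subject, per-metric maximum
across models (ties all flagged).

## Burden counting

The two standard rating slices are the basal-ganglia slice (anterior
commissure; in phantoms, the mid-ventricle slice analogue) and the centrum
semiovale slice, `ventricle_top + ceil(10 mm / slice_thickness)` (5 slices at
2 mm). A PVS count is the number of 2D connected components under
8-connectivity (a diagonal-touching thin PVS is one structure; 4-connectivity
is configurable), with an optional minimum-area filter that defaults to off.
Counting is per-slice, matching the visual-rating protocol, not 3D.
Agreement uses tie-corrected Spearman correlation (average ranks, then
Pearson), with an exact permutation p-value for n ≤ 8 and the t
approximation otherwise.

## Phantom generator

The phantom emulates the statistical structure of axial T2 data at voxel
0.69 × 0.69 × 2.0 mm: an ellipsoidal brain at tissue intensity on a dark
exterior; a central CSF-bright ventricle spanning the lower-middle slices
(its top slice anchors the CSO landmark; its mid slice stands in for the
anterior-commissure level); PVSs as capsules — in-plane tubes and
through-plane dots — at CSF-like intensity with centres kept
`min_separation_mm` apart, inside the brain and outside the ventricle.
Rasterisation always paints at least the voxel containing the capsule
centre, so sub-voxel-radius PVSs cannot vanish under the anisotropic grid
and requested counts survive. Confounders mirror the documented failure
modes: sulcus-like bright arcs hugging the brain boundary, lacune-like blobs
larger than any PVS radius, and a configurable fraction of PVSs rendered at
reduced contrast (intensity interpolated toward tissue). Noise is Rician by
default (magnitude of a complex Gaussian-perturbed signal, the MR magnitude
model; Gaussian available for analytic convenience) and is applied last.

Ground truth ships with each volume: the binary mask, per-slice 8-connected
component counts, the landmark slice indices and the structure table.
Subject k of a cohort uses derived seed `seed + k`, so cohorts extend without
reshuffling earlier subjects; ages are drawn uniformly over 42–79 years,
emulating an age-spread patient cohort.

What the phantom does *not* model: real anatomy (the brain is a schematic
ellipsoid), k-space/bias-field/partial-volume physics, T1 contrast, or
empirical PVS size/contrast distributions (none are published for cohorts of
this kind); its defaults are chosen for testability. Passing the phantom
end-to-end therefore shows that the implementation is correct and that the
learning problem behaves as expected (clean ≫ confounded), not that a
clinical-grade Dice would be reached on real patients.

## Reduced reference conditions

The full-scale protocol (20 patients, 320×320 slices, 1000 epochs) is a
GPU-scale workload on non-deposited data. The package's reference conditions
(`perivox.presets`) are sized for a single CPU: 5 phantom subjects on a
64 × 64 × 16 grid, 4 tubes + 6 dots per subject (radius 0.5–1.0 mm, tube
length 4–10 mm to fit the ~44 mm field of view), noise σ = 5 on a 100-unit
tissue / 200-unit CSF intensity scale; a depth-3 network with 8 base
channels; 20 training epochs with selection at epoch 20. Two regimes are
defined once and not tuned: *clean* (full contrast, no confounders) and
*confounded* (3 sulcus arcs, 2 lacunes, 40% faint PVSs). Under these
conditions the five-fold protocol reaches mean held-out Dice ≈ 0.98 (clean)
vs ≈ 0.78 (confounded).

## Numerical notes and limitations

* float32 forward/backward; Adagrad accumulators in float64; loss sums in
  float64 on the plain-array path.
* Batch-norm running statistics use momentum 0.1; eval mode uses running
  stats, so very short trainings can have poorly burned-in statistics.
* Max-pool gradient splits ties equally (deterministic); threshold ties at
  exactly 0.5 go to background.
* The constant-volume z-score is defined as all zeros (with a warning).
* Spearman is undefined for constant count vectors and is flagged rather
  than raised.
* Structure placement is rejection sampling with a bounded retry budget; an
  infeasible (count, separation) request raises a placement error naming the
  achieved count.
* Parameter parity with any externally published model of the same family
  cannot be asserted: exact node counts, widths and attention mechanisms of
  such models are not fully specified publicly.
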