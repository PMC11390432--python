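# perivox

Segmentation and burden counting of **perivascular spaces (PVSs)** on axial
T2-weighted 3T MR images.

PVSs (Virchow–Robin spaces) are thin fluid-filled channels around penetrating
brain vessels. On axial T2-weighted slices they appear as bright *linear*
structures when the vessel runs parallel to the imaging plane and as bright
*dots* when it runs through-plane, at a signal intensity close to CSF. Their
number and size track aging and several neurodegenerative diseases, so
radiology research needs reproducible, quantitative PVS maps — but PVSs are
tiny (often a voxel or two wide), easily confused with sulci and lacunes, and
tedious to count by hand.

`perivox` implements a complete, desk-reproducible version of a
multi-scale-supervised dense nested segmentation pipeline for this problem:

* **Densely nested encoder–decoder** (`perivox.network`): a triangular grid of
  convolutional nodes X(i, j) in which every interior node fuses all same-row
  predecessors with the upsampled output of the row below, giving each target
  size a U-shaped sub-network of matching depth. Per-node channel attention
  (squeeze-and-excite) is toggleable. One 1×1 + sigmoid head per row emits a
  probability pyramid. The network runs on the package's own numpy
  reverse-mode autodiff core (`perivox.nn`) — no GPU or deep-learning
  framework required.
* **Deep supervision with foreground-highlighting pyramids**
  (`perivox.supervision`): ground-truth masks are downsampled by 2×2
  *max*-pooling, so a coarse pixel is foreground iff any fine pixel of its
  block is — thin PVSs survive to the coarsest supervision scale. Each scale
  is trained with a soft dice loss

  `L = 1 − (2·Σ p·y + s) / (Σ p + Σ y + s)`,

  averaged over scales with configurable weights.
* **Training protocol** (`perivox.training`): five-fold, age-balanced
  (sort-and-deal) cross-validation; per round one test fold, one seeded
  validation fold, three training folds; mini-batches of 4 slices, Adagrad at
  learning rate 0.05, deployment of the fixed-epoch checkpoint (best-validation
  selection available). Inference thresholds the finest head at 0.5.
* **Evaluation** (`perivox.evaluation`): per-subject `DSC = 2TP/(2TP+FP+FN)`,
  `SEN = TP/(TP+FN)`, `PPV = TP/(TP+FP)`; Mean and population-Std aggregation
  and a best-score-flagged comparison table. A reference table of per-subject
  scores for five published models (IAANet, TriSegNet, U-Net, nnU-Net,
  MfNS_De) on a 20-patient cohort is bundled.
* **Burden counting** (`perivox.burden`): connected-component PVS counts on
  the two standard rating slices — basal ganglia (anterior-commissure slice)
  and centrum semiovale (1 cm above the uppermost ventricle slice) — and
  tie-corrected Spearman agreement between automated and rater counts.
* **Phantom generator** (`perivox.phantom`): seeded synthetic T2-like volumes
  (ellipsoidal brain, CSF-bright ventricle, capsule-shaped PVS tubes and dots,
  sulcus- and lacune-like confounders, faint PVSs, Rician noise) with exact
  ground-truth masks, per-slice counts and landmark slices, so the whole
  pipeline is testable without any data download.

## Worked example

```bash
perivox simulate --out data/ --n-subjects 5 --seed 1
perivox crossval --data data/ --out run/ --seed 1 --config config.yaml
```

or in Python, using the package's reduced reference conditions (5 phantom
subjects on a 64×64×16 grid, depth-3 network, 20 epochs — a few minutes on
one CPU):

```python
from perivox.presets import reduced_crossval
from perivox.evaluation import records_frame, aggregate

res = reduced_crossval(seed=1, confounders=False)
print(aggregate(res["records"]).round(3))
```

prints

```
                      DSC    SEN  PPV
model         row
nested-segnet Mean  0.978  0.959  1.0
              Std   0.022  0.042  0.0
```

i.e. on clean high-contrast phantoms the cross-validated network recovers the
PVS masks almost perfectly (mean held-out Dice 0.978 over the 5 subjects).
Re-running with `confounders=True` (sulcus arcs, lacune blobs, 40% faint
PVSs) drops the mean Dice to ≈ 0.78 — the same failure modes reported for PVS
segmentation on real MRI, reproduced in miniature.

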