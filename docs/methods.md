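# Methods

`ventrivol` implements an automatic ventricular-volumetry pipeline for 3D
cranial ultrasound of preterm infants with post-haemorrhagic ventricular
dilatation (PHVD), together with the statistics used to validate such a
method against manual reference volumetry. This note documents the models,
the parameters that matter, the numerical choices, and what the synthetic
phantoms do and do not demonstrate.

## Pipeline overview

1. **Volume I/O** — NRRD volumes with isotropic voxel spacing, 8-bit
   intensities. Axis convention: axis 0 = sagittal index, axis 1 = axial,
   axis 2 = coronal; a sagittal slice is `(axial, coronal)`.
2. **Pre-labelling** — a three-step threshold bootstrap (3D median filter,
   iterative global threshold with geometric blob classification, 3-class
   map) that produces a starting segmentation proposal.
3. **2.5D dataset** — thickened slices: each training image is a
   200×200×3 stack of sagittal slices (s−1, s, s+1) in the R/G/B
   channels; the label is the pixelwise OR of the three ventricle masks,
   rebalanced into ventricle / background (exactly-black pixels) / brain.
4. **Slice segmenter** — an encoder–decoder convolutional network trained
   with median-frequency class-weighted cross-entropy, SGD (lr 0.01,
   momentum 0.9, weight decay 5e-4), batch size 2, 10 epochs, per-epoch
   reshuffle without replacement, optional affine augmentation
   (translation ±20 px, rotation ±30°, scale 0.8–1.2, shear ±20°).
5. **Volumetry** — per-slice predictions are unpadded/unscaled back to
   native geometry, stacked into a binary volume; 26-connected blobs are
   counted and multiplied by the calibrated voxel volume (cm³); sides are
   assigned by blob centroid relative to the mid-sagittal plane, with
   straddling blobs split by the plane.
6. **Agreement** — ICC(A,k) (two-way random effects, absolute agreement,
   average measures, k = 2 methods), Passing–Bablok regression, Lin's CCC,
   and Bland–Altman limits of agreement with their confidence intervals.

## Synthetic phantoms

Clinical 3D ultrasound is not redistributable, so every stage is exercised
on parametric head phantoms: an ellipsoidal bright cranial shell, a
speckle-textured parenchyma, two mirrored bent-ellipsoid dark cavities
(ventricles), an optional spherical periventricular cyst, and an
exactly-zero exterior. Speckle is multiplicative log-normal noise (scale
`speckle_sigma`, default 0.05), applied to the mean-intensity map (cavity
30, brain 120, shell 220) and clipped to [0, 255]; interior voxels are kept
≥ 1 so that "exactly black" remains an exterior-only property. Temporal
series scale cavity volumes by a per-day multiplicative factor (semi-axes
scale by its cube root), optionally switching to a shrink factor after an
intervention day, emulating PHVD progression and post-drainage decline.

Default geometry is a 64×96×96 grid at 0.5 mm pitch with per-side cavity
semi-axes (5, 12, 7) mm (≈ 1.76 cm³ per side at day 0, a clearly dilated
system at this scale). The semi-axes deliberately leave headroom inside
the brain ellipsoid so multi-day growth schedules are not distorted by
clipping; the generator warns if more than 2% of a cavity is clipped.

What the phantoms do **not** emulate: acoustic physics (attenuation,
shadowing, fan-shaped footprints), anatomical ventricle shape beyond
tortuosity, wall irregularity (modelled separately by `degrade_wall`,
which raises a chosen fraction of cavity-boundary voxels to parenchymal
intensity), or inter-observer label noise. Tests passing on phantoms
demonstrate the pipeline's internal consistency and its behaviour under
controlled contrast/noise — not clinical accuracy.

## Pre-labelling: threshold search and stopping rule

Candidate voxels at threshold `t` are `0 < v < t` — exactly-zero voxels
lie outside the acquisition footprint and are background by definition.
The scan visits every integer `t` up to the maximum intensity present
(steps with an unchanged sub-threshold histogram are skipped; the result
is identical). At each step, 26-connected blobs are classified by
volume (default 0.5–80 cm³), elongation (ratio of principal extents,
default ≤ 15) and centrality (centroid distance from the grid centre as a
fraction of the half-diagonal, default ≤ 0.6); these defaults are
package choices, exposed in `BlobCriteria`.

The accepted-voxel count over `t` shows a characteristic shape: a fill-in
ramp, a long plateau once the cavity is fully submerged, then a growth
resumption as the dark region percolates into the parenchyma. Measured on
default phantoms, the percolation grows ≤ 1.4× per integer step, so a
jump test between consecutive steps cannot see it; instead, a step is
*quiescent* when the count grew ≤ 0.5% since the previous distinct step,
and a leak is declared when the count exceeds `leak_factor` (default 2)
times the latest quiescent count. The returned threshold/label is that
quiescent step. Two guards reject non-segmentations: a quiescent
reference younger than 5 integer thresholds at leak time is a transient
percolation artefact (pure-noise volumes), and a "cavity" covering more
than half of the non-zero voxels is a flood. On noise-free two-mode
volumes the rule reduces to "largest threshold before the jump". The
known failure mode matches the method's clinical reputation: with heavy
speckle or degraded walls it underestimates, and the result carries an
`empty` flag rather than raising.

## Class weighting

Median-frequency balancing: `p_c` is the pixel count of class `c` divided
by the total pixels of the images in which `c` appears at least once;
`m_p` is the median of the `p_c`; the loss weight is `α_c = m_p / p_c`.
The weighted loss is `Σ w·nll / Σ w`, which reduces exactly to plain mean
cross-entropy at `α ≡ 1`. Weights are computed on the training split only.

## The slice segmenter

The network is a symmetric encoder–decoder built from 3×3 convolutions,
2×2 max-pooling, and nearest-neighbour upsampling, with channel reduction
applied before each upsampling step so the full-resolution convolutions
stay narrow. Two sizes exist: `tiny` (8→16→32 channels, two pooling
stages — the size used for all tests and experiments in this package,
trained from scratch) and `vgg16` (a VGG16-shaped encoder truncated to
three pooling stages, constructable and loadable from a pretrained
checkpoint via `pretrained_init`, but far too large to train on a
laptop-class CPU). Implementation is pure numpy (im2col convolutions with
the input gradient computed as a flipped-kernel correlation), float32,
single-threaded deterministic: identical seeds give bit-identical weights
and predictions.

Because labels are OR-compressed over three consecutive slices, the
learnt masks are slightly dilated sagittally; reconstructed volumes
therefore carry a small systematic overestimate relative to the voxel
ground truth. This is a property of the 2.5D labelling scheme, visible as
a positive Bland–Altman bias in the agreement stage.

## Evaluation conventions

Per-slice ventricle IoU skips slices where both truth and prediction are
empty (undefined ratio) and scores 0 where only the truth is empty; DSC
is computed from per-slice pixel counts, not converted from IoU. 3D Dice
is `2|A∩B|/(|A|+|B|)` with both-empty defined as 1.0. `dsc_from_iou`
implements the algebraic identity `DSC = 2·IoU/(1+IoU)`.

## Agreement statistics

* **ICC**: two-way random-effects ANOVA on the n×2 table;
  absolute-agreement average-measures form
  `(MSR − MSE)/(MSR + (MSC − MSE)/n)`; CI by the McGraw & Wong
  F-distribution construction on the single-measures form, carried up by
  Spearman–Brown. Cross-checked against pingouin's ICC(A,k) in tests.
* **Passing–Bablok**: slope = shifted median of all pairwise slopes
  (undefined and exactly −1 slopes excluded, offset K = #{S < −1});
  intercept = median(y − Bx); CIs from the normal approximation to the
  slope-median rank, intercept CI from the slope CI endpoints. A Kendall
  τ below 0.3 sets a warning flag (the procedure assumes correlated
  arms). Note the estimator models error in *both* variables: simulations
  with noise on one arm only recover a slope inflated by the classic
  errors-in-variables factor, so recovery tests place measurement error
  on both arms.
* **Lin's CCC**: `2s_xy / (s_x² + s_y² + (x̄−ȳ)²)` with biased (1/n)
  moments.
* **Bland–Altman**: differences d = y − x; bias = mean, SD with n−1;
  LoA = bias ± 1.96·SD (1.96 exactly, not a t quantile); each limit's
  standard error is `SD·√(3/n)` and its CI is limit ± 1.96·SE; tallies
  count differences strictly outside the limits.

## Problem sizes and defaults

The packaged experiments use a 4-day growth trajectory (factor 1.15/day)
of default phantoms, giving ≈ 190–230 thickened slices after the
ROI restriction, split 75:25 per-slice; the segmenter trains 10 epochs.
Stochastic claims (slice IoU, 3D Dice) are medians over three seeds.
Per-slice splitting follows the corpus-count convention; per-volume
grouping is available (`group_key`) because per-slice splits leak
near-duplicate neighbouring slices between train and test — a known
fidelity/rigour trade-off, documented rather than hidden.

## Degenerate inputs and tie-breaks

Anisotropic NRRD spacing (> 1% relative) is rejected. Oversized slices
are uniformly downscaled by `max(H, W)/200` (linear for intensities,
nearest for labels) before centring on the zero canvas; padding offsets
and the scale factor are recorded so the mapping inverts exactly.
Median filters replicate edges so borders are not darkened (zero-padding
would interact with the exactly-black ⇒ background rule). In
`rebalance_classes` the precedence is ventricle > background > brain, so
a ventricle annotation on an exactly-black pixel survives. Blobs with a
single voxel have elongation 1 by convention. `measure_volumes` accepts
a configurable midline; the default is the mid-sagittal grid plane.

## Known limitations

* The phantom's geometric simplicity makes segmentation easier than
  clinical data; reported IoU/Dice on phantoms are upper bounds.
* The pre-labeller's plateau detection assumes a bimodal-ish intensity
  structure; with speckle σ ≳ 0.1 it underestimates or returns empty.
* The `vgg16`-sized network and pretrained initialisation are hooks, not
  validated paths.
* Sagittal OR-compression biases volumes upward by roughly one voxel
  pitch of sagittal dilation; a deconvolution of this bias is not
  attempted.
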