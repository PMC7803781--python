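# ventrivol

Automatic ventricular volumetry for 3D cranial ultrasound of preterm
infants with post-haemorrhagic ventricular dilatation (PHVD).

Serial cranial ultrasound is how neonatologists monitor ventricular
dilatation after germinal-matrix/intraventricular haemorrhage, but manual
volumetry (rotational contouring of each ventricle in 12 planes) takes
~20 minutes per acquisition and fails outright on complex or poorly
delineated ventricles. `ventrivol` implements the full automatic
alternative — from raw NRRD volume to calibrated per-side ventricular
volumes — plus the method-comparison statistics needed to validate it
against a manual reference, and a synthetic phantom generator so the
whole pipeline is testable without clinical data.

## What it does

* **2.5D segmentation**: each sagittal plane *s* becomes a 200×200×3
  *thickened slice* (channels = slices *s−1, s, s+1*); labels are the
  pixelwise OR of the three ventricle masks, rebalanced into three
  classes (ventricle / background = exactly-black pixels / brain). A
  numpy encoder–decoder CNN is trained with median-frequency weighted
  cross-entropy (α_c = m_p/p_c), SGD (lr 0.01, momentum 0.9, weight
  decay 5·10⁻⁴), batch size 2, 10 epochs.
* **Volumetry**: predictions are mapped back to native geometry, stacked
  into a binary volume; each 26-connected blob's volume is
  `voxels × voxel_size³` (cm³), with left/right assignment by centroid
  against the mid-sagittal plane. Overlap is quantified by the 3D Dice
  coefficient, DSC = 2·IoU/(1+IoU).
* **Threshold pre-labelling**: the bootstrap labeller — 3D median
  filter, iterative global threshold over the volume histogram with
  geometric blob classification at every step, leak detection — used to
  produce starting segmentation proposals.
* **Agreement statistics**: ICC(A,k) (two-way random effects, absolute
  agreement, average measures), Passing–Bablok regression (slope B =
  shifted median of pairwise slopes; intercept A), Lin's concordance
  correlation, and Bland–Altman limits of agreement
  bias ± 1.96·SD with CIs from SE = SD·√(3/n).
* **Phantoms**: speckled head phantoms with exact ground-truth cavity
  masks and day-over-day growth/shrink trajectories emulating PHVD and
  post-drainage decline.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

```python
import ventrivol as vv

# a 4-day dilatation trajectory of synthetic phantoms (growth 15 %/day)
series = vv.generate_trajectory(vv.TrajectorySpec(n_days=4, growth_per_day=1.15))
vols  = [v for v, _ in series]
labs  = [l for _, l in series]
rois  = [vv.auto_roi(l) for l in labs]

# threshold pre-labelling vs exact truth
pre = vv.prelabel_volume(vols[0])
print(f"pre-label DSC {vv.dsc_3d(pre.label, labs[0]):.3f}")

# train the slice segmenter and segment day 0
ds = vv.build_dataset(vols, labs, rois, seed=0)
model, log = vv.train(ds, vv.TrainConfig(epochs=10, seed=0))
seg, meas, metrics = vv.segment_volume(model, vols[0], rois[0], reference=labs[0])
print(f"slice IoU {log[-1].test_ventricle_iou:.3f}  3D DSC {metrics.dsc_3d:.3f}")
for m in meas:
    print(f"{m.side:>5}: {m.volume_cm3:.2f} cm3  (truth "
          f"{labs[0].meta['true_volume_cm3'][m.side]:.2f})")
```

Representative output (seed 0):

```
pre-label DSC 0.995
slice IoU 0.946  3D DSC 0.907
 left: 2.12 cm3  (truth 1.76)
right: 2.12 cm3  (truth 1.76)
total: 4.24 cm3  (truth 3.52)
```

The pre-labeller recovers the clean cavity almost exactly; the CNN
segments held-out slices at IoU ≈ 0.95 and rebuilds the 3D cavity at
Dice ≈ 0.91. The automatic volumes run high — the
OR-compression of labels over three consecutive slices teaches the
network slightly sagittally-dilated masks, which surfaces downstream as a
positive Bland–Altman bias between the automatic and reference methods.

The same pipeline is scriptable from the shell:

```bash
ventrivol run pipeline.yaml --seed 7 --out run/
# stages: simulate -> prelabel -> build-dataset -> train -> segment -> agree
```

producing `truth.csv`, `model.npz`, `volumes.csv`, `report.json` and a
`manifest.json` of SHA-256 hashes; re-running with the same config and
seed reproduces the outputs bit-exactly.

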