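# attrscint

Automated detection and Perugini scoring of cardiac transthyretin amyloidosis
(ATTR-CM) on total-body planar bone scintigraphy.

Bone-avid tracers (99mTc-MDP/DPD/HDP/PYP) accumulate in amyloid-infiltrated
myocardium; the Perugini scale grades that cardiac uptake from 0 (none) to 3
(myocardium brighter than bone). Reading total-body studies for ATTR-CM is
expert work with real inter-observer variability, and most bone scans are
acquired for oncologic or orthopedic indications, where incidental cardiac
uptake is easily missed. `attrscint` implements a fully automated reading
pipeline for researchers in nuclear-medicine image analysis:

1. **simulate** — a 3D digital-phantom generator (torso, ribs/spine, kidneys,
   bladder, heart with a myocardial LV shell, Poisson counting noise) with a
   controllable cardiac-uptake fraction standing in for Perugini grades;
2. **project** — pseudo-planar images by summing SPECT-like volumes along the
   anterior–posterior axis (count-conserving; parallel-hole collimation has no
   magnification), with union-projected anatomy masks;
3. **augment** — "explainable" uptake augmentation: graded synthetic uptake
   (5–150 % of the image's 99th percentile, 5 % steps) injected inside the LV
   mask, expanding each normal case into 29 images so segmenters stay robust
   across the whole severity range;
4. **segment / crop** — trainable 2D segmenters for LV, whole heart and
   ribcage (sliding-window inference, 50 % overlap) driving bounding-box crops
   with 70 / 50 / 1 mm physical margins;
5. **classify** — binary CNNs for the detection task (grade 0 vs 1–3) and the
   severity task (0–1 vs 2–3), trained patient-wise in 3 folds on three views
   (anterior, posterior, summation) × three crops — 27 models per task;
6. **ensemble / evaluate** — two-stage probability averaging (folds within
   each crop/view group, then groups) with argmax decisions, plus a full
   metric suite: F1, sensitivity, specificity, precision, accuracy, balanced
   accuracy `BAC = (sens + spec)/2`, Mann–Whitney AUC and ROC;
7. **explain** — GradCAM and occlusion-sensitivity saliency maps with
   thresholded overlays.

The two-stage ensemble weighs model *certainty*, not votes: members
(0.45, 0.55), (0.95, 0.05), (0.48, 0.52) vote 2–1 for class 1, yet their
average (0.627, 0.373) decides class 0 because the dissenting model is far
more confident.

All networks are small CNNs implemented on numpy with manual backpropagation
(gradient-checked in the test suite), so the whole pipeline trains and runs on
a single CPU with no GPU framework. See `docs/methods.md` for models,
parameters and limitations.

## Worked example

```python
from attrscint.datatypes import PhantomSpec
from attrscint.phantom import generate_phantom
from attrscint.projection import project_volume, project_mask
from attrscint.augment import UptakeLevelScheme, expand_case

vol, anat = generate_phantom(PhantomSpec(grid_shape=(96, 96, 96), seed=1))
base = project_volume(vol)                      # pseudo-planar image
lv2d = project_mask(anat["lv"])                 # projected LV mask
cases = expand_case(base, lv2d, UptakeLevelScheme(), seed=0)
print(len(cases), cases[0].fraction, cases[-1].fraction)
```

prints

```
29 0.0 1.4000000000000001
```

— the original grade-0 image plus 28 uptake levels from 5 % to 140 % of the
image's own 99th percentile; 85 such cases yield 2465 training images.

Running the full pipeline on a 60-patient synthetic cohort with balanced
grades (this is exactly what the end-to-end acceptance test does):

```python
from attrscint.pipeline import run_end_to_end

reports = run_end_to_end(n_patients=60, seed=0)
for task, r in reports.items():
    print(task, round(r.auc, 3), round(r.bac, 3), round(r.accuracy, 3))
```

prints

```
detection 1.0 0.933 0.9
severity 1.0 0.984 0.983
```

— held-out AUC / balanced accuracy / accuracy per task, where every case is
scored only by the nine (crop × view) models of the fold that never trained
on that patient. Expect roughly ten minutes on one CPU core.

There is also a stage-per-subcommand CLI operating on a YAML config
(`attrscint simulate | project | augment | train-seg | segment | crop |
train-cls | predict | ensemble | evaluate | explain`); every stage writes a
JSON manifest (inputs, config hash, seed, version) next to its outputs so any
artifact can be reproduced exactly. `attrscint --help` lists the stages.

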