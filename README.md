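# ctavg — average-brain CT templates for small-hemorrhage detection

Small traumatic intracranial hemorrhages (< 10 mm) are easy to miss on
noncontrast head CT, yet missing them can cost a patient the window for
intervention. `ctavg` implements a simple, robust screening idea: build an
"average brain" CT from lesion-free control scans, deform that template
onto each patient's scan, and subtract. Healthy tissue cancels; anything
hyperdense that is *not* in the average — fresh blood at > 60 HU against
brain parenchyma and CSF at 3–40 HU — stands out in the difference map.

The package is aimed at medical-image-analysis researchers who want a
complete, reproducible reference pipeline: a from-scratch deformable
registration stack, template construction, subtraction-based candidate
detection with quantitative scoring, and a seeded synthetic-phantom
cohort generator that replaces patient data in all tests.

## Method at a glance

* **Registration** (`ctavg.registration`) — rigid → affine → cubic
  B-spline free-form deformation (20 mm control-point spacing), optimized
  by adaptive stochastic gradient descent over a 4-level Gaussian scale
  space (σ = 4/2/1/0.5 voxels). The cost is −MI, mutual information from a
  32×32 joint histogram with cubic B-spline Parzen windows, estimated from
  3000 random coordinates per iteration (≥ 150 must align, or the stage
  aborts). Analytic gradients throughout; deterministic under a seed.
* **Template** (`ctavg.template`) — every control (including the chosen
  reference) is registered to the reference and the template is the
  voxelwise arithmetic mean:  T(x) = (1/N) Σᵢ Mᵢ(φᵢ(x)).
* **Detection** (`ctavg.detector`) — with subject S and deformed template
  T∘φ, the map D = S − T∘φ is thresholded: candidates are 26-connected
  components with D > 25 HU and S > 60 HU, outside dilated bone, larger
  than 2 mm sphere-equivalent diameter. Overlays render |D| through a
  blue→green→yellow lookup table.
* **Evaluation** (`ctavg.evaluation`) — greedy one-to-one centroid
  matching at 5 mm; pooled sensitivity TP/(TP+FN).
* **Phantoms** (`ctavg.phantom`) — seeded synthetic heads (skull shell,
  white/gray matter, ventricles, per-subject affine + smooth-field
  deformation, CT noise) with spherical 3–10 mm, 70–80 HU lesions painted
  at exactly known positions.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

Detect a single synthetic 6 mm hemorrhage by subtracting the lesion-free
version of the same head (the pure subtraction path; the full pipeline
additionally registers a population template onto the subject):

```python
import numpy as np
from ctavg import phantom, detector, volumes

spec = phantom.PhantomSpec().fast()          # 2 mm phantoms
lesion = phantom.LesionSpec(diameter_mm=6.0, hu=72.0)
subject_raw, truths, _ = phantom.generate_tbi(spec, [lesion], seed=5)
control_raw, _ = phantom.generate_control(spec, seed=5)   # same head, no lesion

subject, mask = volumes.preprocess(subject_raw, slice_mm=2.0)
reference, _ = volumes.preprocess(control_raw, slice_mm=2.0)

diff = detector.subtract(subject, reference)
cands = detector.extract_candidates(diff, subject, mask)
print(f"ground truth: d={truths[0].diameter_mm:.1f} mm at {np.round(truths[0].centroid, 1)}")
for c in cands:
    print(f"candidate: d={c.diameter_mm:.1f} mm, peak diff {c.peak_diff:.1f} HU, "
          f"mean {c.mean_hu:.1f} HU at {np.round(c.centroid, 1)}")
```

prints

```
ground truth: d=6.0 mm at [ 63.1 106.6 120.1]
candidate: d=7.4 mm, peak diff 37.0 HU, mean 69.9 HU at [ 63.1 106.4 120.1]
```

— exactly one candidate, centered 0.2 mm from the inserted lesion: the
72 HU sphere leaves a ~37 HU residual over the 35 HU white matter, and its
mean subject density (69.9 HU) clears the blood floor. The sphere-
equivalent diameter (7.4 mm) slightly exceeds the nominal 6 mm because the
one-voxel feather ring also passes the thresholds.

## Command line

Each pipeline stage is a subcommand; `run` chains them end to end.

```bash
ctavg phantom --controls 30 --tbi-plan 12,2,11,16,3,14,2,1,6 --seed 42 --fast -o data/
ctavg preprocess data/controls/ctrl_00.nii.gz prep.nii.gz --slice-mm 2.0
ctavg register FIXED.nii.gz MOVING.nii.gz -o chain.txt --stages rigid,affine,bspline --seed 7
ctavg build-template prep/*.nii.gz --fixed 0 -o template.nii.gz --seed 17
ctavg detect SUBJECT.nii.gz --template template.nii.gz -o out/ --diff-hu 25 --blood-hu 60
ctavg evaluate --pred out/*/candidates.tsv --truth data/cohort_truth.tsv --max-dist 5
ctavg run --seed 42 --fast --out study_out/
ctavg dump-defaults > run.yaml       # inspect/edit every default
```

`run` writes the phantom cohort, the template (NIfTI + provenance JSON +
per-control transform-chain files), per-subject difference volumes and
candidate tables, `cohort_result.json` (pooled TP/FP/FN and sensitivity)
and a manifest with the effective configuration, seeds and stage timings.
Reruns with the same seed reproduce `cohort_result.json` byte for byte.

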