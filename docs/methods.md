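# Methods

`ctavg` detects small (< 10 mm) hyperdense intracranial lesions on
noncontrast head CT by comparing each scan against a computed "average
brain": a voxelwise-mean template built from lesion-free control scans
after multi-stage deformable registration. This note documents the model,
the numerical choices, and what the synthetic validation does and does not
show.

## Image model and preprocessing

All volumes are 3-D Hounsfield-unit grids with axis order (axial slice,
row, column), strictly positive per-axis spacing and an axis-aligned
physical frame (`p = origin + index · spacing`). Oblique NIfTI
orientations are rejected rather than resliced; clinical axial head CT fits
this restriction and it keeps every transform testable in closed form.

Preprocessing has three steps, in order: (1) axial cropping to the
contiguous slice range containing bone (default threshold 300 HU) — slices
above the vertex and below the skull base carry no intracranial signal;
(2) axial resampling to a uniform slice thickness by 1-D not-a-knot cubic
splines (exact on linear ramps, extent preserved to within one slice);
(3) external-structure removal: the head mask is the largest 26-connected
component above −200 HU, morphologically closed and hole-filled, and
everything outside is set to air (−1000 HU). The two thresholds are
conventions, not literature values, and are exposed on the CLI. Ties
between equal-sized components go to the one nearest the volume centroid
(the head is central in head CT).

## Registration

Registration is intensity-based and parametric, built from scratch on five
components:

* **Scale space** — four levels of isotropic Gaussian smoothing with
  σ = 4, 2, 1, 0.5 voxels, interpreted in voxel units and without
  downsampling (smoothing-only pyramid), so all levels share one grid.
* **Sampling** — every iteration draws 3000 fresh continuous points
  uniformly over the fixed head mask (voxel drawn uniformly, then jittered
  within its physical extent). An iteration is valid only if at least 150
  points land inside both image domains; otherwise the stage aborts
  ("insufficient coordinate alignments").
* **Metric** — mutual information in nats from a 32×32 joint histogram
  built with cubic B-spline Parzen windows on both intensity axes.
  Intensities map linearly into bin space [1, n_bins − 2] using a range
  frozen per stage/level from an initial sample draw, padded by 2 % so the
  window stays differentiable at the extremes; out-of-range values clamp
  with zero derivative. A degenerate channel (max = min) yields MI = 0.
  Note that with Parzen smoothing MI(X, X) equals H_f + H_m − H_joint of
  the smoothed histogram, which is *smaller* than the marginal entropy —
  the kernel spreads the joint off the diagonal.
* **Transforms** — a chain applied fixed → moving: rigid (Euler angles
  about the volume axes around the head centroid + translation), full
  affine, then a cubic B-spline free-form deformation with 20 mm
  control-point spacing whose lattice covers the (transformed) fixed
  domain plus a one-spacing margin. Each stage starts at identity on top
  of the frozen previous stages. Rotation and linear-map parameters are
  scaled by the head radius so all parameters live in mm-equivalent units.
  FFD coefficients are bounded at 0.4× the control spacing — the standard
  injectivity condition; at 20 mm spacing this still allows ±8 mm of local
  deformation but prevents the folding that an unregularized MI objective
  can otherwise reward.
* **Optimizer** — adaptive stochastic gradient descent. The analytic
  gradient chains the Parzen-window derivative with the moving image's
  analytic interpolant gradient and the transform Jacobian (verified
  against central finite differences to 5 % / 1e-6). Step size is
  `a/(A + t_k)^α` with A = 20, α = 0.602; the internal time `t_k` shrinks
  when successive stochastic gradients correlate and grows when they
  anti-correlate (sigmoid response in [−0.5, 1]). The gain `a` is
  auto-scaled per level from probe gradients so the first update moves no
  parameter more than ≈ 0.3·σ_level·spacing mm, and every update is capped
  at that (decaying) trust step — a gain calibrated near an optimum, where
  probe gradients are pure sampling noise, cannot blow up once a real
  gradient appears. The returned parameters are the Polyak–Ruppert average
  of the last half of each level's iterates, which cancels the zero-mean
  oscillation around the optimum (rigid recovery error drops from ~0.3 mm
  to ~0.003 mm).

The per-stage iteration budgets (rigid 1500, affine 1500, B-spline 2500)
are treated as stage totals and split evenly across the four levels.
Interpolation is trilinear on the three coarse levels and cubic B-spline
(prefiltered, mirror boundary) on the final level, for both images.
Moving-image resampling onto a target grid uses cubic interpolation of the
full chain, with points outside the moving volume's physical extent (half
a voxel beyond the outermost centers) filled with −1000 HU. Registration
is fully deterministic given its seed.

Known behavior: self-registration does not return the exact identity.
The stochastic Parzen gradient has nonzero per-iteration noise even for
identical images, leaving an equilibrium wander of ~0.3 mm mean
displacement over head voxels (bounded by the spec'd 0.5 mm contract).
At tissue interfaces this translates into locally large HU differences
after resampling (a 2 mm-voxel skull edge has a ~500 HU/mm gradient), so
voxelwise comparisons of "identical" inputs after registration are
edge-dominated: the median head-voxel error is well under 1 HU while the
mean is several HU. This is inherent to stochastic-sampling optimizers,
not an implementation artifact; the averaging-identity check in the
acceptance suite documents it.

## Template construction

One control is the fixed reference; every control *including the
reference* is registered to it with the full chain and resampled onto its
grid, and the template is the plain voxelwise arithmetic mean (no
trimming, no intensity harmonization). A control whose registration fails
is dropped with a warning; fewer than two survivors abort. Per-control
seeds derive from the master seed and the control's identifier and
contributions are summed in identifier order, so the build is
reproducible and invariant to input order. The fixed image can be given
explicitly or chosen with `--fixed auto` (the control whose affine-only
alignment to all others has the lowest mean cost — quadratic in cohort
size and a deviation from a manually chosen reference, logged as such).

## Detection

The template is deformed onto each subject (subject as fixed image) and
subtracted voxelwise (signed, subject − template). Candidates are
26-connected components of voxels with residual > 25 HU *and* subject
intensity > 60 HU, inside the head mask with bone (subject > 300 HU,
dilated one voxel) removed. The two HU anchors come from CT physiology:
brain parenchyma and CSF lie in 3–40 HU while fresh blood exceeds
~60 HU, so a hemorrhage is simultaneously a large positive residual and an
absolutely hyperdense focus; the absolute floor also suppresses residuals
from imperfect alignment of low-density structures (ventricles).
Components below 2 mm sphere-equivalent diameter are discarded; the list
is sorted by peak residual, then voxel count, then centroid —
deterministic under any labeling order. Hypodense residuals are rendered
but never become candidates. No ventricle segmentation is attempted, so
periventricular residuals remain a known false-positive source on real
data; the skull-edge artifact is suppressed for candidates (bone
exclusion) while the overlay keeps full anatomy.

Overlays map |residual| through a blue → green → yellow lookup (blue at
≤ half the threshold, green at the threshold, yellow from twice the
threshold) over a grayscale brain-window underlay, one PNG per axial slice
with an embedded colorbar; a signed-rendering switch exists.

## Scoring

Candidates match ground-truth lesions one-to-one, greedily by ascending
centroid distance with a 5 mm gate (half the largest target lesion
diameter — phantom lesions are small spheres, so centroid distance is a
cleaner criterion than overlap). Matched pairs are TP, unmatched truths
FN, unmatched candidates FP; sensitivity is pooled over all lesions
(TP/(TP+FN), reported to 3 decimals), matching the arithmetic of "65 of
67 detected". An unscored threshold-sweep helper exists.

## Synthetic phantoms

The generator produces the validation substrate: an ellipsoidal ~1000 HU
skull shell around white matter (35 HU), a 5 mm gray-matter ribbon
(40 HU) and paired CSF ventricles (8 HU) — all inside the physiological
3–40 HU band so the ≥ 60 HU blood class is separable. Per-subject
variation composes a random affine jitter (±5 % per-axis scale, ±5°
rotations, ±5 mm translations) with a smooth random displacement field
(Gaussian-filtered white noise, 15 mm correlation scale, peak amplitude
drawn up to 3 mm); the subject volume is evaluated *analytically* through
that mapping, so tissue edges stay crisp and the deformation is known
exactly. Optional clutter (a detached 40 HU slab) exercises
external-structure stripping, and Gaussian noise (σ = 3 HU, typical
brain-window CT noise) is added last. Landmarks (inner-skull poles,
ventricle tips) are carried through the deformation by fixed-point
inversion to 1e-9 mm.

Lesions are spheres painted in the subject frame *after* the deformation
— ground-truth centroids are exact by construction. A lesion has its
nominal HU throughout the sphere and a cosine feather falling to zero one
voxel beyond the surface; voxels outside that support are untouched. The
default cohort draws diameters uniformly from 3–10 mm and densities
uniformly from 70–80 HU (acute clotted blood; the physiological bound is
only > 60 HU), places centers ≥ 3 mm plus the lesion support away from the
skull (a near-bone flag overrides), and keeps lesions disjoint. The
default study layout is 30 controls and 9 lesioned subjects carrying
12, 2, 11, 16, 3, 14, 2, 1, 6 lesions (67 total). Grids default to 1 mm
isotropic (120×160×160); a half-resolution mode (2 mm, 60×80×80) exists
for bounded-time runs and is what the acceptance script uses.

What the phantoms do *not* model: real cortical folding and the highly
variable temporal fossa (the source of the two misses in practice),
beam-hardening and streak artifacts, scanner-vendor differences, midline
shift, and age-related atrophy. Passing the synthetic suite therefore
shows the pipeline's machinery is correct and self-consistent under the
stated variation model — not that the clinical sensitivity transfers to
patient data.

## Transform-chain files

Registrations are replayable: a chain serializes to a plain-text file
whose first line is `ctavg-transform-chain v1`, followed by one block per
stage. Rigid and affine blocks carry `center` (mm), `rot_scale` (the mm
radius used to scale angular/linear parameters) and `params` (the scaled
parameter vector: 3 scaled Euler angles + 3 translations, or 9 scaled
linear-map entries + 3 translations). B-spline blocks carry
`grid_origin` (mm), `grid_spacing` (mm), `grid_shape` (control points per
axis) and `coef` (the flattened control-point displacement vectors, mm,
in z-y-x-component order). All numbers print with full precision, so a
reloaded chain reproduces the original mapping exactly.

## Problem sizes and determinism

The acceptance script and the cohort-level tests run the full 30 + 9
pipeline at half resolution with all registration defaults unchanged —
about 39 full rigid/affine/B-spline registrations. Per-subject and
per-stage seeds derive from the master seed by stable hashing, so a rerun
with the same seed reproduces the cohort result JSON byte for byte.
Compiled kernels (numba) make a half-resolution registration take a few
seconds; the first call in a fresh environment pays a one-time JIT cost.

## Limitations

* Pairwise registration to a single chosen reference biases the template
  toward that subject; groupwise registration would remove the bias and is
  out of scope.
* The false-positive behavior on real CT (periventricular, tentorium,
  pons regions) is not reproduced by the phantoms' clean geometry.
* The candidate extractor is a deliberately simple thresholded-component
  detector that makes sensitivity computable without an observer; it is
  not a substitute for radiologist reading of the colorized maps.
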