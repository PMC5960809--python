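"""Seeded synthetic head-CT phantoms with known inserted hemorrhages.

The generator emulates the statistical structure the template-subtraction
method relies on, without claiming anatomical realism:

* an ellipsoidal skull shell (~1000 HU) around a brain whose tissues sit in
  the physiological CT bands — white matter 35 HU, a gray-matter ribbon
  40 HU, paired CSF-filled ventricles 8 HU (all within the 3–40 HU
  soft-tissue range, so that fresh blood at >60 HU is separable);
* inter-subject variation: a random affine jitter (±5 % scale, ±5°
  rotation, ±5 mm translation) composed with a smooth random displacement
  field (amplitude ≤ 3 mm), sampled per subject from a seed;
* optional external clutter (a detached 40 HU "pillow" slab) and additive
  Gaussian HU noise (σ = 3 by default);
* hyperdense spherical lesions 3–10 mm in diameter at 60–80 HU, painted in
  the subject frame *after* the deformation so ground-truth centroids are
  exact.

Every subject also carries a sidecar of landmark positions (inner-skull
poles, ventricle tips) mapped through the subject's deformation, used by
the registration recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .evaluation import GroundTruthLesion, write_truth_tsv
from .volumes import AIR_HU, VolumeHU, write_volume

#: Per-patient lesion counts of the study cohort (9 subjects, 67 lesions).
TBI_PLAN_DEFAULT = (12, 2, 11, 16, 3, 14, 2, 1, 6)

LESION_LABELS = ("DAI", "subarachnoid", "cerebral contusion", "subdural", "intraventricular")


@dataclass
class PhantomSpec:
    """Geometry and statistics of the synthetic head.

    All lengths in mm, all intensities in HU.  Axis order (axial, row,
    column) matches :class:`~ctavg.volumes.VolumeHU`.
    """

    shape: tuple[int, int, int] = (120, 160, 160)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    skull_semiaxes: tuple[float, float, float] = (48.0, 62.0, 58.0)
    skull_thickness: float = 6.0
    skull_hu: float = 1000.0
    white_hu: float = 35.0
    gray_hu: float = 40.0
    gray_thickness: float = 5.0
    csf_hu: float = 8.0
    ventricle_semiaxes: tuple[float, float, float] = (12.0, 20.0, 9.0)
    ventricle_offset_x: float = 14.0
    pillow: bool = False
    pillow_hu: float = 40.0
    noise_sigma: float = 3.0
    # subject-to-subject variation
    scale_jitter: float = 0.05
    rot_jitter_deg: float = 5.0
    trans_jitter_mm: float = 5.0
    warp_amp_mm: float = 3.0
    warp_smooth_mm: float = 15.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing) or any(n < 4 for n in self.shape):
            raise ValueError("invalid phantom grid")
        for hu in (self.white_hu, self.gray_hu, self.csf_hu):
            if not (3.0 <= hu <= 40.0):
                raise ValueError("brain/CSF tissue HU must lie in the 3-40 HU band")

    @property
    def center(self) -> np.ndarray:
        """Physical center of the grid (origin is 0)."""
        return (np.array(self.shape) - 1) * np.array(self.spacing) / 2.0

    def fast(self) -> "PhantomSpec":
        """Half-resolution variant (2 mm isotropic) for quick runs."""
        return replace(
            self,
            shape=tuple(n // 2 for n in self.shape),
            spacing=tuple(s * 2 for s in self.spacing),
        )


@dataclass
class LesionSpec:
    """A hyperdense spherical lesion to insert.

    ``center`` is in subject physical coordinates (mm); ``None`` means
    "sample a valid position inside the brain".
    """

    diameter_mm: float
    hu: float
    center: np.ndarray | None = None
    label: str = "DAI"
    near_bone: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.diameter_mm):
            raise ValueError("diameter must be positive")
        if self.center is not None:
            self.center = np.asarray(self.center, dtype=np.float64).reshape(3)


# ---------------------------------------------------------------------------
# Canonical tissue model (analytic, evaluated at arbitrary physical points)
# ---------------------------------------------------------------------------

def _rho2(pts: np.ndarray, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    d = (pts - center) / semi
    return np.einsum("ij,ij->i", d, d)


def canonical_hu(pts: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """HU of the canonical (undeformed) head at physical points (N, 3)."""
    pts = np.asarray(pts, dtype=np.float64).reshape(-1, 3)
    c = spec.center
    outer = np.array(spec.skull_semiaxes)
    inner = outer - spec.skull_thickness
    white = inner - spec.gray_thickness
    hu = np.full(len(pts), AIR_HU)
    r_out = _rho2(pts, c, outer)
    r_in = _rho2(pts, c, inner)
    hu[(r_out <= 1.0) & (r_in > 1.0)] = spec.skull_hu
    brain = r_in <= 1.0
    hu[brain] = spec.gray_hu
    hu[_rho2(pts, c, white) <= 1.0] = spec.white_hu
    v_semi = np.array(spec.ventricle_semiaxes)
    for sx in (-1.0, 1.0):
        vc = c + np.array([0.0, 0.0, sx * spec.ventricle_offset_x])
        hu[brain & (_rho2(pts, vc, v_semi) <= 1.0)] = spec.csf_hu
    return hu


CANONICAL_LANDMARK_NAMES = (
    "skull_pole_z-", "skull_pole_z+", "skull_pole_y-", "skull_pole_y+",
    "skull_pole_x-", "skull_pole_x+",
    "ventricle_left_tip_y-", "ventricle_left_tip_y+",
    "ventricle_right_tip_y-", "ventricle_right_tip_y+",
)


def canonical_landmarks(spec: PhantomSpec) -> np.ndarray:
    """Inner-skull poles and ventricle tips in canonical coordinates (mm)."""
    c = spec.center
    inner = np.array(spec.skull_semiaxes) - spec.skull_thickness
    pts = []
    for ax in range(3):
        for s in (-1.0, 1.0):
            p = c.copy()
            p[ax] += s * inner[ax]
            pts.append(p)
    vy = spec.ventricle_semiaxes[1]
    for sx in (-1.0, 1.0):
        vc = c + np.array([0.0, 0.0, sx * spec.ventricle_offset_x])
        for s in (-1.0, 1.0):
            p = vc.copy()
            p[1] += s * vy
            pts.append(p)
    return np.array(pts)


# ---------------------------------------------------------------------------
# Subject deformation: canonical <- subject mapping
# ---------------------------------------------------------------------------

@dataclass
class SubjectDeformation:
    """Maps subject physical points to canonical points: u = A(p-c)+c+t+D(p)."""

    matrix: np.ndarray          # 3x3
    translation: np.ndarray     # 3
    center: np.ndarray          # 3
    field: np.ndarray           # (3, nz, ny, nx) displacement, mm
    spacing: np.ndarray

    def _field_at(self, pts: np.ndarray) -> np.ndarray:
        idx = (pts / self.spacing).T  # origin 0
        return np.stack(
            [ndimage.map_coordinates(self.field[d], idx, order=1, mode="nearest")
             for d in range(3)], axis=1)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=np.float64).reshape(-1, 3)
        aff = (pts - self.center) @ self.matrix.T + self.center + self.translation
        return aff + self._field_at(pts)

    def invert(self, pts_canonical: np.ndarray, tol: float = 1e-9, max_iter: int = 200) -> np.ndarray:
        """Subject positions of canonical points, by fixed-point iteration."""
        u = np.asarray(pts_canonical, dtype=np.float64).reshape(-1, 3)
        inv = np.linalg.inv(self.matrix)
        p = u.copy()
        for _ in range(max_iter):
            p_new = (u - self.translation - self._field_at(p) - self.center) @ inv.T + self.center
            if np.max(np.abs(p_new - p)) < tol:
                return p_new
            p = p_new
        return p


def _euler_matrix(angles: np.ndarray) -> np.ndarray:
    """Rotation about the (axial, row, col) axes: R = R0 @ R1 @ R2."""
    mats = []
    for ax, th in enumerate(angles):
        c, s = np.cos(th), np.sin(th)
        m = np.eye(3)
        i, j = [k for k in range(3) if k != ax]
        m[i, i] = c
        m[j, j] = c
        m[i, j] = -s
        m[j, i] = s
        mats.append(m)
    return mats[0] @ mats[1] @ mats[2]


def _sample_deformation(spec: PhantomSpec, rng: np.random.Generator) -> SubjectDeformation:
    scales = 1.0 + rng.uniform(-spec.scale_jitter, spec.scale_jitter, 3)
    angles = np.deg2rad(rng.uniform(-spec.rot_jitter_deg, spec.rot_jitter_deg, 3))
    trans = rng.uniform(-spec.trans_jitter_mm, spec.trans_jitter_mm, 3)
    matrix = _euler_matrix(angles) @ np.diag(scales)
    spacing = np.array(spec.spacing)
    noise = rng.standard_normal((3,) + tuple(spec.shape))
    sig = spec.warp_smooth_mm / spacing
    for d in range(3):
        noise[d] = ndimage.gaussian_filter(noise[d], sigma=sig, mode="reflect")
    norm = np.sqrt(np.sum(noise**2, axis=0))
    peak = float(norm.max())
    amp = rng.uniform(0.3, 1.0) * spec.warp_amp_mm
    field = noise * (amp / peak) if peak > 0 else noise
    return SubjectDeformation(
        matrix=matrix,
        translation=trans,
        center=spec.center,
        field=field,
        spacing=spacing,
    )


# ---------------------------------------------------------------------------
# Subject generation
# ---------------------------------------------------------------------------

def _grid_points(spec: PhantomSpec) -> np.ndarray:
    axes = [np.arange(n) * s for n, s in zip(spec.shape, spec.spacing)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)


def _paint_pillow(vox: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Add a detached clutter slab beside the head; returns its mask."""
    ny = spec.shape[1]
    sy = spec.spacing[1]
    lo = int(round((ny * sy - 7.0) / sy))   # slab in the last ~6 mm of rows
    lo = min(lo, ny - 2)
    mask = np.zeros(spec.shape, dtype=bool)
    z0, z1 = spec.shape[0] // 4, 3 * spec.shape[0] // 4
    x0, x1 = spec.shape[2] // 4, 3 * spec.shape[2] // 4
    mask[z0:z1, lo:, x0:x1] = True
    mask &= vox <= AIR_HU + 1.0  # never touch the head
    vox[mask] = spec.pillow_hu
    return mask


def generate_control(spec: PhantomSpec, seed: int) -> tuple[VolumeHU, dict]:
    """One lesion-free subject; deterministic given ``seed``.

    Returns the volume and a sidecar dict with the deformation, landmark
    positions (canonical and subject frame), the bone-bearing axial slice
    range, and the clutter mask if enabled.
    """
    vol, sidecar, _ = _generate_subject(spec, lesions=[], seed=seed)
    return vol, sidecar


def generate_tbi(
    spec: PhantomSpec, lesions: list[LesionSpec], seed: int
) -> tuple[VolumeHU, list[GroundTruthLesion], dict]:
    """One lesioned subject plus exact ground truth, deterministic given seed."""
    vol, sidecar, truths = _generate_subject(spec, lesions=lesions, seed=seed)
    return vol, truths, sidecar


def _generate_subject(spec: PhantomSpec, lesions: list[LesionSpec], seed: int):
    ss = np.random.SeedSequence(seed)
    rng_vol, rng_les = (np.random.default_rng(s) for s in ss.spawn(2))
    deform = _sample_deformation(spec, rng_vol)
    pts = _grid_points(spec)
    vox = canonical_hu(deform.apply(pts), spec).reshape(spec.shape)

    truths = _paint_lesions(vox, spec, lesions, rng_les)

    pillow_mask = _paint_pillow(vox, spec) if spec.pillow else None
    if spec.noise_sigma > 0:
        vox = vox + rng_vol.normal(0.0, spec.noise_sigma, spec.shape)

    lm_canon = canonical_landmarks(spec)
    lm_subject = deform.invert(lm_canon)
    bone = np.nonzero(np.any(vox > 300.0, axis=(1, 2)))[0]
    sidecar = {
        "seed": int(seed),
        "deformation": deform,
        "landmarks_canonical": lm_canon,
        "landmarks_subject": lm_subject,
        "landmark_names": list(CANONICAL_LANDMARK_NAMES),
        "bone_slice_range": (int(bone[0]), int(bone[-1])) if len(bone) else None,
        "pillow_mask": pillow_mask,
    }
    vol = VolumeHU(vox, np.array(spec.spacing), np.zeros(3))
    return vol, sidecar, truths


def _paint_lesions(
    vox: np.ndarray, spec: PhantomSpec, lesions: list[LesionSpec], rng: np.random.Generator
) -> list[GroundTruthLesion]:
    """Paint spherical lesions into the subject volume (in place).

    A lesion has its nominal HU on the whole sphere interior and a cosine
    feather falling to 0 one voxel beyond the sphere surface; voxels
    outside that support are untouched.  Centers passed as ``None`` are
    sampled inside the brain with enough margin from the skull (and from
    previously placed lesions) for the full support to fit.
    """
    spacing = np.array(spec.spacing)
    feather = float(spacing.max())
    truths: list[GroundTruthLesion] = []
    placed: list[tuple[np.ndarray, float]] = []

    brain = (vox > 0.0) & (vox < 300.0)
    dist_mm = ndimage.distance_transform_edt(brain, sampling=spacing)

    for les in lesions:
        radius = les.diameter_mm / 2.0
        if les.center is None:
            center = _sample_center(dist_mm, spacing, radius + feather, placed, rng)
        else:
            center = np.asarray(les.center, dtype=np.float64)
        support_r = radius + feather
        lo = np.maximum(np.floor((center - support_r) / spacing - 1), 0).astype(int)
        hi = np.minimum(np.ceil((center + support_r) / spacing + 1), np.array(vox.shape) - 1).astype(int)
        sl = tuple(slice(a, b + 1) for a, b in zip(lo, hi))
        axes = [np.arange(a, b + 1) * s for a, b, s in zip(lo, hi, spacing)]
        zz, yy, xx = np.meshgrid(*axes, indexing="ij")
        r = np.sqrt((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
        w = np.zeros_like(r)
        w[r <= radius] = 1.0
        ramp = (r > radius) & (r <= support_r)
        w[ramp] = 0.5 * (1.0 + np.cos(np.pi * (r[ramp] - radius) / feather))
        region = vox[sl]
        touches_bone = np.any((w > 0) & (region > 300.0))
        outside_head = np.any((w > 0) & (region <= AIR_HU + 1.0))
        if (touches_bone or outside_head) and not les.near_bone:
            raise ValueError(
                f"lesion at {np.round(center, 1)} (d={les.diameter_mm} mm) collides "
                "with skull or leaves the head; set near_bone=True to allow"
            )
        paintable = region < 300.0  # never overwrite bone
        region[paintable] += (w * (les.hu - region))[paintable]
        vox[sl] = region
        placed.append((center, radius))
        truths.append(
            GroundTruthLesion(centroid=center, diameter_mm=les.diameter_mm,
                              label=les.label, hu=les.hu)
        )
    return truths


def _sample_center(dist_mm, spacing, margin_mm, placed, rng, max_tries: int = 5000):
    """Sample a lesion center ≥ max(3 mm, support) from the skull and clear
    of already-placed lesions."""
    margin = max(margin_mm, 3.0)
    ok = dist_mm >= margin + float(spacing.max())
    idx = np.argwhere(ok)
    if len(idx) == 0:
        raise ValueError("no interior region deep enough for the requested lesion")
    for _ in range(max_tries):
        vi = idx[rng.integers(len(idx))]
        center = (vi + rng.uniform(-0.5, 0.5, 3)) * spacing
        if all(np.linalg.norm(center - c) >= margin_mm + r + 4.0 for c, r in placed):
            return center
    raise ValueError("could not place lesion without overlap; too many lesions for the brain size")


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _subject_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def sample_lesion_specs(n: int, rng: np.random.Generator) -> list[LesionSpec]:
    """Default lesion population: diameters U[3, 10] mm, density U[70, 80] HU
    (acute clotted blood), labels drawn from the clinical vocabulary."""
    out = []
    for _ in range(n):
        out.append(
            LesionSpec(
                diameter_mm=float(rng.uniform(3.0, 10.0)),
                hu=float(rng.uniform(70.0, 80.0)),
                label=str(rng.choice(LESION_LABELS)),
            )
        )
    return out


def generate_cohort(
    out_dir,
    n_controls: int = 30,
    tbi_plan=TBI_PLAN_DEFAULT,
    master_seed: int = 42,
    spec: PhantomSpec | None = None,
    fast: bool = False,
) -> dict:
    """Write a full synthetic study cohort to ``out_dir``.

    Creates ``controls/``, ``tbi/``, ``cohort_truth.tsv`` and one JSON
    sidecar per subject.  Per-subject seeds are derived from
    ``master_seed`` so reruns are byte-identical.
    """
    if n_controls < 1 or any(k < 0 for k in tbi_plan):
        raise ValueError("counts must be positive")
    spec = spec or PhantomSpec()
    if fast:
        spec = spec.fast()
    out_dir = Path(out_dir)
    (out_dir / "controls").mkdir(parents=True, exist_ok=True)
    (out_dir / "tbi").mkdir(parents=True, exist_ok=True)

    n_tbi = len(tbi_plan)
    seeds = _subject_seeds(master_seed, n_controls + n_tbi)
    manifest = {"master_seed": int(master_seed), "controls": [], "tbi": [],
                "spec": _spec_dict(spec)}
    truth_rows = []

    for i in range(n_controls):
        name = f"ctrl_{i:02d}"
        vol, sidecar = generate_control(spec, seeds[i])
        write_volume(vol, out_dir / "controls" / f"{name}.nii.gz")
        _write_sidecar(out_dir / "controls" / f"{name}.json", name, sidecar)
        manifest["controls"].append({"id": name, "seed": seeds[i]})

    for j, n_lesions in enumerate(tbi_plan):
        name = f"tbi_{j:02d}"
        seed = seeds[n_controls + j]
        rng_plan = np.random.default_rng(np.random.SeedSequence((master_seed, 1000 + j)))
        lesions = sample_lesion_specs(n_lesions, rng_plan)
        vol, truths, sidecar = generate_tbi(spec, lesions, seed)
        write_volume(vol, out_dir / "tbi" / f"{name}.nii.gz")
        _write_sidecar(out_dir / "tbi" / f"{name}.json", name, sidecar)
        truth_rows.extend((name, t) for t in truths)
        manifest["tbi"].append({"id": name, "seed": seed, "n_lesions": n_lesions})

    write_truth_tsv(out_dir / "cohort_truth.tsv", truth_rows)
    with open(out_dir / "cohort_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _spec_dict(spec: PhantomSpec) -> dict:
    d = {}
    for k, v in spec.__dict__.items():
        if isinstance(v, (tuple, list, np.ndarray)):
            d[k] = [float(x) for x in v]
        else:
            d[k] = v if isinstance(v, (bool, str)) else float(v)
    return d


def _write_sidecar(path, name, sidecar) -> None:
    deform: SubjectDeformation = sidecar["deformation"]
    payload = {
        "id": name,
        "seed": sidecar["seed"],
        "affine_matrix": deform.matrix.tolist(),
        "translation": deform.translation.tolist(),
        "center": deform.center.tolist(),
        "landmark_names": sidecar["landmark_names"],
        "landmarks_canonical": sidecar["landmarks_canonical"].tolist(),
        "landmarks_subject": sidecar["landmarks_subject"].tolist(),
        "bone_slice_range": sidecar["bone_slice_range"],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
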