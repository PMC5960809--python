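"""Template-subtraction detection of hyperdense lesions.

The average template is deformed onto a subject scan (subject as fixed
image), subtracted voxelwise, and hemorrhage candidates are the
26-connected components where the signed difference exceeds a threshold
*and* the subject itself is in the blood density range.  The HU anchors
come from CT physiology: CSF and brain parenchyma lie between 3 and 40 HU
while fresh blood is above ~60 HU, so a small hemorrhage shows up as both
a large positive residual against the template and an absolutely
hyperdense focus.  Skull-edge residuals — the known artifact of
subtracting unstripped heads — are suppressed by excluding bone
(subject > 300 HU, dilated by one voxel) from the candidate mask while the
rendered overlay keeps the full anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
from scipy import ndimage

matplotlib.use("Agg")
from matplotlib.image import imsave  # noqa: E402

from .registration import RegistrationConfig, register, resample
from .template import AverageTemplate
from .volumes import HeadMask, VolumeHU

#: LUT anchors (relative to diff_threshold): blue below 0.5x, green at 1x,
#: yellow from 2x upward.
_LUT_COLORS = {"blue": (0.1, 0.2, 0.9), "green": (0.1, 0.85, 0.2), "yellow": (0.95, 0.9, 0.1)}


@dataclass
class DetectionConfig:
    diff_threshold: float = 25.0     # HU residual needed to flag a voxel
    blood_hu_min: float = 60.0       # subject must be in the blood band
    min_diameter_mm: float = 2.0     # sphere-equivalent size filter
    max_diameter_mm: float | None = None
    skull_hu: float = 300.0
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.diff_threshold <= 0 or self.blood_hu_min <= 0 or self.min_diameter_mm <= 0:
            raise ValueError("thresholds must be positive")
        if self.max_diameter_mm is not None and self.max_diameter_mm <= self.min_diameter_mm:
            raise ValueError("max_diameter_mm must exceed min_diameter_mm")
        if self.connectivity != 26:
            raise ValueError("only 26-neighborhood connectivity is supported")


@dataclass
class DifferenceMap:
    """Signed voxelwise subject − template, on the subject grid."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    @property
    def volume(self) -> VolumeHU:
        return VolumeHU(self.values, self.spacing, self.origin)


@dataclass
class LesionCandidate:
    centroid: np.ndarray        # physical mm
    diameter_mm: float          # sphere-equivalent
    peak_diff: float            # max residual HU
    mean_hu: float              # mean subject HU over the component
    n_voxels: int

    def as_row(self) -> str:
        z, y, x = self.centroid
        return (f"{z:.3f}\t{y:.3f}\t{x:.3f}\t{self.diameter_mm:.3f}"
                f"\t{self.peak_diff:.2f}\t{self.mean_hu:.2f}\t{self.n_voxels}")


CANDIDATE_HEADER = "id\tz_mm\ty_mm\tx_mm\tdiameter_mm\tpeak_diff_hu\tmean_hu\tn_voxels"


def align_template_to_subject(
    template: AverageTemplate | VolumeHU,
    subject: VolumeHU,
    config: RegistrationConfig | None = None,
    seed: int = 0,
    subject_mask: HeadMask | None = None,
) -> VolumeHU:
    """Deform the template onto the subject grid (subject is fixed)."""
    tvol = template.volume if isinstance(template, AverageTemplate) else template
    chain = register(subject, tvol, config, seed=seed, fixed_mask=subject_mask)
    return resample(tvol, chain, subject)


def subtract(subject: VolumeHU, aligned_template: VolumeHU) -> DifferenceMap:
    """Signed difference subject − template; grids must be congruent."""
    if not subject.same_grid(aligned_template):
        raise ValueError("subject and aligned template are not on the same grid")
    return DifferenceMap(
        values=subject.voxels - aligned_template.voxels,
        spacing=subject.spacing.copy(),
        origin=subject.origin.copy(),
    )


def extract_candidates(
    diff: DifferenceMap,
    subject: VolumeHU,
    mask: HeadMask,
    cfg: DetectionConfig | None = None,
) -> list[LesionCandidate]:
    """Hyperdense candidate components from the difference map.

    A voxel is flagged if its residual exceeds ``diff_threshold`` and the
    subject intensity exceeds ``blood_hu_min``, inside the head mask with
    dilated bone removed.  26-connected components smaller than the
    sphere-equivalent ``min_diameter_mm`` are discarded.  The list is
    sorted by peak residual (descending), then voxel count, then
    lexicographic centroid — deterministic regardless of labeling order.
    """
    cfg = cfg or DetectionConfig()
    if diff.values.shape != subject.shape or mask.mask.shape != subject.shape:
        raise ValueError("difference map, subject and mask must be congruent")
    skull = ndimage.binary_dilation(
        subject.voxels > cfg.skull_hu, structure=np.ones((3, 3, 3), dtype=bool)
    )
    sel = (
        (diff.values > cfg.diff_threshold)
        & (subject.voxels > cfg.blood_hu_min)
        & mask.mask
        & ~skull
    )
    labels, n = ndimage.label(sel, structure=np.ones((3, 3, 3), dtype=int))
    vox_volume = float(np.prod(subject.spacing))
    out: list[LesionCandidate] = []
    slices = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        box = slices[lab - 1]
        if box is None:
            continue
        local = np.argwhere(labels[box] == lab)
        idx = local + np.array([s.start for s in box])
        count = len(idx)
        eq_d = (6.0 * count * vox_volume / np.pi) ** (1.0 / 3.0)
        if eq_d < cfg.min_diameter_mm:
            continue
        if cfg.max_diameter_mm is not None and eq_d > cfg.max_diameter_mm:
            continue
        centroid = subject.index_to_world(idx.mean(axis=0))
        vals = diff.values[tuple(idx.T)]
        out.append(
            LesionCandidate(
                centroid=centroid,
                diameter_mm=float(eq_d),
                peak_diff=float(vals.max()),
                mean_hu=float(subject.voxels[tuple(idx.T)].mean()),
                n_voxels=count,
            )
        )
    out.sort(key=lambda c: (-c.peak_diff, -c.n_voxels, tuple(np.round(c.centroid, 6))))
    return out


def write_candidates_tsv(path, candidates: list[LesionCandidate]) -> None:
    lines = [CANDIDATE_HEADER]
    for i, c in enumerate(candidates):
        lines.append(f"{i}\t{c.as_row()}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_candidates_tsv(path) -> list[LesionCandidate]:
    out = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != CANDIDATE_HEADER:
            raise ValueError(f"unexpected candidate header: {header!r}")
        for line in fh:
            if not line.strip():
                continue
            _, z, y, x, d, pk, mh, nv = line.split("\t")
            out.append(LesionCandidate(
                centroid=np.array([float(z), float(y), float(x)]),
                diameter_mm=float(d), peak_diff=float(pk),
                mean_hu=float(mh), n_voxels=int(nv),
            ))
    return out


# ---------------------------------------------------------------------------
# Colorized overlay (blue = normal, yellow = strongly hyperdense)
# ---------------------------------------------------------------------------

def _lut(diff_norm: np.ndarray) -> np.ndarray:
    """Map |diff| / diff_threshold through blue → green → yellow.

    ≤ 0.5 is solid blue (normal tissue), 1.0 is green, ≥ 2.0 solid yellow.
    """
    b = np.array(_LUT_COLORS["blue"])
    g = np.array(_LUT_COLORS["green"])
    y = np.array(_LUT_COLORS["yellow"])
    x = np.asarray(diff_norm, dtype=np.float64)
    rgb = np.empty(x.shape + (3,))
    t1 = np.clip((x - 0.5) / 0.5, 0.0, 1.0)[..., None]   # blue -> green
    t2 = np.clip((x - 1.0) / 1.0, 0.0, 1.0)[..., None]   # green -> yellow
    rgb[:] = b * (1 - t1) + g * t1
    rgb = rgb * (1 - t2) + y * t2
    return rgb


def overlay_rgb(
    subject_slice: np.ndarray,
    diff_slice: np.ndarray,
    cfg: DetectionConfig,
    signed: bool = False,
    window: tuple[float, float] = (0.0, 80.0),
    alpha: float = 0.55,
) -> np.ndarray:
    """One axial slice as an RGB array: gray underlay + LUT color."""
    d = diff_slice if signed else np.abs(diff_slice)
    color = _lut(np.clip(d, 0.0, None) / cfg.diff_threshold)
    lo, hi = window
    gray = np.clip((subject_slice - lo) / (hi - lo), 0.0, 1.0)[..., None]
    return (1.0 - alpha) * np.repeat(gray, 3, axis=-1) + alpha * color


def render_overlay(
    subject: VolumeHU,
    diff: DifferenceMap,
    out_dir,
    cfg: DetectionConfig | None = None,
    signed: bool = False,
) -> list[Path]:
    """Write one PNG per axial slice with an embedded colorbar strip."""
    cfg = cfg or DetectionConfig()
    if diff.values.shape != subject.shape:
        raise ValueError("difference map and subject must be congruent")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_rows = subject.shape[1]
    bar_w = max(4, subject.shape[2] // 16)
    # vertical colorbar: top = 2x threshold (yellow), bottom = 0 (blue)
    bar_vals = np.linspace(2.0, 0.0, n_rows)[:, None] * np.ones((1, bar_w))
    bar = _lut(bar_vals)
    paths = []
    for k in range(subject.shape[0]):
        rgb = overlay_rgb(subject.voxels[k], diff.values[k], cfg, signed=signed)
        framed = np.concatenate([rgb, np.ones((n_rows, 2, 3)), bar], axis=1)
        p = out_dir / f"slice_{k:03d}.png"
        imsave(p, np.clip(framed, 0.0, 1.0))
        paths.append(p)
    return paths
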