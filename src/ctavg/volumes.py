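"""Volume data model, NIfTI I/O and head-CT preprocessing.

The whole pipeline works on a single image currency: a 3-D scalar grid in
Hounsfield units (HU) with axis order ``(axial slice, row, column)``,
positive per-axis spacing in mm, and an origin giving the physical position
of voxel ``(0, 0, 0)``.  Physical coordinates are axis-aligned:
``p = origin + index * spacing``.  Oblique orientations are rejected on
read — clinical head CT reconstructed to the axial plane fits this model,
and it keeps every downstream transform testable in closed form.

Preprocessing mirrors a routine head-CT cleanup: crop axial slices outside
the skull, resample to a uniform axial slice thickness, and remove
external structures (hair, pillows, sheets) by thresholding and
connected-component analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

AIR_HU = -1000.0
#: Default HU threshold above which a voxel is considered bone.
BONE_HU_DEFAULT = 300.0
#: Default HU threshold above which a voxel belongs to the head (soft tissue).
SOFT_HU_DEFAULT = -200.0


class VolumeError(ValueError):
    """Raised for malformed volumes or preprocessing precondition failures."""


@dataclass
class VolumeHU:
    """A 3-D scalar CT volume in Hounsfield units.

    Attributes
    ----------
    voxels : ndarray
        3-D float array of intensities (HU), axis order (axial, row, col).
    spacing : ndarray
        Per-axis voxel size in mm, strictly positive.
    origin : ndarray
        Physical position (mm) of voxel index (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise VolumeError(
                f"expected 3-D volume, got {self.voxels.ndim}-D data"
            )
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if not np.all(np.isfinite(self.spacing)) or np.any(self.spacing <= 0):
            raise VolumeError(f"spacing must be positive and finite, got {self.spacing}")
        if not np.all(np.isfinite(self.origin)):
            raise VolumeError("origin must be finite")
        if not np.all(np.isfinite(self.voxels)):
            raise VolumeError("voxel intensities must be finite (no NaN/inf)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Physical coordinates (mm) of (fractional) voxel indices (N, 3)."""
        return self.origin + np.asarray(idx, dtype=np.float64) * self.spacing

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of physical points (N, 3)."""
        return (np.asarray(pts, dtype=np.float64) - self.origin) / self.spacing

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical extent covered by voxel volumes (lo, hi), mm."""
        lo = self.origin - 0.5 * self.spacing
        hi = self.origin + (np.array(self.shape) - 0.5) * self.spacing
        return lo, hi

    def copy(self) -> "VolumeHU":
        return VolumeHU(self.voxels.copy(), self.spacing.copy(), self.origin.copy())

    def same_grid(self, other: "VolumeHU", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class HeadMask:
    """Boolean mask congruent with a :class:`VolumeHU` grid."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise VolumeError("mask must be 3-D")


# --------------------------------------------------------------------------
# NIfTI I/O
# --------------------------------------------------------------------------

def read_volume(path) -> VolumeHU:
    """Read a NIfTI-1 volume as HU.

    The file's scale slope/intercept are honored (``get_fdata``).  Only
    axis-aligned, positive-spacing orientations are accepted; the NIfTI
    (i, j, k) = (col, row, slice) axes are transposed to the internal
    (slice, row, col) order.
    """
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise FileNotFoundError(f"no such NIfTI file: {path}") from None
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeError(f"expected 3-D volume in {path}, got {data.ndim}-D")
    aff = img.affine
    lin = aff[:3, :3]
    off_diag = lin - np.diag(np.diag(lin))
    if np.max(np.abs(off_diag)) > 1e-6 * max(1.0, np.max(np.abs(lin))):
        raise VolumeError(f"oblique orientation not supported: {path}")
    diag = np.diag(lin)
    if np.any(diag <= 0):
        raise VolumeError(f"non-positive spacing in affine of {path}")
    # NIfTI stores (x=col, y=row, z=slice); internal order is (slice, row, col)
    voxels = np.ascontiguousarray(data.transpose(2, 1, 0))
    spacing = diag[::-1].copy()
    origin = aff[:3, 3][::-1].copy()
    return VolumeHU(voxels, spacing, origin)


def write_volume(vol: VolumeHU, path) -> None:
    """Write a volume as 32-bit NIfTI-1 with an axis-aligned affine."""
    data = np.asarray(vol.voxels, dtype=np.float32).transpose(2, 1, 0)
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = vol.spacing[::-1]
    aff[:3, 3] = vol.origin[::-1]
    img = nib.Nifti1Image(data, aff)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


# --------------------------------------------------------------------------
# Preprocessing
# --------------------------------------------------------------------------

def resample_axial(vol: VolumeHU, target_slice_mm: float) -> VolumeHU:
    """Resample along the axial axis to a uniform slice thickness.

    Intensities are obtained by 1-D cubic-spline interpolation along the
    axial axis (not-a-knot spline: reproduces linear ramps exactly);
    in-plane sampling is untouched.  The physical extent is preserved to
    within one slice.
    """
    if target_slice_mm <= 0:
        raise VolumeError("target slice thickness must be positive")
    nz = vol.shape[0]
    extent = (nz - 1) * vol.spacing[0]
    if nz > 1 and target_slice_mm > extent:
        raise VolumeError(
            f"target slice thickness {target_slice_mm} mm exceeds axial extent {extent} mm"
        )
    if abs(target_slice_mm - vol.spacing[0]) < 1e-12:
        return vol.copy()
    z_old = np.arange(nz) * vol.spacing[0]
    n_new = int(np.floor(extent / target_slice_mm + 1e-9)) + 1
    z_new = np.arange(n_new) * target_slice_mm
    if nz < 4:  # cubic spline needs 4 points; fall back to linear
        new_vox = np.empty((n_new,) + vol.shape[1:])
        for i, z in enumerate(z_new):
            j = min(int(z // vol.spacing[0]), nz - 2)
            t = z / vol.spacing[0] - j
            new_vox[i] = (1 - t) * vol.voxels[j] + t * vol.voxels[j + 1]
    else:
        spline = CubicSpline(z_old, vol.voxels, axis=0)
        new_vox = spline(z_new)
    spacing = vol.spacing.copy()
    spacing[0] = target_slice_mm
    return VolumeHU(new_vox, spacing, vol.origin.copy())


def crop_irrelevant_slices(vol: VolumeHU, bone_hu_threshold: float = BONE_HU_DEFAULT) -> VolumeHU:
    """Retain the contiguous axial slice range that contains bone.

    Slices above the skull vertex and below the skull base carry no
    intracranial information; the kept range runs from the first to the
    last slice with any voxel above ``bone_hu_threshold``.  The origin is
    shifted so retained voxels keep their physical coordinates.
    """
    has_bone = np.any(vol.voxels > bone_hu_threshold, axis=(1, 2))
    if not np.any(has_bone):
        raise VolumeError("no skull found: no voxels above bone threshold")
    idx = np.nonzero(has_bone)[0]
    lo, hi = int(idx[0]), int(idx[-1]) + 1
    origin = vol.origin.copy()
    origin[0] += lo * vol.spacing[0]
    return VolumeHU(vol.voxels[lo:hi].copy(), vol.spacing.copy(), origin)


def strip_externals(
    vol: VolumeHU, soft_hu_threshold: float = SOFT_HU_DEFAULT
) -> tuple[VolumeHU, HeadMask]:
    """Remove structures not connected to the head (hair, pillows, sheets).

    The head mask is the largest 3-D connected component of voxels above
    ``soft_hu_threshold``, morphologically closed to fill internal
    cavities; everything outside is set to air (−1000 HU).  Ties between
    equal-size components are broken toward the component containing the
    volume centroid (the head is central in a head CT).
    """
    fg = vol.voxels > soft_hu_threshold
    if not np.any(fg):
        raise VolumeError("nothing above soft-tissue threshold; cannot locate head")
    labels, n = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    top = np.nonzero(sizes == sizes[best - 1])[0] + 1
    if len(top) > 1:
        # deterministic tie-break: component containing (or nearest to) the
        # volume's central voxel, by centroid distance
        center = (np.array(vol.shape) - 1) / 2.0
        centroids = np.array(ndimage.center_of_mass(fg, labels, index=top))
        best = int(top[np.argmin(np.linalg.norm(centroids - center, axis=1))])
    head = labels == best
    head = ndimage.binary_closing(head, structure=np.ones((3, 3, 3)), iterations=2)
    head |= labels == best  # closing must never remove original voxels
    # fill enclosed cavities (ventricles etc.) slice-independent in 3-D
    head = ndimage.binary_fill_holes(head)
    out = vol.voxels.copy()
    out[~head] = AIR_HU
    return VolumeHU(out, vol.spacing.copy(), vol.origin.copy()), HeadMask(head)


def preprocess(
    vol: VolumeHU,
    slice_mm: float = 1.0,
    bone_hu: float = BONE_HU_DEFAULT,
    soft_hu: float = SOFT_HU_DEFAULT,
) -> tuple[VolumeHU, HeadMask]:
    """Full preprocessing chain: crop → axial resample → strip externals."""
    vol = crop_irrelevant_slices(vol, bone_hu)
    vol = resample_axial(vol, slice_mm)
    return strip_externals(vol, soft_hu)
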