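"""Intensity-based deformable registration, implemented from scratch.

The framework follows the classic parametric-registration recipe:

* a 4-level Gaussian scale space (smoothing-only, σ = 4/2/1/0.5 voxels, no
  downsampling) to avoid local optima;
* a random coordinate sampler drawing 3000 fresh continuous points inside
  the fixed head mask at every iteration, with a minimum of 150 points that
  must land inside both image domains for an iteration to be valid;
* negated mutual information as the cost, estimated on a 32x32 joint
  histogram built with cubic B-spline Parzen windows (differentiable);
* a transform chain rigid -> affine -> cubic B-spline free-form deformation
  (20 mm control-point spacing), each stage optimized with the previous
  stages frozen as a preceding map;
* adaptive stochastic gradient descent (ASGD): step size a/(A + t_k)^alpha
  where the internal time t_k shrinks when successive stochastic gradients
  correlate and grows when they anti-correlate.

All geometry is in physical mm; a chain maps fixed-space points to
moving-space points, so the moving image is resampled onto the fixed grid
by pulling intensities at chain(x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import _kernels as K
from .volumes import AIR_HU, HeadMask, VolumeHU

#: Interpolation order per pyramid level: linear on the three coarse levels,
#: cubic on the final one.
LEVEL_INTERP_ORDERS = (1, 1, 1, 3)


class RegistrationError(RuntimeError):
    """Raised when a registration stage cannot proceed."""


class InsufficientAlignments(RegistrationError):
    """Fewer valid coordinate alignments than the sampler minimum."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PyramidConfig:
    """Gaussian scale space: per-level smoothing sigmas in voxel units."""

    sigmas: tuple = (4.0, 2.0, 1.0, 0.5)

    def __post_init__(self) -> None:
        s = tuple(float(x) for x in self.sigmas)
        if len(s) < 1 or any(x <= 0 for x in s):
            raise ValueError("sigmas must be positive")
        if any(s[i] <= s[i + 1] for i in range(len(s) - 1)):
            raise ValueError("sigmas must be strictly decreasing")
        self.sigmas = s

    @property
    def levels(self) -> int:
        return len(self.sigmas)


@dataclass
class SamplerConfig:
    n_samples: int = 3000
    min_valid: int = 150
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.min_valid <= self.n_samples):
            raise ValueError("need 0 < min_valid <= n_samples")


@dataclass
class MetricConfig:
    n_bins: int = 32
    #: relative padding added to the frozen per-stage intensity range so the
    #: window stays differentiable at the extremes
    range_pad: float = 0.02

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass
class OptimizerConfig:
    """ASGD budgets and gain schedule.

    The per-stage iteration totals are distributed evenly over the pyramid
    levels.  The gain ``a`` is auto-scaled per level from probe gradients so
    the first parameter update has magnitude ``step_factor * sigma_level``
    (in mm); A and alpha follow the usual stochastic-approximation schedule.
    """

    iterations: dict = field(
        default_factory=lambda: {"rigid": 1500, "affine": 1500, "bspline": 2500}
    )
    A: float = 20.0
    alpha: float = 0.602
    step_factor: float = 0.3
    step_min_mm: float = 0.1
    step_max_mm: float = 3.0
    #: sigmoid for the adaptive time update
    f_min: float = -0.5
    f_max: float = 1.0
    omega: float = 0.25

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.iterations.values()):
            raise ValueError("iteration counts must be positive")


@dataclass
class RegistrationConfig:
    """Bundle of all registration settings."""

    pyramid: PyramidConfig = field(default_factory=PyramidConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    metric: MetricConfig = field(default_factory=MetricConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    bspline_spacing_mm: float = 20.0
    stages: tuple = ("rigid", "affine", "bspline")


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def _rot_axis(ax: int, th: float, deriv: bool = False) -> np.ndarray:
    c, s = math.cos(th), math.sin(th)
    m = np.zeros((3, 3)) if deriv else np.eye(3)
    i, j = [k for k in range(3) if k != ax]
    if deriv:
        m[i, i] = -s
        m[j, j] = -s
        m[i, j] = -c
        m[j, i] = c
    else:
        m[i, i] = c
        m[j, j] = c
        m[i, j] = -s
        m[j, i] = s
    return m


class RigidTransform:
    """Rotation (Euler angles about the volume axes) + translation.

    Angles are internally scaled by a characteristic radius so that all six
    parameters live in comparable mm units for the optimizer.
    """

    kind = "rigid"

    def __init__(self, center, rot_scale_mm: float = 80.0):
        self.center = np.asarray(center, dtype=np.float64).reshape(3)
        self.rot_scale = float(rot_scale_mm)
        self.angles = np.zeros(3)
        self.translation = np.zeros(3)

    # -- parameter vector (scaled, mm units) --
    @property
    def n_params(self) -> int:
        return 6

    def get_scaled(self) -> np.ndarray:
        return np.concatenate([self.angles * self.rot_scale, self.translation])

    def set_scaled(self, q: np.ndarray) -> None:
        q = np.asarray(q, dtype=np.float64)
        self.angles = q[:3] / self.rot_scale
        self.translation = q[3:].copy()

    def matrix(self) -> np.ndarray:
        return (
            _rot_axis(0, self.angles[0])
            @ _rot_axis(1, self.angles[1])
            @ _rot_axis(2, self.angles[2])
        )

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=np.float64)
        return (pts - self.center) @ self.matrix().T + self.center + self.translation

    def param_gradient(self, pts: np.ndarray, alpha: np.ndarray) -> np.ndarray:
        """g[k] = sum_s alpha[s] . dT/dq_k (pts[s]), scaled parameters."""
        d = pts - self.center
        g = np.empty(6)
        r = [_rot_axis(i, self.angles[i]) for i in range(3)]
        dr = [_rot_axis(i, self.angles[i], deriv=True) for i in range(3)]
        dmats = (
            dr[0] @ r[1] @ r[2],
            r[0] @ dr[1] @ r[2],
            r[0] @ r[1] @ dr[2],
        )
        for k in range(3):
            g[k] = np.einsum("si,si->", alpha, d @ dmats[k].T) / self.rot_scale
        g[3:] = alpha.sum(axis=0)
        return g

    def as_affine(self) -> tuple[np.ndarray, np.ndarray]:
        """(linear, offset) such that T(p) = linear @ p + offset."""
        m = self.matrix()
        return m, self.center + self.translation - m @ self.center

    def clip_params(self, q: np.ndarray) -> np.ndarray:
        return q


class AffineTransform:
    """Full linear map (rotation/scale/shear) + translation about a center."""

    kind = "affine"

    def __init__(self, center, rot_scale_mm: float = 80.0):
        self.center = np.asarray(center, dtype=np.float64).reshape(3)
        self.rot_scale = float(rot_scale_mm)
        self.linear = np.eye(3)
        self.translation = np.zeros(3)

    @property
    def n_params(self) -> int:
        return 12

    def get_scaled(self) -> np.ndarray:
        return np.concatenate([
            (self.linear - np.eye(3)).ravel() * self.rot_scale, self.translation
        ])

    def set_scaled(self, q: np.ndarray) -> None:
        q = np.asarray(q, dtype=np.float64)
        self.linear = np.eye(3) + q[:9].reshape(3, 3) / self.rot_scale
        self.translation = q[9:].copy()

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=np.float64)
        return (pts - self.center) @ self.linear.T + self.center + self.translation

    def param_gradient(self, pts: np.ndarray, alpha: np.ndarray) -> np.ndarray:
        d = pts - self.center
        g = np.empty(12)
        g[:9] = (alpha.T @ d).ravel() / self.rot_scale
        g[9:] = alpha.sum(axis=0)
        return g

    def clip_params(self, q: np.ndarray) -> np.ndarray:
        return q

    def as_affine(self) -> tuple[np.ndarray, np.ndarray]:
        return self.linear, self.center + self.translation - self.linear @ self.center

    @property
    def invertible(self) -> bool:
        return abs(np.linalg.det(self.linear)) > 1e-12


class BSplineTransform:
    """Cubic B-spline free-form deformation on a uniform control lattice.

    ``T(p) = p + d(p)`` where d blends the 4x4x4 surrounding control-point
    displacements with cubic B-spline weights.  With all coefficients zero
    the transform is exactly the identity.
    """

    kind = "bspline"

    def __init__(self, domain_lo, domain_hi, spacing_mm: float = 20.0):
        self.spacing = float(spacing_mm)
        lo = np.asarray(domain_lo, dtype=np.float64)
        hi = np.asarray(domain_hi, dtype=np.float64)
        # one-control-spacing margin on each side; full 4^3 support everywhere
        self.grid_origin = lo - self.spacing
        n = np.ceil((hi - lo) / self.spacing).astype(int) + 4
        self.coef = np.zeros((n[0], n[1], n[2], 3))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.coef.shape[:3]

    @property
    def n_params(self) -> int:
        return self.coef.size

    def get_scaled(self) -> np.ndarray:
        return self.coef.ravel().copy()

    def set_scaled(self, q: np.ndarray) -> None:
        self.coef = np.asarray(q, dtype=np.float64).reshape(self.coef.shape).copy()

    def _grid_coords(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=np.float64) - self.grid_origin) / self.spacing

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=np.float64).reshape(-1, 3)
        out = np.empty_like(pts)
        K.ffd_displacement(self.coef, np.ascontiguousarray(self._grid_coords(pts)), out)
        return out

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=np.float64)
        return pts + self.displacement(pts).reshape(pts.shape)

    def param_gradient(self, pts: np.ndarray, alpha: np.ndarray) -> np.ndarray:
        grad = np.zeros_like(self.coef)
        gz, gy, gx = self.grid_shape
        K.ffd_scatter(
            gz, gy, gx,
            np.ascontiguousarray(self._grid_coords(pts)),
            np.ascontiguousarray(alpha),
            grad,
        )
        return grad.ravel()

    def clip_params(self, q: np.ndarray) -> np.ndarray:
        # injectivity bound: coefficients below ~0.4x the control spacing
        # cannot fold the deformation (local displacements still reach
        # several mm at 20 mm spacing)
        bound = 0.4 * self.spacing
        return np.clip(q, -bound, bound)


@dataclass
class TransformChain:
    """Ordered transform stages; empty chain is the identity map."""

    stages: list = field(default_factory=list)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=np.float64)
        for st in self.stages:
            pts = st.apply(pts)
        return pts


# ---------------------------------------------------------------------------
# Chain serialization (plain text, replayable)
# ---------------------------------------------------------------------------

def save_chain(chain: TransformChain, path) -> None:
    lines = ["ctavg-transform-chain v1"]
    for st in chain.stages:
        lines.append(f"stage {st.kind}")
        if st.kind in ("rigid", "affine"):
            lines.append("center " + " ".join(f"{v:.17g}" for v in st.center))
            lines.append(f"rot_scale {st.rot_scale:.17g}")
            lines.append("params " + " ".join(f"{v:.17g}" for v in st.get_scaled()))
        else:
            lines.append("grid_origin " + " ".join(f"{v:.17g}" for v in st.grid_origin))
            lines.append(f"grid_spacing {st.spacing:.17g}")
            lines.append("grid_shape " + " ".join(str(v) for v in st.grid_shape))
            lines.append("coef " + " ".join(f"{v:.17g}" for v in st.coef.ravel()))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_chain(path) -> TransformChain:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("ctavg-transform-chain"):
        raise ValueError(f"not a transform-chain file: {path}")
    chain = TransformChain()
    i = 1
    while i < len(lines):
        kind = lines[i].split()[1]
        if kind in ("rigid", "affine"):
            center = np.array([float(v) for v in lines[i + 1].split()[1:]])
            rot_scale = float(lines[i + 2].split()[1])
            params = np.array([float(v) for v in lines[i + 3].split()[1:]])
            cls = RigidTransform if kind == "rigid" else AffineTransform
            st = cls(center, rot_scale)
            st.set_scaled(params)
            chain.stages.append(st)
            i += 4
        elif kind == "bspline":
            origin = np.array([float(v) for v in lines[i + 1].split()[1:]])
            spacing = float(lines[i + 2].split()[1])
            shape = tuple(int(v) for v in lines[i + 3].split()[1:])
            coef = np.array([float(v) for v in lines[i + 4].split()[1:]]).reshape(shape + (3,))
            st = BSplineTransform(origin + spacing, origin + spacing, spacing)
            st.grid_origin = origin
            st.coef = coef
            chain.stages.append(st)
            i += 5
        else:
            raise ValueError(f"unknown stage kind {kind!r}")
    return chain


# ---------------------------------------------------------------------------
# Scale space, sampling, interpolation
# ---------------------------------------------------------------------------

def build_pyramid(vol: VolumeHU, cfg: PyramidConfig | None = None) -> list[VolumeHU]:
    """Smoothing-only Gaussian scale space on the input grid.

    Level L is the input convolved with an isotropic Gaussian of
    ``sigmas[L]`` voxels; the grid is never downsampled, which keeps all
    coordinate bookkeeping on the original volume.
    """
    cfg = cfg or PyramidConfig()
    return [
        VolumeHU(
            ndimage.gaussian_filter(vol.voxels, sigma=s, mode="nearest"),
            vol.spacing.copy(),
            vol.origin.copy(),
        )
        for s in cfg.sigmas
    ]


def mask_sample_indices(mask: HeadMask | np.ndarray) -> np.ndarray:
    m = mask.mask if isinstance(mask, HeadMask) else np.asarray(mask, dtype=bool)
    idx = np.argwhere(m)
    if len(idx) == 0:
        raise RegistrationError("empty sampling mask")
    return idx


def sample_coordinates(
    mask: HeadMask | np.ndarray,
    grid: VolumeHU,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    idx: np.ndarray | None = None,
) -> np.ndarray:
    """Draw ``n_samples`` continuous physical points uniformly over the mask.

    A voxel is drawn uniformly among mask voxels, then jittered uniformly
    within its physical extent, so points are continuous rather than voxel
    centers.  A fresh draw is taken every optimizer iteration.
    """
    if idx is None:
        idx = mask_sample_indices(mask)
    pick = idx[rng.integers(0, len(idx), size=cfg.n_samples)]
    jitter = rng.uniform(-0.5, 0.5, size=(cfg.n_samples, 3))
    return grid.index_to_world(pick + jitter)


class Interpolator:
    """Callable image interpolant with analytic spatial gradients (per mm).

    order 1: trilinear; order 3: cubic B-spline on prefiltered coefficients
    (interpolation at voxel centers reproduces voxel values).
    """

    def __init__(self, vol: VolumeHU, order: int):
        if order not in (1, 3):
            raise ValueError("order must be 1 or 3")
        self.vol = vol
        self.order = order
        if order == 3:
            self.data = ndimage.spline_filter(vol.voxels, order=3, mode="mirror")
        else:
            self.data = np.ascontiguousarray(vol.voxels)

    def __call__(self, pts_mm: np.ndarray):
        """Returns (values, gradients_mm, valid) for physical points (N, 3)."""
        pts = np.ascontiguousarray(self.vol.world_to_index(np.asarray(pts_mm).reshape(-1, 3)))
        n = len(pts)
        vals = np.empty(n)
        grads = np.empty((n, 3))
        valid = np.empty(n, dtype=np.bool_)
        if self.order == 1:
            K.interp_trilinear(self.data, pts, vals, grads, valid)
        else:
            K.interp_cubic(self.data, pts, vals, grads, valid)
        grads /= self.vol.spacing  # voxel -> mm
        return vals, grads, valid


def interpolate(vol: VolumeHU, points_mm: np.ndarray, order: int = 3) -> np.ndarray:
    """Interpolate the volume at physical points; NaN marks out-of-domain.

    Convenience wrapper around :class:`Interpolator` matching the one-shot
    call signature; for repeated evaluation build the Interpolator once.
    """
    pts = np.asarray(points_mm, dtype=np.float64)
    single = pts.ndim == 1
    vals, _, valid = Interpolator(vol, order)(pts.reshape(-1, 3))
    vals = vals.copy()
    vals[~valid] = np.nan
    return float(vals[0]) if single else vals


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------

def _bin_positions(vals: np.ndarray, vmin: float, vmax: float, n_bins: int):
    """Map intensities linearly into Parzen bin space [1, n_bins-2]."""
    scale = (n_bins - 3) / (vmax - vmin)
    u = 1.0 + (vals - vmin) * scale
    inside = (u >= 1.0) & (u <= n_bins - 2.0)
    return np.clip(u, 1.0, n_bins - 2.0), scale, inside


def _padded_range(vals: np.ndarray, cfg: MetricConfig) -> tuple[float, float]:
    vmin, vmax = float(np.min(vals)), float(np.max(vals))
    pad = (vmax - vmin) * cfg.range_pad + 1e-12
    return vmin - pad, vmax + pad


def mutual_information(
    fixed_samples: np.ndarray,
    moving_samples: np.ndarray,
    cfg: MetricConfig | None = None,
) -> float:
    """Parzen-window mutual information of paired intensity samples (nats).

    Each channel's bin mapping uses that sample list's min/max.  A
    degenerate channel (max == min) carries no information: MI = 0.
    """
    cfg = cfg or MetricConfig()
    f = np.asarray(fixed_samples, dtype=np.float64).ravel()
    m = np.asarray(moving_samples, dtype=np.float64).ravel()
    if f.shape != m.shape:
        raise ValueError("paired sample lists must have equal length")
    if len(f) == 0 or np.min(f) == np.max(f) or np.min(m) == np.max(m):
        return 0.0
    fu, _, _ = _bin_positions(f, *_padded_range(f, cfg), cfg.n_bins)
    mu, _, _ = _bin_positions(m, *_padded_range(m, cfg), cfg.n_bins)
    mi, _ = K.parzen_mi_alpha(fu, mu, cfg.n_bins)
    return float(mi)


def parzen_joint_histogram(
    fixed_samples: np.ndarray, moving_samples: np.ndarray, cfg: MetricConfig | None = None
) -> np.ndarray:
    """Normalized joint Parzen histogram (for reports and cross-checks)."""
    cfg = cfg or MetricConfig()
    f = np.asarray(fixed_samples, dtype=np.float64).ravel()
    m = np.asarray(moving_samples, dtype=np.float64).ravel()
    fu, _, _ = _bin_positions(f, *_padded_range(f, cfg), cfg.n_bins)
    mu, _, _ = _bin_positions(m, *_padded_range(m, cfg), cfg.n_bins)
    return K.parzen_joint(fu, mu, cfg.n_bins)


def metric_value_and_gradient(
    stage,
    pre_pts: np.ndarray,
    fixed_vals: np.ndarray,
    moving_interp: Interpolator,
    cfg: MetricConfig,
    f_range: tuple[float, float],
    m_range: tuple[float, float],
    min_valid: int = 1,
):
    """Cost (−MI) and its analytic gradient w.r.t. the stage's parameters.

    ``pre_pts`` are fixed-space sample points already mapped through the
    frozen preceding stages; ``fixed_vals`` the fixed-image intensities at
    the original sample positions.  The intensity-to-bin mappings are
    frozen (``f_range``/``m_range``) so the function is smooth in the
    parameters; samples mapping outside the moving domain are dropped, and
    an :class:`InsufficientAlignments` error is raised if fewer than
    ``min_valid`` remain.
    """
    out_pts = stage.apply(pre_pts)
    m_vals, m_grads, valid = moving_interp(out_pts)
    n_valid = int(valid.sum())
    if n_valid < min_valid:
        raise InsufficientAlignments(
            f"only {n_valid} valid coordinate alignments (minimum {min_valid})"
        )
    fv = fixed_vals[valid]
    mv = m_vals[valid]
    if f_range[1] <= f_range[0] or m_range[1] <= m_range[0]:
        return 0.0, np.zeros(stage.n_params)
    fu, _, _ = _bin_positions(fv, f_range[0], f_range[1], cfg.n_bins)
    mu, m_scale, m_inside = _bin_positions(mv, m_range[0], m_range[1], cfg.n_bins)
    mi, dmi_dmu = K.parzen_mi_alpha(fu, mu, cfg.n_bins)
    # chain rule: cost = -MI, mu = 1 + (m - mmin)*scale (zero slope if clamped)
    dcost_dm = np.zeros(len(pre_pts))
    dcost_dm[valid] = -dmi_dmu * m_scale * m_inside
    alpha = dcost_dm[:, None] * m_grads
    grad = stage.param_gradient(pre_pts, alpha)
    return -mi, grad


# ---------------------------------------------------------------------------
# ASGD optimizer
# ---------------------------------------------------------------------------

def asgd_optimize(
    stage,
    fixed_interp: Interpolator,
    moving_interp: Interpolator,
    mask_idx: np.ndarray,
    grid: VolumeHU,
    sampler: SamplerConfig,
    metric: MetricConfig,
    opt: OptimizerConfig,
    rng: np.random.Generator,
    n_iters: int,
    pre_chain: TransformChain | None = None,
    step_mm: float = 1.0,
) -> np.ndarray:
    """Optimize one transform stage with adaptive stochastic gradient descent.

    Deterministic given ``rng``'s seed.  Returns the final scaled parameter
    vector (also written into ``stage``).
    """
    pre = pre_chain or TransformChain()

    def draw():
        pts = sample_coordinates(None, grid, sampler, rng, idx=mask_idx)
        f_vals, _, f_valid = fixed_interp(pts)
        pts = pts[f_valid]
        return pts, f_vals[f_valid]

    # freeze the intensity-to-bin mapping for this stage/level
    pts0, f0 = draw()
    pre0 = pre.apply(pts0)
    m0, _, v0 = moving_interp(stage.apply(pre0))
    if int(v0.sum()) < sampler.min_valid:
        raise InsufficientAlignments(
            f"only {int(v0.sum())} valid coordinate alignments (minimum {sampler.min_valid})"
        )
    f_range = _padded_range(f0, metric)
    m_range = _padded_range(m0[v0], metric)

    # probe gradients to auto-scale the gain
    gnorm = 0.0
    n_probe = 5
    for _ in range(n_probe):
        pts, fv = draw()
        _, g = metric_value_and_gradient(
            stage, pre.apply(pts), fv, moving_interp, metric,
            f_range, m_range, sampler.min_valid,
        )
        gnorm += float(np.max(np.abs(g)))
    gnorm /= n_probe
    if gnorm <= 1e-300:
        return stage.get_scaled()
    a = step_mm * (opt.A + 1.0) ** opt.alpha / gnorm

    q = stage.get_scaled()
    t = 0.0
    g_prev = None
    # Polyak–Ruppert tail averaging: the stochastic iterates oscillate
    # around the optimum; averaging the last half of the trajectory cancels
    # the zero-mean oscillation and sharpens the returned estimate.
    tail_start = n_iters - max(1, n_iters // 2)
    q_acc = np.zeros_like(q)
    n_acc = 0
    for it in range(n_iters):
        pts, fv = draw()
        _, g = metric_value_and_gradient(
            stage, pre.apply(pts), fv, moving_interp, metric,
            f_range, m_range, sampler.min_valid,
        )
        decay = ((opt.A + 1.0) / (opt.A + t)) ** opt.alpha
        gamma = a * decay / (opt.A + 1.0) ** opt.alpha
        # trust cap: no parameter moves more than the (decaying) level step,
        # so a gain calibrated near an optimum cannot blow up once the true
        # gradient appears
        gmax = float(np.max(np.abs(g)))
        cap = step_mm * decay
        if gmax > 0 and gamma * gmax > cap:
            gamma = cap / gmax
        q = stage.clip_params(q - gamma * g)
        stage.set_scaled(q)
        if g_prev is not None:
            denom = float(np.linalg.norm(g) * np.linalg.norm(g_prev))
            x = -float(np.dot(g, g_prev)) / denom if denom > 0 else 0.0
            t = max(0.0, t + opt.f_min + (opt.f_max - opt.f_min) / (1.0 + math.exp(-x / opt.omega)))
        g_prev = g
        if it >= tail_start:
            q_acc += q
            n_acc += 1
    q = q_acc / n_acc
    stage.set_scaled(q)
    return q


# ---------------------------------------------------------------------------
# Multi-stage, multi-level registration driver
# ---------------------------------------------------------------------------

def _default_mask(fixed: VolumeHU) -> HeadMask:
    return HeadMask(fixed.voxels > -500.0)


def register(
    fixed: VolumeHU,
    moving: VolumeHU,
    config: RegistrationConfig | None = None,
    seed: int = 0,
    fixed_mask: HeadMask | None = None,
) -> TransformChain:
    """Full rigid → affine → B-spline registration of preprocessed volumes.

    Each stage runs the Gaussian scale-space schedule (linear interpolation
    on the coarse levels, cubic on the final one), initialized on top of
    the frozen preceding stages, and its iteration budget is split evenly
    over the levels.  Returns the chain mapping fixed-space physical points
    to moving-space physical points.  Fully deterministic given ``seed``.
    """
    cfg = config or RegistrationConfig()
    mask = fixed_mask or _default_mask(fixed)
    if mask.mask.shape != fixed.shape:
        raise RegistrationError("fixed mask shape mismatch")
    mask_idx = mask_sample_indices(mask)
    centroid = fixed.index_to_world(mask_idx.mean(axis=0))
    # characteristic head radius for rotation/linear parameter scaling
    extents = (mask_idx.max(axis=0) - mask_idx.min(axis=0)) * fixed.spacing
    rot_scale = max(float(np.mean(extents)) / 2.0, 1.0)

    fixed_pyr = build_pyramid(fixed, cfg.pyramid)
    moving_pyr = build_pyramid(moving, cfg.pyramid)
    levels = cfg.pyramid.levels
    orders = LEVEL_INTERP_ORDERS if levels == len(LEVEL_INTERP_ORDERS) else (
        (1,) * (levels - 1) + (3,)
    )

    chain = TransformChain()
    for s_idx, kind in enumerate(cfg.stages):
        if kind == "rigid":
            stage = RigidTransform(centroid, rot_scale)
        elif kind == "affine":
            stage = AffineTransform(centroid, rot_scale)
        elif kind == "bspline":
            lo, hi = fixed.world_bounds()
            corners = np.array([[a, b, c] for a in (lo[0], hi[0])
                                for b in (lo[1], hi[1]) for c in (lo[2], hi[2])])
            mapped = chain.apply(corners)
            stage = BSplineTransform(mapped.min(axis=0), mapped.max(axis=0),
                                     cfg.bspline_spacing_mm)
        else:
            raise RegistrationError(f"unknown stage kind {kind!r}")

        total = cfg.optimizer.iterations.get(kind, 1500)
        per_level = max(1, int(round(total / levels)))
        mean_sp = float(np.mean(fixed.spacing))
        for lev in range(levels):
            order = orders[lev]
            step = float(np.clip(cfg.optimizer.step_factor * cfg.pyramid.sigmas[lev] * mean_sp,
                                 cfg.optimizer.step_min_mm, cfg.optimizer.step_max_mm))
            rng = np.random.default_rng(
                np.random.SeedSequence((int(seed) & 0x7FFFFFFF, s_idx, lev))
            )
            try:
                asgd_optimize(
                    stage,
                    Interpolator(fixed_pyr[lev], order),
                    Interpolator(moving_pyr[lev], order),
                    mask_idx,
                    fixed,
                    cfg.sampler,
                    cfg.metric,
                    cfg.optimizer,
                    rng,
                    per_level,
                    pre_chain=chain,
                    step_mm=step,
                )
            except RegistrationError as exc:
                raise RegistrationError(f"stage {kind!r} level {lev}: {exc}") from exc
        chain.stages.append(stage)
    return chain


def resample(
    moving: VolumeHU,
    chain: TransformChain,
    target_grid: VolumeHU,
    fill_value: float = AIR_HU,
) -> VolumeHU:
    """Pull the moving image onto the target grid through the chain.

    Output voxel x takes the cubic-B-spline-interpolated moving intensity
    at chain(x); points mapping outside the moving domain are filled with
    air (−1000 HU).
    """
    shape = target_grid.shape
    idx = np.indices(shape).reshape(3, -1).T
    pts = target_grid.index_to_world(idx)
    mapped = chain.apply(pts)
    interp = Interpolator(moving, 3)
    vals, _, valid = interp(mapped)
    vals[~valid] = fill_value
    return VolumeHU(vals.reshape(shape), target_grid.spacing.copy(), target_grid.origin.copy())
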