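"""Independent reference implementations used as test oracles.

These deliberately re-derive quantities with naive, readable numpy code
(dense kernels, explicit sums) so they share no code path with the
package's compiled implementations.
"""

import numpy as np
from scipy import ndimage


def bspline3(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline kernel, support |t| < 2."""
    a = np.abs(np.asarray(t, dtype=np.float64))
    return np.where(
        a < 1.0, (4.0 - 6.0 * a**2 + 3.0 * a**3) / 6.0,
        np.where(a < 2.0, (2.0 - a) ** 3 / 6.0, 0.0),
    )


def parzen_mi(f: np.ndarray, m: np.ndarray, n_bins: int = 32, pad: float = 0.02) -> float:
    """Brute-force Parzen-window MI: dense kernel matrices + explicit sums."""
    def positions(v):
        vmin, vmax = v.min(), v.max()
        p = (vmax - vmin) * pad + 1e-12
        vmin, vmax = vmin - p, vmax + p
        scale = (n_bins - 3) / (vmax - vmin)
        return np.clip(1.0 + (v - vmin) * scale, 1.0, n_bins - 2.0)

    fu, mu = positions(np.asarray(f, float)), positions(np.asarray(m, float))
    bins = np.arange(n_bins)
    wf = bspline3(bins[None, :] - fu[:, None])
    wm = bspline3(bins[None, :] - mu[:, None])
    h = wf.T @ wm / len(fu)
    pf, pm = h.sum(axis=1), h.sum(axis=0)
    nz = h > 0
    return float((h[nz] * np.log(h[nz] / np.outer(pf, pm)[nz])).sum())


def parzen_entropies(f: np.ndarray, m: np.ndarray, n_bins: int = 32):
    """(H_fixed, H_moving, H_joint) from the same brute-force histogram."""
    def positions(v):
        vmin, vmax = v.min(), v.max()
        p = (vmax - vmin) * 0.02 + 1e-12
        vmin, vmax = vmin - p, vmax + p
        scale = (n_bins - 3) / (vmax - vmin)
        return np.clip(1.0 + (v - vmin) * scale, 1.0, n_bins - 2.0)

    fu, mu = positions(np.asarray(f, float)), positions(np.asarray(m, float))
    bins = np.arange(n_bins)
    h = (bspline3(bins[None, :] - fu[:, None]).T
         @ bspline3(bins[None, :] - mu[:, None])) / len(fu)

    def H(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    return H(h.sum(axis=1)), H(h.sum(axis=0)), H(h.ravel())


def separable_cubic_interp(vol: np.ndarray, pts_vox: np.ndarray) -> np.ndarray:
    """Naive cubic B-spline interpolation: prefilter via scipy, then an
    explicit 4x4x4 weighted sum per point with mirror indexing."""
    coef = ndimage.spline_filter(vol, order=3, mode="mirror")
    n = np.array(vol.shape)

    def mirror(i, size):
        period = 2 * (size - 1)
        i = np.mod(i, period)
        i = np.where(i < 0, i + period, i)
        return np.where(i > size - 1, period - i, i)

    out = np.empty(len(pts_vox))
    for k, p in enumerate(np.asarray(pts_vox, float)):
        b = np.minimum(np.floor(p).astype(int), n - 2)
        acc = 0.0
        for a in range(4):
            for bb in range(4):
                for c in range(4):
                    idx = (int(mirror(b[0] - 1 + a, n[0])),
                           int(mirror(b[1] - 1 + bb, n[1])),
                           int(mirror(b[2] - 1 + c, n[2])))
                    w = (bspline3(b[0] - 1 + a - p[0])
                         * bspline3(b[1] - 1 + bb - p[1])
                         * bspline3(b[2] - 1 + c - p[2]))
                    acc += coef[idx] * float(w)
        out[k] = acc
    return out


def gaussian_impulse_kernel(sigma: float, radius: int) -> np.ndarray:
    """Discrete normalized 3-D Gaussian: outer product of sampled 1-D kernels."""
    x = np.arange(-radius, radius + 1)
    k1 = np.exp(-0.5 * (x / sigma) ** 2)
    k1 /= k1.sum()
    return k1[:, None, None] * k1[None, :, None] * k1[None, None, :]


def best_one_to_one_matching(cands: np.ndarray, truths: np.ndarray, max_dist: float) -> int:
    """Maximum number of one-to-one candidate-truth pairs within max_dist,
    by exhaustive enumeration (small inputs only)."""
    from itertools import permutations

    cands = np.asarray(cands, float).reshape(-1, 3)
    truths = np.asarray(truths, float).reshape(-1, 3)
    nc, nt = len(cands), len(truths)
    if nc == 0 or nt == 0:
        return 0
    best = 0
    idx = list(range(nc)) + [-1] * max(0, nt - nc)
    for perm in set(permutations(idx, nt)):
        tp = 0
        for j, i in enumerate(perm):
            if i >= 0 and np.linalg.norm(cands[i] - truths[j]) <= max_dist:
                tp += 1
        best = max(best, tp)
    return best
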