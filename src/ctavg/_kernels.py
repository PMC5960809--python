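"""Compiled inner loops for registration.

Everything here is numerics on plain arrays: image interpolation (trilinear
and cubic B-spline with analytic spatial gradients), evaluation/scatter of
a cubic B-spline free-form deformation lattice, and the Parzen-window joint
histogram behind the mutual-information metric.  The cubic B-spline basis
on a uniform knot grid, for fractional offset ``s = u - floor(u)`` in
[0, 1), has the four non-zero weights

    w0 = (1-s)^3/6,  w1 = (3s^3-6s^2+4)/6,
    w2 = (-3s^3+3s^2+3s+1)/6,  w3 = s^3/6

which sum to 1 (partition of unity); their derivatives sum to 0.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _cubic_w(s, w, dw):
    s2 = s * s
    s3 = s2 * s
    w[0] = (1.0 - 3.0 * s + 3.0 * s2 - s3) / 6.0
    w[1] = (3.0 * s3 - 6.0 * s2 + 4.0) / 6.0
    w[2] = (-3.0 * s3 + 3.0 * s2 + 3.0 * s + 1.0) / 6.0
    w[3] = s3 / 6.0
    dw[0] = -0.5 * (1.0 - s) * (1.0 - s)
    dw[1] = 1.5 * s2 - 2.0 * s
    dw[2] = -1.5 * s2 + s + 0.5
    dw[3] = 0.5 * s2


@njit(cache=True)
def interp_trilinear(vol, pts, vals, grads, valid):
    """Trilinear interpolation with analytic gradient (voxel units).

    pts: (N, 3) continuous voxel coordinates.  Points outside the grid are
    flagged invalid; their value/gradient are left at 0.
    """
    nz, ny, nx = vol.shape
    n = pts.shape[0]
    for i in range(n):
        z = pts[i, 0]
        y = pts[i, 1]
        x = pts[i, 2]
        # the voxel extent reaches half a voxel beyond the outermost centers
        if (z < -0.5 or z > nz - 0.5 or y < -0.5 or y > ny - 0.5
                or x < -0.5 or x > nx - 0.5):
            valid[i] = False
            vals[i] = 0.0
            grads[i, 0] = 0.0
            grads[i, 1] = 0.0
            grads[i, 2] = 0.0
            continue
        valid[i] = True
        z = min(max(z, 0.0), nz - 1.0)
        y = min(max(y, 0.0), ny - 1.0)
        x = min(max(x, 0.0), nx - 1.0)
        iz = int(np.floor(z))
        iy = int(np.floor(y))
        ix = int(np.floor(x))
        if iz > nz - 2:
            iz = nz - 2
        if iy > ny - 2:
            iy = ny - 2
        if ix > nx - 2:
            ix = nx - 2
        tz = z - iz
        ty = y - iy
        tx = x - ix
        c000 = vol[iz, iy, ix]
        c001 = vol[iz, iy, ix + 1]
        c010 = vol[iz, iy + 1, ix]
        c011 = vol[iz, iy + 1, ix + 1]
        c100 = vol[iz + 1, iy, ix]
        c101 = vol[iz + 1, iy, ix + 1]
        c110 = vol[iz + 1, iy + 1, ix]
        c111 = vol[iz + 1, iy + 1, ix + 1]
        c00 = c000 + (c001 - c000) * tx
        c01 = c010 + (c011 - c010) * tx
        c10 = c100 + (c101 - c100) * tx
        c11 = c110 + (c111 - c110) * tx
        c0 = c00 + (c01 - c00) * ty
        c1 = c10 + (c11 - c10) * ty
        vals[i] = c0 + (c1 - c0) * tz
        grads[i, 0] = c1 - c0
        g00 = (c001 - c000) + ((c011 - c010) - (c001 - c000)) * ty
        g10 = (c101 - c100) + ((c111 - c110) - (c101 - c100)) * ty
        grads[i, 2] = g00 + (g10 - g00) * tz
        d0 = c01 - c00
        d1 = c11 - c10
        grads[i, 1] = d0 + (d1 - d0) * tz


@njit(cache=True, inline="always")
def _mirror(i, n):
    """Reflect an index into [0, n-1] (scipy 'mirror' convention)."""
    if n == 1:
        return 0
    period = 2 * (n - 1)
    i = i % period
    if i < 0:
        i += period
    if i > n - 1:
        i = period - i
    return i


@njit(cache=True)
def interp_cubic(coef, pts, vals, grads, valid):
    """Cubic B-spline interpolation of prefiltered coefficients.

    pts: (N, 3) continuous voxel coordinates.  The whole grid [0, n-1] is
    valid; taps beyond the edge use mirror reflection, matching the
    mirror-mode prefilter so voxel centers (including boundary ones)
    reproduce voxel values.
    """
    nz, ny, nx = coef.shape
    n = pts.shape[0]
    wz = np.empty(4)
    wy = np.empty(4)
    wx = np.empty(4)
    dz = np.empty(4)
    dy = np.empty(4)
    dx = np.empty(4)
    for i in range(n):
        z = pts[i, 0]
        y = pts[i, 1]
        x = pts[i, 2]
        if (z < -0.5 or z > nz - 0.5 or y < -0.5 or y > ny - 0.5
                or x < -0.5 or x > nx - 0.5):
            valid[i] = False
            vals[i] = 0.0
            grads[i, 0] = 0.0
            grads[i, 1] = 0.0
            grads[i, 2] = 0.0
            continue
        valid[i] = True
        z = min(max(z, 0.0), nz - 1.0)
        y = min(max(y, 0.0), ny - 1.0)
        x = min(max(x, 0.0), nx - 1.0)
        bz = min(int(np.floor(z)), nz - 2)
        by = min(int(np.floor(y)), ny - 2)
        bx = min(int(np.floor(x)), nx - 2)
        _cubic_w(z - bz, wz, dz)
        _cubic_w(y - by, wy, dy)
        _cubic_w(x - bx, wx, dx)
        v = 0.0
        gz = 0.0
        gy = 0.0
        gx = 0.0
        for a in range(4):
            iz = _mirror(bz - 1 + a, nz)
            for b in range(4):
                iy = _mirror(by - 1 + b, ny)
                row_v = 0.0
                row_dx = 0.0
                for c in range(4):
                    cc = coef[iz, iy, _mirror(bx - 1 + c, nx)]
                    row_v += cc * wx[c]
                    row_dx += cc * dx[c]
                wyb = wy[b]
                v += row_v * wz[a] * wyb
                gz += row_v * dz[a] * wyb
                gy += row_v * wz[a] * dy[b]
                gx += row_dx * wz[a] * wyb
        vals[i] = v
        grads[i, 0] = gz
        grads[i, 1] = gy
        grads[i, 2] = gx


@njit(cache=True)
def ffd_displacement(coef, pts_grid, out):
    """Displacement of a cubic B-spline lattice at grid coordinates.

    coef: (gz, gy, gx, 3) control-point displacements (mm);
    pts_grid: (N, 3) coordinates in lattice units;
    out: (N, 3).  Coordinates outside the supported range are clamped,
    extending the boundary deformation.
    """
    gz, gy, gx = coef.shape[0], coef.shape[1], coef.shape[2]
    n = pts_grid.shape[0]
    wz = np.empty(4)
    wy = np.empty(4)
    wx = np.empty(4)
    dz = np.empty(4)
    dy = np.empty(4)
    dx = np.empty(4)
    for i in range(n):
        z = min(max(pts_grid[i, 0], 1.0), gz - 2.0)
        y = min(max(pts_grid[i, 1], 1.0), gy - 2.0)
        x = min(max(pts_grid[i, 2], 1.0), gx - 2.0)
        bz = min(int(np.floor(z)), gz - 3)
        by = min(int(np.floor(y)), gy - 3)
        bx = min(int(np.floor(x)), gx - 3)
        _cubic_w(z - bz, wz, dz)
        _cubic_w(y - by, wy, dy)
        _cubic_w(x - bx, wx, dx)
        d0 = 0.0
        d1 = 0.0
        d2 = 0.0
        for a in range(4):
            for b in range(4):
                wab = wz[a] * wy[b]
                for c in range(4):
                    w = wab * wx[c]
                    d0 += coef[bz - 1 + a, by - 1 + b, bx - 1 + c, 0] * w
                    d1 += coef[bz - 1 + a, by - 1 + b, bx - 1 + c, 1] * w
                    d2 += coef[bz - 1 + a, by - 1 + b, bx - 1 + c, 2] * w
        out[i, 0] = d0
        out[i, 1] = d1
        out[i, 2] = d2


@njit(cache=True)
def ffd_scatter(shape_z, shape_y, shape_x, pts_grid, alpha, grad):
    """Accumulate dCost/d(control point) for the FFD lattice.

    alpha: (N, 3) = dCost/d(output point) per sample; grad: (gz, gy, gx, 3)
    preallocated zeros, filled with sum_s alpha[s] * w_cp(x_s).
    """
    n = pts_grid.shape[0]
    wz = np.empty(4)
    wy = np.empty(4)
    wx = np.empty(4)
    dz = np.empty(4)
    dy = np.empty(4)
    dx = np.empty(4)
    for i in range(n):
        a0 = alpha[i, 0]
        a1 = alpha[i, 1]
        a2 = alpha[i, 2]
        if a0 == 0.0 and a1 == 0.0 and a2 == 0.0:
            continue
        z = min(max(pts_grid[i, 0], 1.0), shape_z - 2.0)
        y = min(max(pts_grid[i, 1], 1.0), shape_y - 2.0)
        x = min(max(pts_grid[i, 2], 1.0), shape_x - 2.0)
        bz = min(int(np.floor(z)), shape_z - 3)
        by = min(int(np.floor(y)), shape_y - 3)
        bx = min(int(np.floor(x)), shape_x - 3)
        _cubic_w(z - bz, wz, dz)
        _cubic_w(y - by, wy, dy)
        _cubic_w(x - bx, wx, dx)
        for a in range(4):
            for b in range(4):
                wab = wz[a] * wy[b]
                for c in range(4):
                    w = wab * wx[c]
                    grad[bz - 1 + a, by - 1 + b, bx - 1 + c, 0] += a0 * w
                    grad[bz - 1 + a, by - 1 + b, bx - 1 + c, 1] += a1 * w
                    grad[bz - 1 + a, by - 1 + b, bx - 1 + c, 2] += a2 * w


@njit(cache=True)
def parzen_joint(fu, mu, nbins):
    """Joint histogram with cubic B-spline Parzen windows on both axes.

    fu, mu: (N,) continuous bin positions, expected in [1, nbins-2]
    (clamped here for safety).  Returns the normalized joint density.
    """
    h = np.zeros((nbins, nbins))
    n = fu.shape[0]
    wf = np.empty(4)
    wm = np.empty(4)
    df = np.empty(4)
    dm = np.empty(4)
    for s in range(n):
        f = min(max(fu[s], 1.0), nbins - 2.0)
        m = min(max(mu[s], 1.0), nbins - 2.0)
        bf = min(int(np.floor(f)), nbins - 3)
        bm = min(int(np.floor(m)), nbins - 3)
        _cubic_w(f - bf, wf, df)
        _cubic_w(m - bm, wm, dm)
        for a in range(4):
            for b in range(4):
                h[bf - 1 + a, bm - 1 + b] += wf[a] * wm[b]
    if n > 0:
        h /= n
    return h


@njit(cache=True)
def parzen_mi_alpha(fu, mu, nbins):
    """Mutual information (nats) and its derivative w.r.t. each moving
    sample's bin position.

    Returns (mi, dmi_dmu) where dmi_dmu[s] = dMI / d mu[s].
    """
    n = fu.shape[0]
    h = parzen_joint(fu, mu, nbins)
    pf = np.zeros(nbins)
    pm = np.zeros(nbins)
    for j in range(nbins):
        for k in range(nbins):
            pf[j] += h[j, k]
            pm[k] += h[j, k]
    mi = 0.0
    logterm = np.zeros((nbins, nbins))
    for j in range(nbins):
        if pf[j] <= 0.0:
            continue
        for k in range(nbins):
            if h[j, k] > 0.0 and pm[k] > 0.0:
                lt = np.log(h[j, k] / (pf[j] * pm[k]))
                logterm[j, k] = lt
                mi += h[j, k] * lt
    dmi = np.zeros(n)
    if n == 0:
        return mi, dmi
    wf = np.empty(4)
    wm = np.empty(4)
    df = np.empty(4)
    dm = np.empty(4)
    inv_n = 1.0 / n
    for s in range(n):
        f = min(max(fu[s], 1.0), nbins - 2.0)
        m = min(max(mu[s], 1.0), nbins - 2.0)
        bf = min(int(np.floor(f)), nbins - 3)
        bm = min(int(np.floor(m)), nbins - 3)
        _cubic_w(f - bf, wf, df)
        _cubic_w(m - bm, wm, dm)
        acc = 0.0
        for a in range(4):
            wa = wf[a]
            if wa == 0.0:
                continue
            for b in range(4):
                acc += wa * dm[b] * logterm[bf - 1 + a, bm - 1 + b]
        dmi[s] = acc * inv_n
    return mi, dmi
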