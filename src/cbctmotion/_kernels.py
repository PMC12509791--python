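"""Low-level numba kernels: Joseph ray tracing and trilinear warps.

The forward projector integrates the trilinear image model along each
source-to-pixel ray by stepping over the voxel planes of the ray's dominant
axis (Joseph's method).  The backprojector scatters with *identical* weights
and segment lengths, so it is the exact algebraic transpose of the forward
projector — a property the optimization and the SIRT normalizations rely on.

All kernels use zero ("air") boundary conditions: samples outside the grid
contribute nothing, and splats landing outside the grid are dropped.
Displacements are expressed in voxel units here; unit conversion from mm
happens in the calling modules.

Per ray, the in-plane sample coordinates are affine in the slice index, so
the inner loops are add-and-gather only; the volume is viewed with the
dominant axis first (a stride trick, no copy) to keep indexing direct.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "joseph_forward",
    "joseph_backward",
    "pull3",
    "pull3_grad",
    "push3",
    "chain_accumulate",
]


@njit(cache=True, fastmath=True, inline="always")
def _ray_setup(shape0, shape1, shape2, origin, voxsize, sx, sy, sz, px, py, pz):
    """Dominant axis + affine slice stepping setup shared by gather/scatter.

    Returns (m, n_m, pa0, dpa, pb0, dpb, seglen); the caller views the
    volume with axes (m, a, b) where a, b follow m cyclically.
    """
    dx = px - sx
    dy = py - sy
    dz = pz - sz
    ax = abs(dx) / voxsize[0]
    ay = abs(dy) / voxsize[1]
    az = abs(dz) / voxsize[2]
    if ax >= ay and ax >= az:
        m = 0
    elif ay >= az:
        m = 1
    else:
        m = 2
    d0 = dx if m == 0 else (dy if m == 1 else dz)
    if d0 == 0.0:
        return m, 0, 0.0, 0.0, 0.0, 0.0, 0.0
    a = (m + 1) % 3
    b = (m + 2) % 3
    s = (sx, sy, sz)
    d = (dx, dy, dz)
    norm = np.sqrt(dx * dx + dy * dy + dz * dz)
    seglen = voxsize[m] * norm / abs(d0)
    t0 = (origin[m] - s[m]) / d0
    dt = voxsize[m] / d0
    pa0 = (s[a] + t0 * d[a] - origin[a]) / voxsize[a]
    dpa = dt * d[a] / voxsize[a]
    pb0 = (s[b] + t0 * d[b] - origin[b]) / voxsize[b]
    dpb = dt * d[b] / voxsize[b]
    nm = shape0 if m == 0 else (shape1 if m == 1 else shape2)
    return m, nm, pa0, dpa, pb0, dpb, seglen


@njit(cache=True, fastmath=True, inline="always")
def _gather_line(volt, nm, pa0, dpa, pb0, dpb, seglen):
    na = volt.shape[1]
    nb = volt.shape[2]
    acc = 0.0
    pa = pa0
    pb = pb0
    for i in range(nm):
        ia = int(np.floor(pa))
        ib = int(np.floor(pb))
        fa = pa - ia
        fb = pb - ib
        if 0 <= ia and ia + 1 < na and 0 <= ib and ib + 1 < nb:
            acc += (
                (1.0 - fa) * ((1.0 - fb) * volt[i, ia, ib] + fb * volt[i, ia, ib + 1])
                + fa * ((1.0 - fb) * volt[i, ia + 1, ib] + fb * volt[i, ia + 1, ib + 1])
            )
        else:
            val = 0.0
            for da in range(2):
                oa = ia + da
                if oa < 0 or oa >= na:
                    continue
                wa = fa if da == 1 else 1.0 - fa
                for db in range(2):
                    ob = ib + db
                    if ob < 0 or ob >= nb:
                        continue
                    wb = fb if db == 1 else 1.0 - fb
                    val += wa * wb * volt[i, oa, ob]
            acc += val
        pa += dpa
        pb += dpb
    return acc * seglen


@njit(cache=True, fastmath=True, inline="always")
def _scatter_line(volt, nm, pa0, dpa, pb0, dpb, contrib):
    na = volt.shape[1]
    nb = volt.shape[2]
    pa = pa0
    pb = pb0
    for i in range(nm):
        ia = int(np.floor(pa))
        ib = int(np.floor(pb))
        fa = pa - ia
        fb = pb - ib
        if 0 <= ia and ia + 1 < na and 0 <= ib and ib + 1 < nb:
            volt[i, ia, ib] += (1.0 - fa) * (1.0 - fb) * contrib
            volt[i, ia, ib + 1] += (1.0 - fa) * fb * contrib
            volt[i, ia + 1, ib] += fa * (1.0 - fb) * contrib
            volt[i, ia + 1, ib + 1] += fa * fb * contrib
        else:
            for da in range(2):
                oa = ia + da
                if oa < 0 or oa >= na:
                    continue
                wa = fa if da == 1 else 1.0 - fa
                for db in range(2):
                    ob = ib + db
                    if ob < 0 or ob >= nb:
                        continue
                    wb = fb if db == 1 else 1.0 - fb
                    volt[i, oa, ob] += wa * wb * contrib
        pa += dpa
        pb += dpb


@njit(cache=True, fastmath=True)
def joseph_forward(vol, origin, voxsize, src, det_center, u_axis, v_axis, pu, pv, out):
    nrows, ncols = out.shape
    cu = 0.5 * (ncols - 1)
    cv = 0.5 * (nrows - 1)
    v0 = vol
    v1 = vol.transpose(1, 2, 0)
    v2 = vol.transpose(2, 0, 1)
    for r in range(nrows):
        dv = (r - cv) * pv
        for c in range(ncols):
            du = (c - cu) * pu
            px = det_center[0] + du * u_axis[0] + dv * v_axis[0]
            py = det_center[1] + du * u_axis[1] + dv * v_axis[1]
            pz = det_center[2] + du * u_axis[2] + dv * v_axis[2]
            m, nm, pa0, dpa, pb0, dpb, seglen = _ray_setup(
                vol.shape[0], vol.shape[1], vol.shape[2],
                origin, voxsize, src[0], src[1], src[2], px, py, pz,
            )
            if nm == 0:
                out[r, c] = 0.0
            elif m == 0:
                out[r, c] = _gather_line(v0, nm, pa0, dpa, pb0, dpb, seglen)
            elif m == 1:
                out[r, c] = _gather_line(v1, nm, pa0, dpa, pb0, dpb, seglen)
            else:
                out[r, c] = _gather_line(v2, nm, pa0, dpa, pb0, dpb, seglen)


@njit(cache=True, fastmath=True)
def joseph_backward(
    proj, origin, voxsize, src, det_center, u_axis, v_axis, pu, pv, out_vol
):
    nrows, ncols = proj.shape
    cu = 0.5 * (ncols - 1)
    cv = 0.5 * (nrows - 1)
    v0 = out_vol
    v1 = out_vol.transpose(1, 2, 0)
    v2 = out_vol.transpose(2, 0, 1)
    for r in range(nrows):
        dv = (r - cv) * pv
        for c in range(ncols):
            value = proj[r, c]
            if value == 0.0:
                continue
            du = (c - cu) * pu
            px = det_center[0] + du * u_axis[0] + dv * v_axis[0]
            py = det_center[1] + du * u_axis[1] + dv * v_axis[1]
            pz = det_center[2] + du * u_axis[2] + dv * v_axis[2]
            m, nm, pa0, dpa, pb0, dpb, seglen = _ray_setup(
                out_vol.shape[0], out_vol.shape[1], out_vol.shape[2],
                origin, voxsize, src[0], src[1], src[2], px, py, pz,
            )
            if nm == 0:
                continue
            contrib = value * seglen
            if m == 0:
                _scatter_line(v0, nm, pa0, dpa, pb0, dpb, contrib)
            elif m == 1:
                _scatter_line(v1, nm, pa0, dpa, pb0, dpb, contrib)
            else:
                _scatter_line(v2, nm, pa0, dpa, pb0, dpb, contrib)


@njit(cache=True, fastmath=True)
def pull3(vol, disp, out):
    """out[r] = vol[r + disp(r)] with trilinear interpolation (disp in voxels)."""
    nx, ny, nz = vol.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                px = i + disp[i, j, k, 0]
                py = j + disp[i, j, k, 1]
                pz = k + disp[i, j, k, 2]
                i0 = int(np.floor(px))
                j0 = int(np.floor(py))
                k0 = int(np.floor(pz))
                fx = px - i0
                fy = py - j0
                fz = pz - k0
                if 0 <= i0 and i0 + 1 < nx and 0 <= j0 and j0 + 1 < ny and 0 <= k0 and k0 + 1 < nz:
                    c00 = (1 - fz) * vol[i0, j0, k0] + fz * vol[i0, j0, k0 + 1]
                    c01 = (1 - fz) * vol[i0, j0 + 1, k0] + fz * vol[i0, j0 + 1, k0 + 1]
                    c10 = (1 - fz) * vol[i0 + 1, j0, k0] + fz * vol[i0 + 1, j0, k0 + 1]
                    c11 = (1 - fz) * vol[i0 + 1, j0 + 1, k0] + fz * vol[i0 + 1, j0 + 1, k0 + 1]
                    out[i, j, k] = (1 - fx) * ((1 - fy) * c00 + fy * c01) + fx * (
                        (1 - fy) * c10 + fy * c11
                    )
                else:
                    val = 0.0
                    for di in range(2):
                        ii = i0 + di
                        if ii < 0 or ii >= nx:
                            continue
                        wx = fx if di == 1 else 1.0 - fx
                        for dj in range(2):
                            jj = j0 + dj
                            if jj < 0 or jj >= ny:
                                continue
                            wy = fy if dj == 1 else 1.0 - fy
                            for dk in range(2):
                                kk = k0 + dk
                                if kk < 0 or kk >= nz:
                                    continue
                                wz = fz if dk == 1 else 1.0 - fz
                                val += wx * wy * wz * vol[ii, jj, kk]
                    out[i, j, k] = val


@njit(cache=True, fastmath=True)
def pull3_grad(vol, disp, out, gout):
    """Pull plus the exact gradient of the interpolant w.r.t. the sample point.

    ``gout[..., p]`` is d out / d disp_p in (value per voxel-unit), i.e. the
    derivative of the *discrete* trilinear model actually used by ``pull3`` —
    not a finite-difference approximation.
    """
    nx, ny, nz = vol.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                px = i + disp[i, j, k, 0]
                py = j + disp[i, j, k, 1]
                pz = k + disp[i, j, k, 2]
                i0 = int(np.floor(px))
                j0 = int(np.floor(py))
                k0 = int(np.floor(pz))
                fx = px - i0
                fy = py - j0
                fz = pz - k0
                if 0 <= i0 and i0 + 1 < nx and 0 <= j0 and j0 + 1 < ny and 0 <= k0 and k0 + 1 < nz:
                    v000 = vol[i0, j0, k0]
                    v001 = vol[i0, j0, k0 + 1]
                    v010 = vol[i0, j0 + 1, k0]
                    v011 = vol[i0, j0 + 1, k0 + 1]
                    v100 = vol[i0 + 1, j0, k0]
                    v101 = vol[i0 + 1, j0, k0 + 1]
                    v110 = vol[i0 + 1, j0 + 1, k0]
                    v111 = vol[i0 + 1, j0 + 1, k0 + 1]
                    c00 = (1 - fz) * v000 + fz * v001
                    c01 = (1 - fz) * v010 + fz * v011
                    c10 = (1 - fz) * v100 + fz * v101
                    c11 = (1 - fz) * v110 + fz * v111
                    out[i, j, k] = (1 - fx) * ((1 - fy) * c00 + fy * c01) + fx * (
                        (1 - fy) * c10 + fy * c11
                    )
                    gout[i, j, k, 0] = (1 - fy) * (c10 - c00) + fy * (c11 - c01)
                    gout[i, j, k, 1] = (1 - fx) * (c01 - c00) + fx * (c11 - c10)
                    dz00 = v001 - v000
                    dz01 = v011 - v010
                    dz10 = v101 - v100
                    dz11 = v111 - v110
                    gout[i, j, k, 2] = (1 - fx) * ((1 - fy) * dz00 + fy * dz01) + fx * (
                        (1 - fy) * dz10 + fy * dz11
                    )
                else:
                    val = 0.0
                    gx = 0.0
                    gy = 0.0
                    gz = 0.0
                    for di in range(2):
                        ii = i0 + di
                        if ii < 0 or ii >= nx:
                            continue
                        wx = fx if di == 1 else 1.0 - fx
                        dwx = 1.0 if di == 1 else -1.0
                        for dj in range(2):
                            jj = j0 + dj
                            if jj < 0 or jj >= ny:
                                continue
                            wy = fy if dj == 1 else 1.0 - fy
                            dwy = 1.0 if dj == 1 else -1.0
                            for dk in range(2):
                                kk = k0 + dk
                                if kk < 0 or kk >= nz:
                                    continue
                                wz = fz if dk == 1 else 1.0 - fz
                                dwz = 1.0 if dk == 1 else -1.0
                                v = vol[ii, jj, kk]
                                val += wx * wy * wz * v
                                gx += dwx * wy * wz * v
                                gy += wx * dwy * wz * v
                                gz += wx * wy * dwz * v
                    out[i, j, k] = val
                    gout[i, j, k, 0] = gx
                    gout[i, j, k, 1] = gy
                    gout[i, j, k, 2] = gz


@njit(cache=True, fastmath=True)
def push3(img, disp, out):
    """Exact adjoint of :func:`pull3`: splat img[r] to the corners of r+disp(r)."""
    nx, ny, nz = img.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                v = img[i, j, k]
                if v == 0.0:
                    continue
                px = i + disp[i, j, k, 0]
                py = j + disp[i, j, k, 1]
                pz = k + disp[i, j, k, 2]
                i0 = int(np.floor(px))
                j0 = int(np.floor(py))
                k0 = int(np.floor(pz))
                fx = px - i0
                fy = py - j0
                fz = pz - k0
                if 0 <= i0 and i0 + 1 < nx and 0 <= j0 and j0 + 1 < ny and 0 <= k0 and k0 + 1 < nz:
                    out[i0, j0, k0] += (1 - fx) * (1 - fy) * (1 - fz) * v
                    out[i0, j0, k0 + 1] += (1 - fx) * (1 - fy) * fz * v
                    out[i0, j0 + 1, k0] += (1 - fx) * fy * (1 - fz) * v
                    out[i0, j0 + 1, k0 + 1] += (1 - fx) * fy * fz * v
                    out[i0 + 1, j0, k0] += fx * (1 - fy) * (1 - fz) * v
                    out[i0 + 1, j0, k0 + 1] += fx * (1 - fy) * fz * v
                    out[i0 + 1, j0 + 1, k0] += fx * fy * (1 - fz) * v
                    out[i0 + 1, j0 + 1, k0 + 1] += fx * fy * fz * v
                else:
                    for di in range(2):
                        ii = i0 + di
                        if ii < 0 or ii >= nx:
                            continue
                        wx = fx if di == 1 else 1.0 - fx
                        for dj in range(2):
                            jj = j0 + dj
                            if jj < 0 or jj >= ny:
                                continue
                            wy = fy if dj == 1 else 1.0 - fy
                            for dk in range(2):
                                kk = k0 + dk
                                if kk < 0 or kk >= nz:
                                    continue
                                wz = fz if dk == 1 else 1.0 - fz
                                out[ii, jj, kk] += wx * wy * wz * v


@njit(cache=True, fastmath=True)
def chain_accumulate(gpos, gimg, tau_t, sigma, H, gtau_t):
    """Fused per-frame gradient chain for the motion estimation.

    h(r) = gimg(r) * gpos(r) is the loss gradient w.r.t. the displacement at
    each voxel.  Accumulates H[c] += tau_t[c] * h (spatial-coefficient path)
    and gtau_t[c] = <sigma[c], h> (temporal path) in one memory pass.
    sigma and H are (nc, nx, ny, nz, 3); gpos is (nx, ny, nz, 3).
    """
    nc = sigma.shape[0]
    nx, ny, nz = gimg.shape
    for c in range(nc):
        acc = 0.0
        tc = tau_t[c]
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    g = gimg[i, j, k]
                    h0 = g * gpos[i, j, k, 0]
                    h1 = g * gpos[i, j, k, 1]
                    h2 = g * gpos[i, j, k, 2]
                    H[c, i, j, k, 0] += tc * h0
                    H[c, i, j, k, 1] += tc * h1
                    H[c, i, j, k, 2] += tc * h2
                    acc += (
                        sigma[c, i, j, k, 0] * h0
                        + sigma[c, i, j, k, 1] * h1
                        + sigma[c, i, j, k, 2] * h2
                    )
        gtau_t[c] = acc
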