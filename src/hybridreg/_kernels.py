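"""Numba inner loops: DRR ray marching and batched EPD evaluation.

Kept free of package imports so the kernels compile once and cache.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _trilinear(vox, x, y, z):
    nx, ny, nz = vox.shape
    if x < 0.0 or y < 0.0 or z < 0.0 or x > nx - 1 or y > ny - 1 or z > nz - 1:
        return 0.0
    i = int(x)
    j = int(y)
    k = int(z)
    if i == nx - 1:
        i -= 1
    if j == ny - 1:
        j -= 1
    if k == nz - 1:
        k -= 1
    fx = x - i
    fy = y - j
    fz = z - k
    c00 = vox[i, j, k] * (1 - fx) + vox[i + 1, j, k] * fx
    c10 = vox[i, j + 1, k] * (1 - fx) + vox[i + 1, j + 1, k] * fx
    c01 = vox[i, j, k + 1] * (1 - fx) + vox[i + 1, j, k + 1] * fx
    c11 = vox[i, j + 1, k + 1] * (1 - fx) + vox[i + 1, j + 1, k + 1] * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


@njit(cache=True, fastmath=True)
def drr_cast(
    vox,
    origin,
    spacing,
    rinv,
    tfull,
    sdd,
    pitch,
    ppr,
    ppc,
    nrows,
    ncols,
    step,
    ortho,
    lo,
    hi,
):
    """Line integrals of attenuation along source-to-pixel rays.

    ``rinv`` maps camera-frame directions into the object frame
    (transpose of the pose rotation); ``tfull`` is the camera-frame
    position of the object-frame origin.  With ``ortho`` nonzero, rays run
    parallel to the optical axis through the detector pixel scaled 1:1.
    ``lo``/``hi`` bound the support of nonzero voxels (index coordinates);
    rays are clipped to that box since samples outside it integrate to zero.
    """
    out = np.zeros((nrows, ncols))
    # source position in object index coordinates (shared by all rays)
    for r in range(nrows):
        dy = (r - ppr) * pitch
        for c in range(ncols):
            dx = (c - ppc) * pitch
            if ortho:
                ocx, ocy, ocz = dx, dy, 0.0
                dcx, dcy, dcz = 0.0, 0.0, 1.0
            else:
                norm = math.sqrt(dx * dx + dy * dy + sdd * sdd)
                dcx, dcy, dcz = dx / norm, dy / norm, sdd / norm
                ocx, ocy, ocz = 0.0, 0.0, 0.0
            # camera frame -> object frame -> index coordinates
            px = ocx - tfull[0]
            py = ocy - tfull[1]
            pz = ocz - tfull[2]
            ox = (rinv[0, 0] * px + rinv[0, 1] * py + rinv[0, 2] * pz - origin[0]) / spacing[0]
            oy = (rinv[1, 0] * px + rinv[1, 1] * py + rinv[1, 2] * pz - origin[1]) / spacing[1]
            oz = (rinv[2, 0] * px + rinv[2, 1] * py + rinv[2, 2] * pz - origin[2]) / spacing[2]
            ux = (rinv[0, 0] * dcx + rinv[0, 1] * dcy + rinv[0, 2] * dcz) / spacing[0]
            uy = (rinv[1, 0] * dcx + rinv[1, 1] * dcy + rinv[1, 2] * dcz) / spacing[1]
            uz = (rinv[2, 0] * dcx + rinv[2, 1] * dcy + rinv[2, 2] * dcz) / spacing[2]
            # slab clipping against the nonzero-support box
            t0 = 0.0
            t1 = 1.0e30
            ok = True
            for a in range(3):
                if a == 0:
                    o, u = ox, ux
                elif a == 1:
                    o, u = oy, uy
                else:
                    o, u = oz, uz
                if abs(u) < 1e-12:
                    if o < lo[a] or o > hi[a]:
                        ok = False
                        break
                else:
                    ta = (lo[a] - o) / u
                    tb = (hi[a] - o) / u
                    if ta > tb:
                        ta, tb = tb, ta
                    if ta > t0:
                        t0 = ta
                    if tb < t1:
                        t1 = tb
            if not ok or t1 <= t0:
                continue
            nsteps = int((t1 - t0) / step)
            if nsteps < 1:
                continue
            acc = 0.0
            for k in range(nsteps):
                tk = t0 + (k + 0.5) * step
                acc += _trilinear(vox, ox + tk * ux, oy + tk * uy, oz + tk * uz)
            out[r, c] = acc * step
    return out


@njit(cache=True, fastmath=True)
def _bilinear_clamped(img, r, c):
    """Bilinear sample with clamping; adds the out-of-bounds travel distance."""
    h, w = img.shape
    rc = min(max(r, 0.0), h - 1.0)
    cc = min(max(c, 0.0), w - 1.0)
    i = int(rc)
    j = int(cc)
    if i == h - 1:
        i -= 1
    if j == w - 1:
        j -= 1
    fr = rc - i
    fc = cc - j
    v = (
        img[i, j] * (1 - fr) * (1 - fc)
        + img[i + 1, j] * fr * (1 - fc)
        + img[i, j + 1] * (1 - fr) * fc
        + img[i + 1, j + 1] * fr * fc
    )
    dr = r - rc
    dc = c - cc
    if dr != 0.0 or dc != 0.0:
        v += math.sqrt(dr * dr + dc * dc)
    return v


@njit(cache=True, fastmath=True)
def epd_batch(pr, pc, dist, ty_px, tx_px, rz_rad, cy, cx, out):
    """Mean chamfer distance of transformed edge points, one value per candidate.

    Edge points ``(pr, pc)`` rotate by ``rz_rad[m]`` about ``(cy, cx)`` and
    translate by ``(ty_px[m], tx_px[m])`` before sampling ``dist``.
    """
    n = pr.shape[0]
    for m in range(out.shape[0]):
        co = math.cos(rz_rad[m])
        si = math.sin(rz_rad[m])
        s = 0.0
        for i in range(n):
            r0 = pr[i] - cy
            c0 = pc[i] - cx
            c1 = co * c0 - si * r0 + cx + tx_px[m]
            r1 = si * c0 + co * r0 + cy + ty_px[m]
            s += _bilinear_clamped(dist, r1, c1)
        out[m] = s / n
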