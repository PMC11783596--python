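"""Numba resampling kernels.

Hot path of the augmentation engine: sequential per-organ deformation
resamples the full grid many times per output image, so the trilinear /
nearest-neighbour samplers and the fused 3-component displacement-field
sampler are hand-written (scipy.ndimage.map_coordinates is several times
slower per call and cannot fuse the three vector components).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(fastmath=True)
def trilinear(vol, ci, cj, ck, cval, out):
    """Trilinear sampling of ``vol`` at fractional indices; ``cval`` outside."""
    ni, nj, nk = vol.shape
    n = ci.size
    for p in range(n):
        x = ci[p]
        y = cj[p]
        z = ck[p]
        if x < -1.0 or x > ni or y < -1.0 or y > nj or z < -1.0 or z > nk:
            out[p] = cval
            continue
        i0 = int(np.floor(x))
        j0 = int(np.floor(y))
        k0 = int(np.floor(z))
        fx = x - i0
        fy = y - j0
        fz = z - k0
        acc = 0.0
        for di in range(2):
            ii = i0 + di
            wx = fx if di == 1 else 1.0 - fx
            if wx == 0.0:
                continue
            for dj in range(2):
                jj = j0 + dj
                wy = fy if dj == 1 else 1.0 - fy
                if wy == 0.0:
                    continue
                for dk in range(2):
                    kk = k0 + dk
                    wz = fz if dk == 1 else 1.0 - fz
                    if wz == 0.0:
                        continue
                    w = wx * wy * wz
                    if 0 <= ii < ni and 0 <= jj < nj and 0 <= kk < nk:
                        acc += w * vol[ii, jj, kk]
                    else:
                        acc += w * cval
        out[p] = acc


@njit(fastmath=True)
def nearest(vol, ci, cj, ck, cval, out):
    """Nearest-neighbour sampling; ``cval`` outside the grid."""
    ni, nj, nk = vol.shape
    n = ci.size
    for p in range(n):
        ii = int(np.floor(ci[p] + 0.5))
        jj = int(np.floor(cj[p] + 0.5))
        kk = int(np.floor(ck[p] + 0.5))
        if 0 <= ii < ni and 0 <= jj < nj and 0 <= kk < nk:
            out[p] = vol[ii, jj, kk]
        else:
            out[p] = cval


@njit(fastmath=True)
def sample_vec3(field, ci, cj, ck, out):
    """Trilinear sampling of a (ni,nj,nk,3) vector field; zero outside."""
    ni, nj, nk = field.shape[0], field.shape[1], field.shape[2]
    n = ci.size
    for p in range(n):
        x = ci[p]
        y = cj[p]
        z = ck[p]
        v0 = 0.0
        v1 = 0.0
        v2 = 0.0
        if -1.0 < x < ni and -1.0 < y < nj and -1.0 < z < nk:
            i0 = int(np.floor(x))
            j0 = int(np.floor(y))
            k0 = int(np.floor(z))
            fx = x - i0
            fy = y - j0
            fz = z - k0
            for di in range(2):
                ii = i0 + di
                if ii < 0 or ii >= ni:
                    continue
                wx = fx if di == 1 else 1.0 - fx
                for dj in range(2):
                    jj = j0 + dj
                    if jj < 0 or jj >= nj:
                        continue
                    wy = fy if dj == 1 else 1.0 - fy
                    for dk in range(2):
                        kk = k0 + dk
                        if kk < 0 or kk >= nk:
                            continue
                        w = wx * wy * (fz if dk == 1 else 1.0 - fz)
                        v0 += w * field[ii, jj, kk, 0]
                        v1 += w * field[ii, jj, kk, 1]
                        v2 += w * field[ii, jj, kk, 2]
        out[p, 0] = v0
        out[p, 1] = v1
        out[p, 2] = v2


@njit(fastmath=True)
def warp_scalar_field(src, field, inv0, inv1, inv2, cval, out):
    """Fused pull-back warp for axis-aligned geometries: trilinear sampling
    of ``src`` at ``i + field[i] * inv_spacing`` without intermediate
    coordinate arrays."""
    ni, nj, nk = src.shape
    for i in range(ni):
        for j in range(nj):
            for k in range(nk):
                x = i + field[i, j, k, 0] * inv0
                y = j + field[i, j, k, 1] * inv1
                z = k + field[i, j, k, 2] * inv2
                if x < -1.0 or x > ni or y < -1.0 or y > nj or z < -1.0 or z > nk:
                    out[i, j, k] = cval
                    continue
                i0 = int(np.floor(x))
                j0 = int(np.floor(y))
                k0 = int(np.floor(z))
                fx = x - i0
                fy = y - j0
                fz = z - k0
                acc = 0.0
                for di in range(2):
                    ii = i0 + di
                    wx = fx if di == 1 else 1.0 - fx
                    if wx == 0.0:
                        continue
                    for dj in range(2):
                        jj = j0 + dj
                        wy = fy if dj == 1 else 1.0 - fy
                        if wy == 0.0:
                            continue
                        for dk in range(2):
                            kk = k0 + dk
                            wz = fz if dk == 1 else 1.0 - fz
                            if wz == 0.0:
                                continue
                            w = wx * wy * wz
                            if 0 <= ii < ni and 0 <= jj < nj and 0 <= kk < nk:
                                acc += w * src[ii, jj, kk]
                            else:
                                acc += w * cval
                out[i, j, k] = acc


@njit(fastmath=True)
def warp_label_field(src, field, inv0, inv1, inv2, out):
    """Fused nearest-neighbour pull-back warp of an integer label map."""
    ni, nj, nk = src.shape
    for i in range(ni):
        for j in range(nj):
            for k in range(nk):
                d0 = field[i, j, k, 0]
                d1 = field[i, j, k, 1]
                d2 = field[i, j, k, 2]
                if d0 == 0.0 and d1 == 0.0 and d2 == 0.0:
                    out[i, j, k] = src[i, j, k]
                    continue
                ii = int(np.floor(i + d0 * inv0 + 0.5))
                jj = int(np.floor(j + d1 * inv1 + 0.5))
                kk = int(np.floor(k + d2 * inv2 + 0.5))
                if 0 <= ii < ni and 0 <= jj < nj and 0 <= kk < nk:
                    out[i, j, k] = src[ii, jj, kk]
                else:
                    out[i, j, k] = 0


@njit(fastmath=True)
def compose_fields(f1, f2, inv0, inv1, inv2, out):
    """Pull-back composition d(x) = f1(x + f2(x)) + f2(x) for axis-aligned
    geometries; voxels where f2 vanishes copy f1 directly."""
    ni, nj, nk = f1.shape[0], f1.shape[1], f1.shape[2]
    for i in range(ni):
        for j in range(nj):
            for k in range(nk):
                d0 = f2[i, j, k, 0]
                d1 = f2[i, j, k, 1]
                d2 = f2[i, j, k, 2]
                if d0 == 0.0 and d1 == 0.0 and d2 == 0.0:
                    out[i, j, k, 0] = f1[i, j, k, 0]
                    out[i, j, k, 1] = f1[i, j, k, 1]
                    out[i, j, k, 2] = f1[i, j, k, 2]
                    continue
                x = i + d0 * inv0
                y = j + d1 * inv1
                z = k + d2 * inv2
                v0 = 0.0
                v1 = 0.0
                v2 = 0.0
                if -1.0 < x < ni and -1.0 < y < nj and -1.0 < z < nk:
                    i0 = int(np.floor(x))
                    j0 = int(np.floor(y))
                    k0 = int(np.floor(z))
                    fx = x - i0
                    fy = y - j0
                    fz = z - k0
                    for di in range(2):
                        ii = i0 + di
                        if ii < 0 or ii >= ni:
                            continue
                        wx = fx if di == 1 else 1.0 - fx
                        for dj in range(2):
                            jj = j0 + dj
                            if jj < 0 or jj >= nj:
                                continue
                            wy = fy if dj == 1 else 1.0 - fy
                            for dk in range(2):
                                kk = k0 + dk
                                if kk < 0 or kk >= nk:
                                    continue
                                w = wx * wy * (fz if dk == 1 else 1.0 - fz)
                                v0 += w * f1[ii, jj, kk, 0]
                                v1 += w * f1[ii, jj, kk, 1]
                                v2 += w * f1[ii, jj, kk, 2]
                out[i, j, k, 0] = v0 + d0
                out[i, j, k, 1] = v1 + d1
                out[i, j, k, 2] = v2 + d2
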