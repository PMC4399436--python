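"""Numba kernels: exact voxel traversal, cone superposition, gamma search.

Grid convention matches :mod:`epidose.grids`: arrays indexed [ix, iy, iz],
``origin`` is the center of voxel (0,0,0), all lengths in cm (mm for the
gamma routines, which receive spacing explicitly).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_TINY = 1e-12


@njit(cache=True)
def seg_raddepth(rho, spacing, origin, p0, p1):
    """Radiological depth (integral of rho dl, cm) along segment p0 -> p1.

    Exact voxel-boundary traversal; the portion of the segment outside the
    grid contributes zero.
    """
    nx, ny, nz = rho.shape
    dx = p1[0] - p0[0]
    dy = p1[1] - p0[1]
    dz = p1[2] - p0[2]
    L = np.sqrt(dx * dx + dy * dy + dz * dz)
    if L <= 0.0:
        return 0.0

    # grid slab bounds (outer voxel faces)
    t0 = 0.0
    t1 = 1.0
    for ax in range(3):
        if ax == 0:
            d, p, n, sp, og = dx, p0[0], nx, spacing[0], origin[0]
        elif ax == 1:
            d, p, n, sp, og = dy, p0[1], ny, spacing[1], origin[1]
        else:
            d, p, n, sp, og = dz, p0[2], nz, spacing[2], origin[2]
        lo = og - 0.5 * sp
        hi = og + (n - 0.5) * sp
        if abs(d) < _TINY:
            if p < lo or p > hi:
                return 0.0
        else:
            ta = (lo - p) / d
            tb = (hi - p) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    if t0 >= t1:
        return 0.0

    depth = 0.0
    t = t0
    while t < t1 - 1e-12:
        eps = 1e-9 * (t1 - t0) + 1e-12
        px = p0[0] + (t + eps) * dx
        py = p0[1] + (t + eps) * dy
        pz = p0[2] + (t + eps) * dz
        ix = int(np.floor((px - (origin[0] - 0.5 * spacing[0])) / spacing[0]))
        iy = int(np.floor((py - (origin[1] - 0.5 * spacing[1])) / spacing[1]))
        iz = int(np.floor((pz - (origin[2] - 0.5 * spacing[2])) / spacing[2]))
        if ix < 0:
            ix = 0
        if iy < 0:
            iy = 0
        if iz < 0:
            iz = 0
        if ix > nx - 1:
            ix = nx - 1
        if iy > ny - 1:
            iy = ny - 1
        if iz > nz - 1:
            iz = nz - 1
        # next boundary crossing
        tn = t1
        if abs(dx) > _TINY:
            bound = origin[0] + ((ix + 0.5) if dx > 0 else (ix - 0.5)) * spacing[0]
            tc = (bound - p0[0]) / dx
            if t < tc < tn:
                tn = tc
        if abs(dy) > _TINY:
            bound = origin[1] + ((iy + 0.5) if dy > 0 else (iy - 0.5)) * spacing[1]
            tc = (bound - p0[1]) / dy
            if t < tc < tn:
                tn = tc
        if abs(dz) > _TINY:
            bound = origin[2] + ((iz + 0.5) if dz > 0 else (iz - 0.5)) * spacing[2]
            tc = (bound - p0[2]) / dz
            if t < tc < tn:
                tn = tc
        if tn <= t:
            tn = t + 1e-9
        depth += rho[ix, iy, iz] * (tn - t) * L
        t = tn
    return depth


@njit(cache=True)
def raddepth_to_centers(rho, spacing, origin, source):
    """Radiological depth from ``source`` to every voxel center."""
    nx, ny, nz = rho.shape
    out = np.empty((nx, ny, nz))
    p1 = np.empty(3)
    for ix in range(nx):
        p1[0] = origin[0] + ix * spacing[0]
        for iy in range(ny):
            p1[1] = origin[1] + iy * spacing[1]
            for iz in range(nz):
                p1[2] = origin[2] + iz * spacing[2]
                out[ix, iy, iz] = seg_raddepth(rho, spacing, origin, source, p1)
    return out


@njit(cache=True, inline="always")
def _ctab(C, b, r, rstep, nr):
    """Linear interpolation of C[b] at radius r (uniform step)."""
    x = r / rstep
    i = int(x)
    if i >= nr - 1:
        return C[b, nr - 1]
    f = x - i
    return C[b, i] * (1.0 - f) + C[b, i + 1] * f


@njit(cache=True)
def cone_superpose(terma, rho, spacing, origin, march_dirs, bands, C, rstep, r_cut, n_az):
    """Collapsed-cone superposition, receiving-voxel formulation.

    For each receiving voxel and direction the ray is marched upstream with
    exact voxel-boundary steps; the segment of TERMA in each traversed voxel
    contributes T * (Ktil(s2) - Ktil(s1)) where Ktil is the CCK-averaged
    cumulative kernel over the receiver's radiological extent,
    Ktil(s) = (C(s + delta) - C(s)) / delta, s measured from the receiver's
    upstream face.  The receiver's own voxel contributes T * Ktil(0).
    """
    nx, ny, nz = rho.shape
    nr = C.shape[1]
    ndir = march_dirs.shape[0]
    dose = np.zeros((nx, ny, nz))

    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                rv = rho[ix, iy, iz]
                acc = 0.0
                for d in range(ndir):
                    mx = march_dirs[d, 0]
                    my = march_dirs[d, 1]
                    mz = march_dirs[d, 2]
                    b = bands[d]
                    # geometric chord of the receiving voxel along this ray
                    chord = 1e30
                    if abs(mx) > _TINY and spacing[0] / abs(mx) < chord:
                        chord = spacing[0] / abs(mx)
                    if abs(my) > _TINY and spacing[1] / abs(my) < chord:
                        chord = spacing[1] / abs(my)
                    if abs(mz) > _TINY and spacing[2] / abs(mz) < chord:
                        chord = spacing[2] / abs(mz)
                    delta = rv * chord
                    if delta < 1e-9:
                        delta = 1e-9

                    # DDA state starting at the receiver center
                    jx, jy, jz = ix, iy, iz
                    if mx > _TINY:
                        sx_step = 1
                        tmx = (0.5 * spacing[0]) / mx
                        tdx = spacing[0] / mx
                    elif mx < -_TINY:
                        sx_step = -1
                        tmx = (0.5 * spacing[0]) / (-mx)
                        tdx = spacing[0] / (-mx)
                    else:
                        sx_step = 0
                        tmx = 1e30
                        tdx = 1e30
                    if my > _TINY:
                        sy_step = 1
                        tmy = (0.5 * spacing[1]) / my
                        tdy = spacing[1] / my
                    elif my < -_TINY:
                        sy_step = -1
                        tmy = (0.5 * spacing[1]) / (-my)
                        tdy = spacing[1] / (-my)
                    else:
                        sy_step = 0
                        tmy = 1e30
                        tdy = 1e30
                    if mz > _TINY:
                        sz_step = 1
                        tmz = (0.5 * spacing[2]) / mz
                        tdz = spacing[2] / mz
                    elif mz < -_TINY:
                        sz_step = -1
                        tmz = (0.5 * spacing[2]) / (-mz)
                        tdz = spacing[2] / (-mz)
                    else:
                        sz_step = 0
                        tmz = 1e30
                        tdz = 1e30

                    # self term: receiver voxel's own TERMA
                    ktil_prev = (_ctab(C, b, delta, rstep, nr) - 0.0) / delta
                    acc_d = terma[jx, jy, jz] * ktil_prev

                    # march: s = radiological distance from receiver's
                    # upstream face (first crossing from the center)
                    s = 0.0
                    t_prev = min(tmx, min(tmy, tmz))  # center -> face
                    # advance out of the receiver voxel
                    if tmx <= tmy and tmx <= tmz:
                        jx += sx_step
                        tmx += tdx
                    elif tmy <= tmz:
                        jy += sy_step
                        tmy += tdy
                    else:
                        jz += sz_step
                        tmz += tdz
                    rcb = r_cut[b]
                    while 0 <= jx < nx and 0 <= jy < ny and 0 <= jz < nz:
                        t_next = min(tmx, min(tmy, tmz))
                        seg = t_next - t_prev
                        s2 = s + rho[jx, jy, jz] * seg
                        tv = terma[jx, jy, jz]
                        if tv != 0.0:
                            ktil = (
                                _ctab(C, b, s2 + delta, rstep, nr)
                                - _ctab(C, b, s2, rstep, nr)
                            ) / delta
                            acc_d += tv * (ktil - ktil_prev)
                            ktil_prev = ktil
                        elif s2 != s:
                            ktil_prev = (
                                _ctab(C, b, s2 + delta, rstep, nr)
                                - _ctab(C, b, s2, rstep, nr)
                            ) / delta
                        s = s2
                        t_prev = t_next
                        if s > rcb:
                            break
                        if tmx <= tmy and tmx <= tmz:
                            jx += sx_step
                            tmx += tdx
                        elif tmy <= tmz:
                            jy += sy_step
                            tmy += tdy
                        else:
                            jz += sz_step
                            tmz += tdz
                    acc += acc_d
                dose[ix, iy, iz] = acc / n_az
    return dose


@njit(cache=True)
def brute_force_superpose(
    terma,
    rho,
    spacing,
    origin,
    axis,
    zedges_rad,
    redges,
    frac,
    vbin,
    gcum_r,
    gcum_v,
    n_sub,
):
    """Direct point-kernel superposition over all (source, receiver) pairs.

    Straight-line density scaling: the kernel is looked up at the
    radiological distance r_eff between the pair, with density scaling
    factor (r_eff / r_geom)^2.  The kernel-fraction density is averaged
    over ``n_sub^3`` subpoints of the receiving voxel (the tabulated bins
    are much finer than a voxel near the origin, so center sampling would
    mis-integrate the near field).

    Space around each source is partitioned at the radiological radius of
    the sphere inscribed in the source voxel: the kernel mass inside it is
    taken from the all-band cumulative table ``gcum_r``/``gcum_v``
    (assigned to the source voxel, whose volume fully contains it) and
    subpoints falling inside it are skipped, so the near-singular region is
    never point-sampled and never double counted.
    """
    nx, ny, nz = rho.shape
    nb = zedges_rad.size - 1
    nrb = redges.size - 1
    dose = np.zeros((nx, ny, nz))
    vvox = spacing[0] * spacing[1] * spacing[2]
    r_vox = 0.5 * min(spacing[0], min(spacing[1], spacing[2]))  # inscribed
    p0 = np.empty(3)
    p1 = np.empty(3)
    # subpoint offsets within a voxel, per axis
    subs = np.empty(n_sub)
    for i in range(n_sub):
        subs[i] = (i + 0.5) / n_sub - 0.5
    for sx in range(nx):
        for sy in range(ny):
            for sz in range(nz):
                T = terma[sx, sy, sz]
                if T == 0.0:
                    continue
                rho_s = rho[sx, sy, sz]
                R = T * rho_s * vvox  # released energy
                p0[0] = origin[0] + sx * spacing[0]
                p0[1] = origin[1] + sy * spacing[1]
                p0[2] = origin[2] + sz * spacing[2]
                # kernel mass within the inscribed sphere -> source voxel
                r_sph = rho_s * r_vox
                g = np.interp(r_sph, gcum_r, gcum_v)
                dose[sx, sy, sz] += T * g
                for jx in range(nx):
                    p1[0] = origin[0] + jx * spacing[0]
                    for jy in range(ny):
                        p1[1] = origin[1] + jy * spacing[1]
                        for jz in range(nz):
                            p1[2] = origin[2] + jz * spacing[2]
                            wx = p1[0] - p0[0]
                            wy = p1[1] - p0[1]
                            wz = p1[2] - p0[2]
                            if jx == sx and jy == sy and jz == sz:
                                # same voxel: local scaling, corner subpoints
                                # beyond the sphere still contribute
                                rscale = rho_s
                            else:
                                r_geom = np.sqrt(wx * wx + wy * wy + wz * wz)
                                # one traversal per pair; subpoints reuse the
                                # center's radiological scaling factor
                                r_eff = seg_raddepth(rho, spacing, origin, p0, p1)
                                rscale = r_eff / r_geom
                            acc = 0.0
                            for ux in range(n_sub):
                                qx = wx + subs[ux] * spacing[0]
                                for uy in range(n_sub):
                                    qy = wy + subs[uy] * spacing[1]
                                    for uz in range(n_sub):
                                        qz = wz + subs[uz] * spacing[2]
                                        rg = np.sqrt(qx * qx + qy * qy + qz * qz)
                                        if rg <= 0.0:
                                            continue
                                        ct = (
                                            qx * axis[0]
                                            + qy * axis[1]
                                            + qz * axis[2]
                                        ) / rg
                                        if ct > 1.0:
                                            ct = 1.0
                                        if ct < -1.0:
                                            ct = -1.0
                                        theta = np.arccos(ct)
                                        re = rg * rscale
                                        if re <= r_sph:
                                            continue  # counted analytically
                                        b = np.searchsorted(zedges_rad, theta) - 1
                                        if b < 0:
                                            b = 0
                                        if b > nb - 1:
                                            b = nb - 1
                                        k = np.searchsorted(redges, re) - 1
                                        if k < 0:
                                            k = 0
                                        if k > nrb - 1:
                                            continue  # beyond kernel support
                                        acc += rscale * rscale * frac[b, k] / vbin[b, k]
                            dose[jx, jy, jz] += R * acc / (n_sub * n_sub * n_sub)
    return dose


@njit(cache=True, inline="always")
def _trilin(a, x, y, z):
    nx, ny, nz = a.shape
    i = int(np.floor(x))
    j = int(np.floor(y))
    k = int(np.floor(z))
    if i < 0:
        i = 0
    if j < 0:
        j = 0
    if k < 0:
        k = 0
    if i > nx - 2:
        i = nx - 2
    if j > ny - 2:
        j = ny - 2
    if k > nz - 2:
        k = nz - 2
    fx = x - i
    fy = y - j
    fz = z - k
    c00 = a[i, j, k] * (1 - fx) + a[i + 1, j, k] * fx
    c10 = a[i, j + 1, k] * (1 - fx) + a[i + 1, j + 1, k] * fx
    c01 = a[i, j, k + 1] * (1 - fx) + a[i + 1, j, k + 1] * fx
    c11 = a[i, j + 1, k + 1] * (1 - fx) + a[i + 1, j + 1, k + 1] * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


@njit(cache=True)
def gamma_shell_search(
    ref, evl, mask, offs_idx, geom_term, dd_abs, cap2, spacing_mm, dta_mm, step_mm
):
    """Shell gamma search over offsets sorted by distance.

    ``offs_idx``: [n, 3] offsets in (fractional) index units of the
    evaluated grid, sorted by geometric distance; ``geom_term``: the
    squared-distance term |offset|^2 / dta^2 of each offset.  The scan over
    offsets stops once the geometric term alone exceeds the best gamma^2
    found so far (admissible, because offsets are distance-sorted).  A
    pattern-search refinement with halved steps then polishes the lattice
    minimum below the lattice quantization error.
    """
    nx, ny, nz = ref.shape
    n_off = offs_idx.shape[0]
    gamma = np.full((nx, ny, nz), np.nan)
    dta2 = dta_mm * dta_mm
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                if not mask[ix, iy, iz]:
                    continue
                dr = ref[ix, iy, iz]
                best = cap2
                bx = 0.0
                by = 0.0
                bz = 0.0
                for k in range(n_off):
                    g = geom_term[k]
                    if g >= best:
                        break
                    x = ix + offs_idx[k, 0]
                    y = iy + offs_idx[k, 1]
                    z = iz + offs_idx[k, 2]
                    if (
                        x < 0.0
                        or y < 0.0
                        or z < 0.0
                        or x > nx - 1.0
                        or y > ny - 1.0
                        or z > nz - 1.0
                    ):
                        continue
                    de = _trilin(evl, x, y, z)
                    dd = (de - dr) / dd_abs
                    v = g + dd * dd
                    if v < best:
                        best = v
                        bx = offs_idx[k, 0] * spacing_mm[0]
                        by = offs_idx[k, 1] * spacing_mm[1]
                        bz = offs_idx[k, 2] * spacing_mm[2]
                # local refinement around the lattice minimum (offsets in mm)
                h = 0.5 * step_mm
                for _ in range(5):
                    improved = True
                    while improved:
                        improved = False
                        for dxi in (-1, 0, 1):
                            for dyi in (-1, 0, 1):
                                for dzi in (-1, 0, 1):
                                    if dxi == 0 and dyi == 0 and dzi == 0:
                                        continue
                                    ox = bx + dxi * h
                                    oy = by + dyi * h
                                    oz = bz + dzi * h
                                    g = (ox * ox + oy * oy + oz * oz) / dta2
                                    if g >= best:
                                        continue
                                    x = ix + ox / spacing_mm[0]
                                    y = iy + oy / spacing_mm[1]
                                    z = iz + oz / spacing_mm[2]
                                    if (
                                        x < 0.0
                                        or y < 0.0
                                        or z < 0.0
                                        or x > nx - 1.0
                                        or y > ny - 1.0
                                        or z > nz - 1.0
                                    ):
                                        continue
                                    de = _trilin(evl, x, y, z)
                                    dd = (de - dr) / dd_abs
                                    v = g + dd * dd
                                    if v < best:
                                        best = v
                                        bx = ox
                                        by = oy
                                        bz = oz
                                        improved = True
                    h *= 0.5
                gamma[ix, iy, iz] = np.sqrt(best)
    return gamma


@njit(cache=True)
def gamma_exhaustive(ref, evl, mask, offs_idx, dist2_mm2, dta_mm, dd_abs, cap2):
    """Brute-force gamma: dense distance-sorted offset lattice, test-only.

    Written independently of :func:`gamma_shell_search` (explicit inline
    interpolation); the distance-sorted early exit is admissible and does
    not change the minimum.
    """
    nx, ny, nz = ref.shape
    n_off = offs_idx.shape[0]
    dta2 = dta_mm * dta_mm
    gamma = np.full((nx, ny, nz), np.nan)
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                if not mask[ix, iy, iz]:
                    continue
                dr = ref[ix, iy, iz]
                best = cap2
                for k in range(n_off):
                    g = dist2_mm2[k] / dta2
                    if g >= best:
                        break
                    x = ix + offs_idx[k, 0]
                    y = iy + offs_idx[k, 1]
                    z = iz + offs_idx[k, 2]
                    if x < 0.0 or y < 0.0 or z < 0.0:
                        continue
                    if x > nx - 1.0 or y > ny - 1.0 or z > nz - 1.0:
                        continue
                    i = int(x)
                    j = int(y)
                    kk = int(z)
                    if i > nx - 2:
                        i = nx - 2
                    if j > ny - 2:
                        j = ny - 2
                    if kk > nz - 2:
                        kk = nz - 2
                    fx = x - i
                    fy = y - j
                    fz = z - kk
                    de = (
                        evl[i, j, kk] * (1 - fx) * (1 - fy) * (1 - fz)
                        + evl[i + 1, j, kk] * fx * (1 - fy) * (1 - fz)
                        + evl[i, j + 1, kk] * (1 - fx) * fy * (1 - fz)
                        + evl[i, j, kk + 1] * (1 - fx) * (1 - fy) * fz
                        + evl[i + 1, j + 1, kk] * fx * fy * (1 - fz)
                        + evl[i + 1, j, kk + 1] * fx * (1 - fy) * fz
                        + evl[i, j + 1, kk + 1] * (1 - fx) * fy * fz
                        + evl[i + 1, j + 1, kk + 1] * fx * fy * fz
                    )
                    dd = (de - dr) / dd_abs
                    v = g + dd * dd
                    if v < best:
                        best = v
                gamma[ix, iy, iz] = np.sqrt(best)
    return gamma
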