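"""Numba kernel: exact ray/voxel-grid intersection lengths (Siddon-style).

One call traces every detector pixel of a single view through a labelled
voxel grid with an Amanatides-Woo traversal, accumulating the exact
chord length spent in each material.  Lengths are in the same unit as
``voxel_mm`` (mm throughout the package).
"""

import numba
import numpy as np

_BIG = 1e30


@numba.njit(parallel=True, fastmath=True, cache=True)
def trace_view(labels, lut, voxel_mm, src, det_center, u_dir, v_dir,
               pixel_mm, n_rows, n_channels, out):
    nx, ny, nz = labels.shape
    cx = -0.5 * nx * voxel_mm
    cy = -0.5 * ny * voxel_mm
    cz = -0.5 * nz * voxel_mm
    for r in numba.prange(n_rows):
        voff = (r - (n_rows - 1) * 0.5) * pixel_mm
        for ch in range(n_channels):
            uoff = (ch - (n_channels - 1) * 0.5) * pixel_mm
            px = det_center[0] + uoff * u_dir[0] + voff * v_dir[0]
            py = det_center[1] + uoff * u_dir[1] + voff * v_dir[1]
            pz = det_center[2] + uoff * u_dir[2] + voff * v_dir[2]
            dx = px - src[0]
            dy = py - src[1]
            dz = pz - src[2]
            ray_len = np.sqrt(dx * dx + dy * dy + dz * dz)
            # clip the ray parameter t in [0, 1] to the grid bounding box
            t0 = 0.0
            t1 = 1.0
            ok = True
            for ax in range(3):
                if ax == 0:
                    d, s, lo, hi = dx, src[0], cx, cx + nx * voxel_mm
                elif ax == 1:
                    d, s, lo, hi = dy, src[1], cy, cy + ny * voxel_mm
                else:
                    d, s, lo, hi = dz, src[2], cz, cz + nz * voxel_mm
                if abs(d) < 1e-12:
                    if s < lo or s > hi:
                        ok = False
                        break
                else:
                    ta = (lo - s) / d
                    tb = (hi - s) / d
                    if ta > tb:
                        ta, tb = tb, ta
                    if ta > t0:
                        t0 = ta
                    if tb < t1:
                        t1 = tb
            if not ok or t0 >= t1:
                continue
            # entry voxel (nudge inside to dodge exact-boundary starts)
            eps = 1e-9
            te = t0 + eps * (t1 - t0)
            ex = src[0] + te * dx
            ey = src[1] + te * dy
            ez = src[2] + te * dz
            ix = int((ex - cx) / voxel_mm)
            iy = int((ey - cy) / voxel_mm)
            iz = int((ez - cz) / voxel_mm)
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
            # per-axis parametric steps
            if dx > 0:
                step_x, tmax_x = 1, (cx + (ix + 1) * voxel_mm - src[0]) / dx
                tdel_x = voxel_mm / dx
            elif dx < 0:
                step_x, tmax_x = -1, (cx + ix * voxel_mm - src[0]) / dx
                tdel_x = -voxel_mm / dx
            else:
                step_x, tmax_x, tdel_x = 0, _BIG, _BIG
            if dy > 0:
                step_y, tmax_y = 1, (cy + (iy + 1) * voxel_mm - src[1]) / dy
                tdel_y = voxel_mm / dy
            elif dy < 0:
                step_y, tmax_y = -1, (cy + iy * voxel_mm - src[1]) / dy
                tdel_y = -voxel_mm / dy
            else:
                step_y, tmax_y, tdel_y = 0, _BIG, _BIG
            if dz > 0:
                step_z, tmax_z = 1, (cz + (iz + 1) * voxel_mm - src[2]) / dz
                tdel_z = voxel_mm / dz
            elif dz < 0:
                step_z, tmax_z = -1, (cz + iz * voxel_mm - src[2]) / dz
                tdel_z = -voxel_mm / dz
            else:
                step_z, tmax_z, tdel_z = 0, _BIG, _BIG
            t = t0
            while t < t1:
                tnext = tmax_x
                if tmax_y < tnext:
                    tnext = tmax_y
                if tmax_z < tnext:
                    tnext = tmax_z
                if tnext > t1:
                    tnext = t1
                lab = labels[ix, iy, iz]
                if lab > 0:
                    m = lut[lab]
                    if m >= 0:
                        out[m, r, ch] += (tnext - t) * ray_len
                t = tnext
                if tmax_x <= tmax_y and tmax_x <= tmax_z:
                    ix += step_x
                    tmax_x += tdel_x
                    if ix < 0 or ix >= nx:
                        break
                elif tmax_y <= tmax_z:
                    iy += step_y
                    tmax_y += tdel_y
                    if iy < 0 or iy >= ny:
                        break
                else:
                    iz += step_z
                    tmax_z += tdel_z
                    if iz < 0 or iz >= nz:
                        break
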