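"""Numba kernel: voxel-driven cone-beam backprojection.

Projections are assumed already cosine-weighted and ramp-filtered, with
detector coordinates rescaled to the isocenter plane (virtual detector
through the rotation axis).  The kernel accumulates the
distance-weighted bilinear sample for every voxel and view.
"""

import numba
import numpy as np


@numba.njit(parallel=True, fastmath=True, cache=True)
def backproject(proj, sin_t, cos_t, sid, du, dv, voxel_mm, z0, out):
    n_views, n_rows, n_ch = proj.shape
    nx, ny, nz = out.shape
    cu = (n_ch - 1) * 0.5
    cv = (n_rows - 1) * 0.5
    for ix in numba.prange(nx):
        x = (ix + 0.5 - nx * 0.5) * voxel_mm
        for iy in range(ny):
            y = (iy + 0.5 - ny * 0.5) * voxel_mm
            for k in range(n_views):
                s = sin_t[k]
                c = cos_t[k]
                L = -s * x + c * y + sid
                if L < 1e-6:
                    continue
                f = sid / L
                w = f * f
                cf = (c * x + s * y) * f / du + cu
                if cf < 0.0 or cf > n_ch - 1:
                    continue
                c0 = int(cf)
                if c0 > n_ch - 2:
                    c0 = n_ch - 2
                fc = cf - c0
                for iz in range(nz):
                    z = (iz + 0.5 - nz * 0.5) * voxel_mm - z0
                    rf = z * f / dv + cv
                    if rf < 0.0 or rf > n_rows - 1:
                        continue
                    r0 = int(rf)
                    if r0 > n_rows - 2:
                        r0 = n_rows - 2
                    fr = rf - r0
                    val = ((1 - fr) * ((1 - fc) * proj[k, r0, c0]
                                       + fc * proj[k, r0, c0 + 1])
                           + fr * ((1 - fc) * proj[k, r0 + 1, c0]
                                   + fc * proj[k, r0 + 1, c0 + 1]))
                    out[ix, iy, iz] += w * val
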