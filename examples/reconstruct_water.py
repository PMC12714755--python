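"""Water-cylinder reconstruction and Hounsfield calibration.

Runs the full chain on a noiseless 20 mm water cylinder: simulate,
correct (low-bin derivation, air correction, STEPC, bad pixels, rings),
FDK-reconstruct each energy bin, calibrate the per-bin water scale
factor 1000/mu_water on a small core region, and report how close the
wider interior lands to 0 HU.
"""

import numpy as np

import pcct
from pcct.pipeline import (RunConfig, correct_scan, make_setup,
                           reconstruct_bins, run_slab_calibration)
from pcct.recon import hu_scale_from_water, to_hounsfield
from pcct.simulate import acquire_scan


def cylinder_mask(shape, voxel, radius_mm, half_height_mm):
    x = (np.arange(shape[0]) + 0.5 - shape[0] / 2)[:, None, None] * voxel
    y = (np.arange(shape[1]) + 0.5 - shape[1] / 2)[None, :, None] * voxel
    z = (np.arange(shape[2]) + 0.5 - shape[2] / 2)[None, None, :] * voxel
    return (x**2 + y**2 <= radius_mm**2) & (np.abs(z) <= half_height_mm)


cfg = RunConfig(seed=5, noise=False)
geom, detector, spectrum = make_setup(cfg)
stepc = run_slab_calibration(geom, detector, spectrum, cfg.seed, noise=False)

water = pcct.build_phantom("water_cylinder",
                           {"diameter_mm": 20.0, "height_mm": 30.0})
scan = acquire_scan(water, geom, detector, spectrum, seed=cfg.seed,
                    noise=False)
stacks, _ = correct_scan(scan, cfg, stepc)
volumes = reconstruct_bins(stacks, geom, cfg)

for bin, vol in volumes.items():
    voxel = vol.voxel_mm[0]
    core = cylinder_mask(vol.shape, voxel, 2.5, 4.0)
    interior = cylinder_mask(vol.shape, voxel, 7.0, 4.0)
    scale = hu_scale_from_water(vol, core)
    hu = to_hounsfield(vol, scale)
    print(f"{bin:>5} bin: scale factor {scale.for_bin(bin):8.0f} HU*mm, "
          f"interior {hu.values[interior].mean():+6.1f} +- "
          f"{hu.values[interior].std():5.1f} HU")
# The interior mean differs from 0 only through beam hardening (the core
# used for calibration hardens less than the wider interior) and residual
# reconstruction artifacts; each bin gets its own water scale factor.
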