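"""Shared fixtures: desk-scale setups and cached expensive simulations."""

import numpy as np
import pytest

import pcct
from pcct import corrections as corr
from pcct.simulate import acquire_scan


@pytest.fixture(scope="session")
def desk_geom():
    return pcct.ScanGeometry.desk_scale(n_views=180)


@pytest.fixture(scope="session")
def tiny_geom():
    """Very small detector for fast per-operation tests."""
    return pcct.ScanGeometry(pixel_mm=0.8, n_channels=64, n_rows=16,
                             angles_deg=np.arange(36) * 10.0)


@pytest.fixture(scope="session")
def spectrum():
    return pcct.generate_spectrum()


@pytest.fixture(scope="session")
def ideal_detector():
    return pcct.DetectorModel()


@pytest.fixture(scope="session")
def water_phantom():
    return pcct.build_phantom("water_cylinder",
                              {"diameter_mm": 20.0, "height_mm": 30.0})


@pytest.fixture(scope="session")
def water_scan_ideal(water_phantom, desk_geom, spectrum, ideal_detector):
    """Noiseless ideal-detector water-cylinder scan (shared: it is slow)."""
    return acquire_scan(water_phantom, desk_geom, ideal_detector, spectrum,
                        seed=0, noise=False)


@pytest.fixture(scope="session")
def water_log_total(water_scan_ideal):
    return corr.air_correct_stack(water_scan_ideal["total"],
                                  water_scan_ideal["flats"]["total"])


@pytest.fixture(scope="session")
def water_volume(water_log_total, desk_geom):
    return pcct.fdk_reconstruct(water_log_total, desk_geom, filter="hann",
                                shape=(96, 96, 24))


def cylinder_mask(shape, voxel_mm, radius_mm, half_height_mm):
    nx, ny, nz = shape
    x = (np.arange(nx) + 0.5 - nx / 2)[:, None, None] * voxel_mm
    y = (np.arange(ny) + 0.5 - ny / 2)[None, :, None] * voxel_mm
    z = (np.arange(nz) + 0.5 - nz / 2)[None, None, :] * voxel_mm
    return (x**2 + y**2 <= radius_mm**2) & (np.abs(z) <= half_height_mm)


@pytest.fixture(scope="session")
def log_frame():
    """A small synthetic log frame with smooth quadratic structure."""
    i = np.arange(16)[:, None]
    j = np.arange(64)[None, :]
    vals = 0.3 + 0.001 * i + 0.002 * j - 1e-5 * i * j + 2e-5 * j**2
    return pcct.ProjectionImage(vals * np.ones((16, 64)), bin="total", kind="log")
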