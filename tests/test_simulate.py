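"""Forward projector and photon-counting detector model."""

import numpy as np
import pytest

import pcct
from pcct.phantoms import VoxelPhantom, build_phantom
from pcct.materials import get_material
from pcct.simulate import (DetectorModel, acquire_scan, acquire_slab_series,
                           detect_counts, expected_counts, forward_paths,
                           make_detector, make_gain_map)


@pytest.fixture(scope="module")
def water_cube():
    """10 mm water cube centred at the isocenter (25 voxels of 0.4 mm)."""
    labels = np.zeros((48, 48, 48), dtype=np.int8)
    labels[12:37, 12:37, 12:37] = 1  # 25 * 0.4 = 10 mm
    return VoxelPhantom(labels, 0.4, {1: get_material("water")})


class TestForwardPaths:
    def test_central_ray_through_cube_is_exact(self, water_cube, tiny_geom):
        paths = forward_paths(water_cube, tiny_geom, 0.0)
        r, c = tiny_geom.n_rows // 2, tiny_geom.n_channels // 2
        # even-sized detector: average the two central channels
        central = 0.5 * (paths.paths_mm[0, r, c - 1] + paths.paths_mm[0, r, c])
        assert central == pytest.approx(10.0, rel=1e-3)

    def test_empty_phantom_gives_zero_paths(self, tiny_geom):
        labels = np.zeros((8, 8, 8), dtype=np.int8)
        ph = VoxelPhantom(labels, 1.0, {})
        paths = forward_paths(ph, tiny_geom, 45.0)
        assert paths.paths_mm.shape == (0, 16, 64)

    def test_oblique_rays_match_dense_ray_marching(self, water_cube, tiny_geom):
        angle = 33.0
        paths = forward_paths(water_cube, tiny_geom, angle)
        src, det, u, v = tiny_geom.source_frame(angle)
        rng = np.random.default_rng(1)
        n = water_cube.labels.shape[0]
        half = n * water_cube.voxel_mm / 2
        step = 0.01 * water_cube.voxel_mm
        for r, c in [(8, 32), (3, 20), (12, 45), (8, 10)]:
            p = (det + (c - (tiny_geom.n_channels - 1) / 2) * tiny_geom.pixel_mm * u
                 + (r - (tiny_geom.n_rows - 1) / 2) * tiny_geom.pixel_mm * v)
            d = p - src
            ts = np.arange(0.0, 1.0, step / np.linalg.norm(d))
            pts = src[None, :] + ts[:, None] * d[None, :]
            idx = np.floor((pts + half) / water_cube.voxel_mm).astype(int)
            inside = np.all((idx >= 0) & (idx < n), axis=1)
            hit = np.zeros(len(ts), bool)
            ii = idx[inside]
            hit[inside] = water_cube.labels[ii[:, 0], ii[:, 1], ii[:, 2]] == 1
            oracle = hit.sum() * step
            got = paths.paths_mm[0, r, c]
            if oracle > 1.0:
                assert got == pytest.approx(oracle, rel=5e-3)

    def test_fov_truncation_warns(self, tiny_geom):
        ph = build_phantom("water_cylinder", {"diameter_mm": 60.0,
                                              "shape": (96, 96, 16),
                                              "voxel_mm": 0.8})
        with pytest.warns(UserWarning, match="field of view"):
            forward_paths(ph, tiny_geom, 0.0)


class TestDetectCounts:
    def test_flat_field_equals_binned_fluence(self, tiny_geom, spectrum):
        det = DetectorModel()
        lam = expected_counts(None, spectrum, det, "total",
                              shape=(tiny_geom.n_rows, tiny_geom.n_channels))
        assert lam[0, 0] == pytest.approx(spectrum.binned(15.0).sum())
        lam_h = expected_counts(None, spectrum, det, "high", shape=lam.shape)
        assert lam_h[0, 0] == pytest.approx(spectrum.binned(30.0).sum())

    def test_huge_budget_saturates_at_counter_max(self, water_cube, tiny_geom):
        hot = pcct.generate_spectrum(photons_per_pixel=1e6)
        det = DetectorModel()
        paths = forward_paths(water_cube, tiny_geom, 0.0)
        img = detect_counts(paths, hot, det, "total", noise=False)
        assert img.values.max() == 4096
        assert img.values[0, 0] == 4096  # air pixel saturated

    def test_gain_doubles_counts_before_clipping(self, water_cube, tiny_geom, spectrum):
        paths = forward_paths(water_cube, tiny_geom, 0.0)
        shape = (tiny_geom.n_rows, tiny_geom.n_channels)
        d1 = DetectorModel(gain=np.ones(shape))
        d2 = DetectorModel(gain=2.0 * np.ones(shape))
        l1 = expected_counts(paths, spectrum, d1, "total")
        l2 = expected_counts(paths, spectrum, d2, "total")
        np.testing.assert_allclose(l2, 2.0 * l1, rtol=1e-12)

    def test_high_counts_never_exceed_total(self, water_cube, tiny_geom, spectrum):
        det = make_detector(tiny_geom, seed=4, n_bad_pixels=0, tile_width=16)
        paths = forward_paths(water_cube, tiny_geom, 20.0)
        t = detect_counts(paths, spectrum, det, "total", noise=False)
        h = detect_counts(paths, spectrum, det, "high", noise=False)
        assert np.all(h.values <= t.values)

    def test_stuck_pixels_flaggable_by_count_rule(self, tiny_geom, spectrum):
        det = make_detector(tiny_geom, seed=9, n_bad_pixels=5, tile_width=16)
        lam = expected_counts(None, spectrum, det, "total",
                              shape=(tiny_geom.n_rows, tiny_geom.n_channels))
        from pcct.simulate import _record
        counts = _record(lam, det, np.random.default_rng(0), noise=False)
        for (r, c), mode in det.bad_pixels.items():
            if mode == "stuck_low":
                assert counts[r, c] < 5
            else:
                assert counts[r, c] > 4090

    def test_low_bin_is_not_acquired(self, spectrum, tiny_geom):
        det = DetectorModel()
        with pytest.raises(ValueError, match="low"):
            expected_counts(None, spectrum, det, "low", shape=(4, 4))

    def test_poisson_mean_matches_expectation(self, spectrum):
        # mean of 200 seeded noisy flat fields vs the analytic expectation,
        # within 4 sigma / sqrt(200) per pixel on a 32x32 crop
        shape = (32, 32)
        det = DetectorModel(gain=make_gain_map(*shape, seed=2, tile_width=8))
        lam = expected_counts(None, spectrum, det, "total", shape=shape)
        rng = np.random.default_rng(123)
        n = 200
        mean = rng.poisson(np.broadcast_to(lam, (n,) + shape)).mean(axis=0)
        bound = 4.0 * np.sqrt(lam) / np.sqrt(n)
        assert np.all(np.abs(mean - lam) <= bound)


class TestAcquisition:
    def test_two_bins_per_angle_plus_flats(self, water_cube, tiny_geom,
                                           spectrum, ideal_detector):
        scan = acquire_scan(water_cube, tiny_geom, ideal_detector, spectrum,
                            seed=0, noise=False, n_flat=10)
        assert len(scan["total"]) == len(scan["high"]) == 36
        assert set(scan["flats"]) == {"total", "high"}
        # 36 angles x 2 acquired bins = 72 frames per couch position
        assert len(scan["total"]) + len(scan["high"]) == 72

    def test_same_seed_is_bit_identical(self, water_cube, tiny_geom, spectrum):
        det = make_detector(tiny_geom, seed=1, tile_width=16)
        a = acquire_scan(water_cube, tiny_geom, det, spectrum, seed=42, n_flat=5)
        b = acquire_scan(water_cube, tiny_geom, det, spectrum, seed=42, n_flat=5)
        np.testing.assert_array_equal(a["total"].as_array(), b["total"].as_array())
        np.testing.assert_array_equal(a["flats"]["high"].values,
                                      b["flats"]["high"].values)


class TestSlabSeries:
    def test_default_lists_give_56_scans(self, tiny_geom, spectrum, ideal_detector):
        from pcct.pipeline import DEFAULT_AL_MM, DEFAULT_PMMA_MM
        series = acquire_slab_series(DEFAULT_PMMA_MM, DEFAULT_AL_MM, tiny_geom,
                                     ideal_detector, spectrum, noise=False)
        assert len(series) == 56

    def test_zero_zero_combination_equals_flat_field(self, tiny_geom, spectrum,
                                                     ideal_detector):
        series = acquire_slab_series((0.0, 10.0), (0.0,), tiny_geom,
                                     ideal_detector, spectrum, noise=False)
        flat = expected_counts(None, spectrum, ideal_detector, "total",
                               shape=(tiny_geom.n_rows, tiny_geom.n_channels))
        np.testing.assert_allclose(series[(0.0, 0.0)]["total"].values, flat,
                                   rtol=1e-9)

    def test_counts_decrease_with_added_pmma(self, tiny_geom, spectrum,
                                             ideal_detector):
        series = acquire_slab_series((0.0, 5.0, 10.0), (0.0,), tiny_geom,
                                     ideal_detector, spectrum, noise=False)
        a = series[(0.0, 0.0)]["total"].values
        b = series[(5.0, 0.0)]["total"].values
        c = series[(10.0, 0.0)]["total"].values
        assert np.all(b < a) and np.all(c < b)

    def test_thickness_lists_must_include_zero(self, tiny_geom, spectrum,
                                               ideal_detector):
        with pytest.raises(ValueError, match="0"):
            acquire_slab_series((5.0,), (0.0,), tiny_geom, ideal_detector,
                                spectrum)

    def test_negative_thickness_rejected(self, tiny_geom, spectrum,
                                         ideal_detector):
        with pytest.raises(ValueError, match="negative"):
            acquire_slab_series((0.0, -5.0), (0.0,), tiny_geom, ideal_detector,
                                spectrum)

    def test_written_layout_matches_dataset_convention(self, tiny_geom, spectrum,
                                                       ideal_detector, tmp_path):
        acquire_slab_series((0.0, 5.0), (0.0, 1.0), tiny_geom, ideal_detector,
                            spectrum, noise=False, out_dir=tmp_path)
        from pcct.io import scan_directory
        m = scan_directory(tmp_path, "slab_series")
        assert len(m.entries) == 8  # 4 combinations x 2 bins
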