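"""Bin subtraction, air correction, STEPC, bad pixels and ring removal."""

import numpy as np
import pytest

from pcct import corrections as corr
from pcct.io import ProjectionImage, ProjectionStack
from pcct.pipeline import DEFAULT_AL_MM, DEFAULT_PMMA_MM
from pcct.simulate import (DetectorModel, acquire_slab_series, make_gain_map,
                           make_threshold_offsets)


def counts(vals, bin="total", angle=0.0):
    return ProjectionImage(np.asarray(vals, float), bin=bin, angle_deg=angle)


class TestDeriveLow:
    def test_simple_subtraction(self):
        low, n = corr.derive_low(counts([[100]]), counts([[30]], "high"))
        assert low.values[0, 0] == 70
        assert low.bin == "low" and n == 0

    def test_equal_bins_give_zero(self):
        low, _ = corr.derive_low(counts([[55]]), counts([[55]], "high"))
        assert low.values[0, 0] == 0

    def test_negative_difference_clips_and_counts(self):
        with pytest.warns(UserWarning, match="1"):
            low, n = corr.derive_low(counts([[30]]), counts([[40]], "high"))
        assert low.values[0, 0] == 0
        assert n == 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            corr.derive_low(counts(np.zeros((2, 2))),
                            counts(np.zeros((2, 3)), "high"))

    def test_angle_mismatch_rejected(self):
        with pytest.raises(ValueError, match="angle"):
            corr.derive_low(counts([[1]], angle=0.0),
                            counts([[1]], "high", angle=1.0))


class TestAirCorrect:
    def test_identical_frames_give_zero_log(self):
        p = corr.air_correct(counts(1000 * np.ones((3, 3))),
                             counts(1000 * np.ones((3, 3))))
        np.testing.assert_allclose(p.values, 0.0)
        assert p.kind == "log"

    def test_ln_identity(self):
        p = corr.air_correct(counts([[1000 / np.e]]), counts([[1000]]))
        assert p.values[0, 0] == pytest.approx(1.0, rel=1e-12)

    def test_zero_counts_clamped_to_one(self):
        p = corr.air_correct(counts([[0]]), counts([[1000]]))
        assert p.values[0, 0] == pytest.approx(np.log(1000.0))

    def test_all_zero_air_is_calibration_error(self):
        with pytest.raises(ValueError, match="flat field"):
            corr.air_correct(counts([[10]]), counts([[0]]))

    def test_inverse_reproduces_clamped_counts(self):
        rng = np.random.default_rng(3)
        obj = counts(rng.integers(0, 3000, (8, 8)))
        air = counts(rng.integers(500, 3000, (8, 8)))
        p = corr.air_correct(obj, air)
        back = np.exp(-p.values) * np.maximum(air.values, 1.0)
        np.testing.assert_allclose(back, np.maximum(obj.values, 1.0), rtol=1e-12)


class TestUniformitySurface:
    def test_quadratic_frame_has_zero_residual(self, log_frame):
        _, resid = corr.fit_uniformity_surface(log_frame)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_spike_isolated_in_residual(self, log_frame):
        vals = log_frame.values.copy()
        vals[7, 30] += 0.5
        _, resid = corr.fit_uniformity_surface(log_frame.replace(values=vals))
        # direct least-squares oracle: spike spread is bounded by leverage
        assert resid[7, 30] == pytest.approx(0.5, rel=0.02)
        mask = np.ones_like(resid, bool)
        mask[7, 30] = False
        assert np.abs(resid[mask]).max() < 0.01

    def test_constant_frame_fits_itself(self):
        f = ProjectionImage(3.14 * np.ones((8, 16)), kind="log")
        surface, resid = corr.fit_uniformity_surface(f)
        np.testing.assert_allclose(surface, 3.14, rtol=1e-12)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)

    def test_too_few_good_pixels(self):
        f = ProjectionImage(np.ones((2, 2)), kind="log")
        with pytest.raises(ValueError, match="6"):
            corr.fit_uniformity_surface(f, good_mask=np.zeros((2, 2), bool))


@pytest.fixture(scope="module")
def slab_logs(desk_geom, spectrum):
    """Air-corrected slab series from a zero-jitter non-uniform detector."""
    off = make_threshold_offsets(desk_geom.n_rows, desk_geom.n_channels,
                                 seed=2, tile_width=64, sigma_pixel_keV=0.0)
    gain = make_gain_map(desk_geom.n_rows, desk_geom.n_channels, seed=2,
                         tile_width=64, sigma_pixel=0.0)
    det = DetectorModel(gain=gain, threshold_offsets_keV=off)
    series = acquire_slab_series(DEFAULT_PMMA_MM, DEFAULT_AL_MM, desk_geom,
                                 det, spectrum, seed=0, noise=False)
    air = series[(0.0, 0.0)]
    air_low, _ = corr.derive_low(air["total"], air["high"])
    logs = {}
    for lab, sc in series.items():
        low, _ = corr.derive_low(sc["total"], sc["high"])
        logs[lab] = {"total": corr.air_correct(sc["total"], air["total"]),
                     "high": corr.air_correct(sc["high"], air["high"]),
                     "low": corr.air_correct(low, air_low)}
    return logs


def _resid_rms(frame):
    _, r = corr.fit_uniformity_surface(frame)
    return float(np.sqrt((r**2).mean()))


class TestStepc:
    def test_table_shape_is_rows_channels_5(self, slab_logs, desk_geom):
        table = corr.stepc_calibrate(slab_logs)
        for bin in ("total", "high", "low"):
            assert table.coeffs[bin].shape == (desk_geom.n_rows,
                                               desk_geom.n_channels, 5)

    def test_zero_jitter_residual_reduced_90_percent(self, slab_logs):
        held = (15.0, 1.5)
        cal = {k: v for k, v in slab_logs.items() if k != held}
        table = corr.stepc_calibrate(cal)
        for lab in ((10.0, 1.0), (30.0, 2.0)):
            fixed = corr.stepc_apply_frames(slab_logs[lab], table)
            for bin in ("total", "high", "low"):
                before = _resid_rms(slab_logs[lab][bin])
                after = _resid_rms(fixed[bin])
                assert after <= 0.1 * before

    def test_held_out_thickness_strictly_improves(self, slab_logs):
        held = (15.0, 1.5)
        cal = {k: v for k, v in slab_logs.items() if k != held}
        table = corr.stepc_calibrate(cal)
        fixed = corr.stepc_apply_frames(slab_logs[held], table)
        for bin in ("total", "high", "low"):
            assert _resid_rms(fixed[bin]) < _resid_rms(slab_logs[held][bin])

    def test_ideal_detector_is_near_no_op(self, tiny_geom, spectrum,
                                          ideal_detector):
        series = acquire_slab_series(DEFAULT_PMMA_MM, DEFAULT_AL_MM, tiny_geom,
                                     ideal_detector, spectrum, noise=False)
        air = series[(0.0, 0.0)]
        logs = {lab: {"total": corr.air_correct(sc["total"], air["total"]),
                      "high": corr.air_correct(sc["high"], air["high"])}
                for lab, sc in series.items()}
        table = corr.stepc_calibrate(logs)
        lab = (20.0, 2.0)
        fixed = corr.stepc_apply_frames(logs[lab], table)
        signal = np.abs(logs[lab]["total"].values).mean()
        change = np.sqrt(np.mean(
            (fixed["total"].values - logs[lab]["total"].values) ** 2))
        assert change < 0.01 * signal

    def test_zero_coefficients_are_identity(self, log_frame):
        shape = log_frame.shape + (5,)
        table = corr.StepcTable({"total": np.zeros(shape),
                                 "high": np.zeros(shape)})
        out = corr.stepc_apply_frames({"total": log_frame,
                                       "high": log_frame.replace(bin="high")},
                                      table)
        np.testing.assert_array_equal(out["total"].values, log_frame.values)

    def test_recalibration_on_corrected_data_predicts_nothing(self, slab_logs):
        # after one correction pass the slab series is uniform, so a second
        # calibration finds (nearly) nothing left to predict
        table = corr.stepc_calibrate(slab_logs)
        corrected = {lab: corr.stepc_apply_frames(fr, table)
                     for lab, fr in slab_logs.items()}
        table2 = corr.stepc_calibrate(corrected)
        lab = (10.0, 1.0)
        s_t = slab_logs[lab]["total"].values
        s_h = slab_logs[lab]["high"].values
        first = np.sqrt((table.predict("total", s_t, s_h) ** 2).mean())
        second = np.sqrt((table2.predict("total", s_t, s_h) ** 2).mean())
        assert second < 0.2 * first

    def test_too_few_scans_rejected(self, slab_logs):
        few = dict(list(slab_logs.items())[:4])
        with pytest.raises(ValueError, match=">= 6"):
            corr.stepc_calibrate(few)

    def test_missing_paired_bin_rejected(self, log_frame):
        shape = log_frame.shape + (5,)
        table = corr.StepcTable({"total": np.zeros(shape)})
        with pytest.raises(ValueError, match="paired"):
            corr.stepc_apply_frames({"total": log_frame}, table)

    def test_save_load_round_trip(self, slab_logs, tmp_path):
        table = corr.stepc_calibrate(slab_logs)
        table.save(tmp_path)
        back = corr.StepcTable.load(tmp_path)
        for bin in table.coeffs:
            np.testing.assert_allclose(back.coeffs[bin], table.coeffs[bin],
                                       rtol=1e-6)


class TestBadPixels:
    def test_threshold_boundaries_are_strict(self):
        vals = np.full((2, 4), 100.0)
        vals[0, 0] = 4    # below 5 -> bad
        vals[0, 1] = 5    # not bad
        vals[1, 0] = 4091  # above 4090 -> bad
        vals[1, 1] = 4090  # not bad
        bad = corr.detect_bad_pixels(counts(vals))
        assert bad == {(0, 0), (1, 0)}

    def test_clean_stack_is_empty(self):
        stack = ProjectionStack([counts(100 * np.ones((3, 3)), angle=a)
                                 for a in (0.0, 1.0)])
        assert corr.detect_bad_pixels(stack) == set()

    def test_any_frame_flags_pixel_and_prior_is_unioned(self):
        a = counts(100 * np.ones((2, 2)), angle=0.0)
        v = 100 * np.ones((2, 2))
        v[1, 1] = 3
        b = counts(v, angle=1.0)
        bad = corr.detect_bad_pixels(ProjectionStack([a, b]), prior={(0, 0)})
        assert bad == {(1, 1), (0, 0)}

    def test_interior_interpolation(self):
        f = counts([[10.0, 77.0, 20.0]])
        out = corr.interp_bad_pixels(f, {(0, 1)})
        assert out.values.tolist() == [[10.0, 15.0, 20.0]]

    def test_run_interpolation_is_linear_in_index(self):
        f = counts([[10.0, 0.0, 0.0, 40.0]])
        out = corr.interp_bad_pixels(f, {(0, 1), (0, 2)})
        assert out.values.tolist() == [[10.0, 20.0, 30.0, 40.0]]

    def test_edge_takes_nearest_good_value(self):
        f = counts([[99.0, 7.0, 8.0]])
        out = corr.interp_bad_pixels(f, {(0, 0)})
        assert out.values[0, 0] == 7.0

    def test_fully_bad_row_is_error(self):
        f = counts([[1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(ValueError, match="row 0"):
            corr.interp_bad_pixels(f, {(0, 0), (0, 1)})


def _static_stack(base, offset, n=32):
    return ProjectionStack([
        ProjectionImage(base + offset, kind="log", angle_deg=360.0 * k / n)
        for k in range(n)
    ])


class TestRing:
    def _smooth_base(self, shape=(16, 64)):
        # gentle low-curvature field, like a real log projection away from
        # sharp object edges
        i = np.arange(shape[0])[:, None] / shape[0]
        j = np.arange(shape[1])[None, :] / shape[1]
        return 0.5 + 0.3 * j + 0.1 * j**2 + 0.05 * i

    def test_known_offset_field_recovered(self):
        # offset high-frequency in the channel direction, constant in rows;
        # the estimator recovers content above its smoothing cutoff, so the
        # interior map matches the injected field closely (edges suffer
        # boundary effects of the filters)
        nch = 256
        jn = np.arange(nch)
        cols = 0.008 * (-1.0) ** jn + 0.006 * np.cos(2 * np.pi * 0.35 * jn + 1.0)
        cols -= cols.mean()
        offset = np.tile(cols, (16, 1))
        stack = _static_stack(self._smooth_base((16, nch)), offset)
        ring = corr.ring_estimate(stack, M=8)
        resid = (ring.error - ring.error.mean()) - (offset - offset.mean())
        rel = np.sqrt((resid[2:-2, 8:-8] ** 2).mean()) / offset.std()
        assert rel < 0.05

    def test_zero_offset_gives_tiny_map(self):
        stack = _static_stack(self._smooth_base(), 0.0)
        ring = corr.ring_estimate(stack, M=8)
        assert np.abs(ring.error).max() < 5e-3

    def test_single_subset_equals_no_subset_variant_on_static_stack(self):
        rng = np.random.default_rng(9)
        offset = np.tile(rng.normal(0.0, 0.01, 64), (16, 1))
        stack = _static_stack(self._smooth_base(), offset)
        m1 = corr.ring_estimate(stack, M=1).error
        m8 = corr.ring_estimate(stack, M=8).error
        np.testing.assert_allclose(m1, m8, atol=1e-12)

    def test_subset_order_is_irrelevant(self):
        rng = np.random.default_rng(10)
        offset = np.tile(rng.normal(0.0, 0.01, 64), (16, 1))
        base = self._smooth_base()
        blocks = [base + offset + 0.01 * k for k in range(4)]
        frames_a = [b for k in (0, 1, 2, 3) for b in [blocks[k]] * 8]
        frames_b = [b for k in (2, 0, 3, 1) for b in [blocks[k]] * 8]
        def mk(frames):
            return ProjectionStack([
                ProjectionImage(f, kind="log", angle_deg=360.0 * i / len(frames))
                for i, f in enumerate(frames)])
        ma = corr.ring_estimate(mk(frames_a), M=4).error
        mb = corr.ring_estimate(mk(frames_b), M=4).error
        np.testing.assert_allclose(ma, mb, atol=1e-12)

    def test_apply_zero_map_is_identity(self):
        stack = _static_stack(self._smooth_base(), 0.0, n=4)
        ring = corr.RingErrorMap(np.zeros((16, 64)))
        out = corr.ring_apply(stack, ring)
        np.testing.assert_array_equal(out.as_array(), stack.as_array())

    def test_subtract_then_estimate_finds_much_less(self):
        rng = np.random.default_rng(11)
        offset = np.tile(rng.normal(0.0, 0.01, 64), (16, 1))
        stack = _static_stack(self._smooth_base(), offset)
        first = corr.ring_estimate(stack, M=8)
        corrected = corr.ring_apply(stack, first)
        second = corr.ring_estimate(corrected, M=8)
        assert np.sqrt((second.error**2).mean()) < \
            0.2 * np.sqrt((first.error**2).mean())

    def test_window_zeroes_outside_channels(self):
        rng = np.random.default_rng(12)
        offset = np.tile(rng.normal(0.0, 0.01, 64), (16, 1))
        stack = _static_stack(self._smooth_base(), offset)
        ring = corr.ring_estimate(stack, M=8, window=(16, 48))
        assert not ring.error[:, :16].any()
        assert not ring.error[:, 48:].any()
        assert ring.error[:, 16:48].any()

    def test_too_many_subsets_rejected(self):
        stack = _static_stack(self._smooth_base(), 0.0, n=4)
        with pytest.raises(ValueError, match="subsets"):
            corr.ring_estimate(stack, M=10)

    def test_shape_mismatch_rejected(self):
        stack = _static_stack(self._smooth_base(), 0.0, n=4)
        with pytest.raises(ValueError, match="shape"):
            corr.ring_apply(stack, corr.RingErrorMap(np.zeros((4, 4))))


def test_total_equals_high_plus_low_before_clipping():
    rng = np.random.default_rng(13)
    t = counts(rng.integers(100, 3000, (8, 8)))
    h = counts(np.minimum(rng.integers(0, 2000, (8, 8)), t.values), "high")
    low, n = corr.derive_low(t, h)
    assert n == 0
    np.testing.assert_array_equal(h.values + low.values, t.values)
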