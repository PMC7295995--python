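"""Doppler reference pipeline: counts, corrections, unwrapping, velocity."""

import math

import numpy as np
import pytest

from octflow import doppler as dop
from octflow import phantom as ph
from octflow.exceptions import (
    AllCorruptedError,
    MissingPhaseError,
    RejectedAngleError,
)
from octflow.pipeline import SteppedMScan
from octflow.simulator import ScanTiming


def _small_scan(rng, n_loc=6, n_dep=5, n_t=128):
    data = rng.standard_normal((n_loc, n_dep, n_t)) \
        + 1j * rng.standard_normal((n_loc, n_dep, n_t))
    return SteppedMScan(data=data, timing=ScanTiming(10e-6, n_t))


class TestPhaseDifferenceCounts:
    def test_counts_for_128_sample_series(self, rng):
        scan = _small_scan(rng)
        stack = dop.phase_difference_stack(scan)
        assert stack.counts[1] == 127
        assert stack.counts[40] == 88
        assert stack.total_images == 4300

    def test_count_identity_for_any_series_length(self, rng):
        scan = _small_scan(rng, n_t=48)
        cfg = dop.DopplerConfig(delays=tuple(range(1, 11)))
        stack = dop.phase_difference_stack(scan, cfg)
        assert stack.counts == {d: 48 - d for d in range(1, 11)}
        assert stack.total_images == sum(48 - d for d in range(1, 11))

    def test_analytic_counts_helper(self):
        counts = dop.image_counts(128, tuple(range(1, 41)))
        assert counts[1] == 127 and counts[40] == 88
        assert sum(counts.values()) == 4300

    def test_intensity_only_input_rejected(self, rng):
        scan = SteppedMScan(data=rng.exponential(1.0, (4, 4, 128)),
                            timing=ScanTiming(10e-6, 128))
        with pytest.raises(MissingPhaseError):
            dop.phase_difference_stack(scan)

    def test_phase_values_match_lag_product(self, rng):
        scan = _small_scan(rng, n_t=16)
        cfg = dop.DopplerConfig(delays=(3,))
        img = dop.phase_difference_stack(scan, cfg).images[3]
        a = scan.data
        expected = np.angle(a[:, :, 3] * np.conj(a[:, :, 0]))
        np.testing.assert_allclose(img[0], expected, rtol=1e-5, atol=1e-6)


class TestBulkMotionCorrection:
    def test_uniform_offset_removed(self, rng):
        truth = rng.uniform(-0.5, 0.5, size=(8, 10))
        static = np.zeros((8, 10), dtype=bool)
        static[:, 7:] = True
        truth[static] = 0.0
        offsets = rng.uniform(-1.0, 1.0, size=(8, 1))
        corrected, flagged = dop.bulk_motion_correct(truth + offsets, static)
        assert flagged == []
        np.testing.assert_allclose(corrected[static], 0.0, atol=1e-6)
        np.testing.assert_allclose(corrected, truth, atol=1e-6)

    def test_zero_image_unchanged(self):
        img = np.zeros((4, 6))
        static = np.ones((4, 6), dtype=bool)
        corrected, flagged = dop.bulk_motion_correct(img, static)
        np.testing.assert_array_equal(corrected, img)
        assert flagged == []

    def test_column_without_static_pixels_flagged(self, rng):
        img = rng.uniform(-1, 1, size=(3, 5))
        static = np.ones((3, 5), dtype=bool)
        static[1] = False
        corrected, flagged = dop.bulk_motion_correct(img, static)
        assert flagged == [1]
        np.testing.assert_array_equal(corrected[1], img[1])

    def test_jitter_rms_reduced_on_phantom(self):
        """Per-A-scan phase jitter on a synthetic phantom is suppressed."""
        spec = ph.PhantomSpec(doppler_angle_deg=85.0, pump_rate_ul_min=30.0,
                              snr_db=None, static_phase_jitter_rad=0.3,
                              n_locations=40, n_depth=48, seed=4)
        (scan, truth), _ = ph.synth_stepped_mscan(spec), spec
        cfg = dop.DopplerConfig(delays=(1,))
        img = dop.averaged_phase_differences(scan, cfg)[1]
        static = ~truth.lumen_mask
        static[:, :spec.top_noise_rows] = False
        static[:, -7:] = False
        corrected, _ = dop.bulk_motion_correct(img, static)
        lum = truth.lumen_mask
        rms_before = np.sqrt(np.mean((img[lum] - truth.phase_ramp_rad[lum]) ** 2))
        rms_after = np.sqrt(np.mean((corrected[lum] - truth.phase_ramp_rad[lum]) ** 2))
        assert rms_after < rms_before


class TestUnwrapping:
    def test_wrapped_planar_ramp_recovered(self):
        x = np.linspace(0, 4 * np.pi, 50)
        truth = np.tile(x, (20, 1))
        wrapped = np.angle(np.exp(1j * truth))
        un = dop.unwrap_2d(wrapped)
        offset = un[0, 0] - truth[0, 0]
        np.testing.assert_allclose(un - offset, truth, atol=1e-9)

    def test_already_continuous_image_unchanged(self, rng):
        img = 0.3 * rng.standard_normal((12, 12))
        np.testing.assert_allclose(dop.unwrap_2d(img), img, atol=1e-9)


class TestRejection:
    def test_clean_stack_keeps_everything(self, rng):
        base = np.outer(np.ones(10), np.linspace(0, 1.0, 12))
        imgs = {d: base * d for d in (1, 2, 3)}
        survivors, excluded = dop.reject_corrupted(imgs)
        assert excluded == 0 and set(survivors) == {1, 2, 3}

    def test_saturated_noise_image_dropped(self, rng):
        base = np.outer(np.ones(10), np.linspace(0, 1.0, 12))
        imgs = {1: base, 2: 2 * base,
                3: rng.uniform(-40.0, 40.0, size=base.shape)}
        survivors, excluded = dop.reject_corrupted(imgs)
        assert 3 not in survivors and excluded == 1

    def test_smooth_but_inconsistent_image_dropped(self):
        base = np.outer(np.ones(10), np.linspace(0, 1.0, 12))
        imgs = {1: base, 2: 2 * base, 4: 4 * base + 2.0}  # wrong by a constant
        survivors, excluded = dop.reject_corrupted(imgs)
        assert 4 not in survivors and excluded == 1

    def test_all_corrupted_raises(self, rng):
        imgs = {d: rng.uniform(-40, 40, size=(10, 12)) for d in (1, 2)}
        with pytest.raises(AllCorruptedError):
            dop.reject_corrupted(imgs)


class TestAverageAndScale:
    def test_exact_for_constant_velocity_noise_free(self):
        dphi1 = np.outer(np.linspace(0, 0.8, 9), np.ones(7))
        per_delay = {d: d * dphi1 for d in (1, 5, 12, 40)}
        np.testing.assert_allclose(dop.average_and_scale(per_delay), dphi1,
                                   atol=1e-12)

    def test_single_delay_stack(self):
        img = np.full((4, 4), 0.6)
        np.testing.assert_allclose(dop.average_and_scale({3: img}), img / 3)

    def test_multi_delay_averaging_reduces_noise(self, rng):
        truth = 0.5
        errs_single, errs_multi = [], []
        for _ in range(200):
            imgs = {d: d * truth + rng.normal(0, 0.2, size=(5, 5))
                    for d in (1, 2, 3, 4)}
            errs_single.append(np.mean(imgs[1] / 1) - truth)
            errs_multi.append(np.mean(dop.average_and_scale(imgs)) - truth)
        assert np.std(errs_multi) < np.std(errs_single)


class TestVelocityConversion:
    def test_zero_phase_is_zero_velocity(self):
        out = dop.doppler_velocity(np.zeros((3, 3)), alpha_deg=80.0)
        np.testing.assert_array_equal(out.v_mm_s, 0.0)

    def test_perpendicular_angle_rejected(self):
        for alpha in (88.0, 90.0, 92.0):
            with pytest.raises(RejectedAngleError):
                dop.doppler_velocity(np.zeros((2, 2)), alpha_deg=alpha)

    def test_closed_form_value_at_pi_phase(self):
        # independent evaluation: for dphi = pi the pis cancel and
        # v = lambda0 / (4 n tau cos(alpha))
        expected_mm_s = 1040e-9 / (4 * 1.36 * 10e-6
                                   * math.cos(math.radians(80.0))) * 1e3
        out = dop.doppler_velocity(np.full((2, 2), np.pi), alpha_deg=80.0)
        np.testing.assert_allclose(out.v_mm_s, expected_mm_s, rtol=1e-12)
        assert out.v_mm_s[0, 0] == pytest.approx(110.09, abs=0.01)


class TestAngleFromDepthShift:
    def test_no_shift_is_perpendicular(self):
        assert dop.doppler_angle_from_depth_shift(50.0, 50.0, 200.0) == 90.0

    def test_unit_slope_is_135_degrees(self):
        assert dop.doppler_angle_from_depth_shift(0.0, 200.0, 200.0) \
            == pytest.approx(135.0)

    def test_small_slope_arithmetic(self):
        alpha = dop.doppler_angle_from_depth_shift(0.0, 17.6, 200.0)
        assert alpha == pytest.approx(90.0 + math.degrees(math.atan(0.088)),
                                      rel=1e-12)


class TestFullPipelineClosure:
    def test_noise_free_phantom_velocity_recovered(self, noise_free_phantom):
        """Single-scan Doppler inversion is unbiased and sits at the
        speckle-decorrelation noise floor (a few percent per pixel); the
        protocol-level closure (10 repeats) is checked in the acceptance
        suite."""
        (scan, truth), spec = noise_free_phantom
        result = dop.doppler_velocity_map(scan, alpha_deg=spec.doppler_angle_deg,
                                          signal_mask=truth.lumen_mask)
        lum = truth.lumen_mask & (truth.velocity_mm_s > 0.05 * truth.v_peak_mm_s)
        rel = np.abs(result.v_mm_s[lum] - truth.velocity_mm_s[lum]) \
            / truth.velocity_mm_s[lum]
        assert np.median(rel) < 0.03
        # no systematic bias: signed mean error well under the noise level
        signed = (result.v_mm_s[lum] - truth.velocity_mm_s[lum])
        assert abs(signed.mean()) < 0.005 * truth.velocity_mm_s[lum].mean()

    def test_wrapped_profile_recovered_after_unwrap(self):
        """High flow at 81 deg wraps the phase; the pipeline still inverts it."""
        spec = ph.PhantomSpec(doppler_angle_deg=81.0, pump_rate_ul_min=100.0,
                              snr_db=None, n_locations=60, n_depth=56,
                              lumen_center_px=(30, 24), seed=2)
        scan, truth = ph.synth_stepped_mscan(spec)
        assert np.max(np.abs(truth.phase_ramp_rad)) > np.pi  # wraps at delay 1
        result = dop.doppler_velocity_map(scan, alpha_deg=81.0,
                                          signal_mask=truth.lumen_mask)
        lum = truth.lumen_mask & (truth.velocity_mm_s > 0.1 * truth.v_peak_mm_s)
        rel = np.abs(result.v_mm_s[lum] - truth.velocity_mm_s[lum]) \
            / truth.velocity_mm_s[lum]
        assert np.median(rel) < 0.01
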