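"""Forward speckle model: grid, field statistics, noise and normalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octflow import simulator as sim
from octflow.exceptions import InvalidGridError, NormalizationError


class TestVelocityGrid:
    def test_reference_grid_endpoints_and_size(self):
        g = sim.make_velocity_grid(64, 0.001, 2000.0)
        assert g.n_classes == 64
        assert g.values_mm_s[0] == pytest.approx(0.001)
        assert g.values_mm_s[-1] == pytest.approx(2000.0)

    def test_two_point_grid_is_endpoints_only(self):
        g = sim.make_velocity_grid(2, 1.0, 10.0)
        np.testing.assert_allclose(g.values_mm_s, [1.0, 10.0])

    def test_reference_grid_common_ratio(self):
        # closed form: (2000/0.001)^(1/63) = (2e6)^(1/63)
        g = sim.make_velocity_grid(64, 0.001, 2000.0)
        expected = (2e6) ** (1.0 / 63.0)
        assert g.ratio == pytest.approx(expected, rel=1e-12)
        assert g.ratio == pytest.approx(1.2590, abs=5e-4)

    @pytest.mark.parametrize("n,vmin,vmax", [(1, 1, 10), (4, 0, 10),
                                             (4, -1, 10), (4, 10, 10),
                                             (4, 10, 1)])
    def test_invalid_grid_rejected(self, n, vmin, vmax):
        with pytest.raises(InvalidGridError):
            sim.make_velocity_grid(n, vmin, vmax)

    @given(n=st.integers(2, 40),
           vmin=st.floats(1e-3, 1.0),
           factor=st.floats(1.5, 1e5))
    @settings(max_examples=25, deadline=None)
    def test_geometric_spacing_property(self, n, vmin, factor):
        g = sim.make_velocity_grid(n, vmin, vmin * factor)
        ratios = g.values_mm_s[1:] / g.values_mm_s[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)


class TestForwardModel:
    def setup_method(self):
        self.beam = sim.BeamModel()
        self.timing = sim.ScanTiming()
        self.cfg = sim.ScattererConfig()

    def test_zero_velocity_gives_constant_intensity(self, rng):
        ts = sim.simulate_field(0.0, self.beam, self.timing, self.cfg, rng)
        assert ts.intensity.shape == (128,)
        np.testing.assert_allclose(ts.intensity, ts.intensity[0], rtol=1e-12)

    def test_intensity_is_squared_field(self, rng):
        ts = sim.simulate_field(30.0, self.beam, self.timing, self.cfg, rng)
        np.testing.assert_allclose(ts.intensity, np.abs(ts.field) ** 2)

    def test_fast_flow_decorrelates_within_one_ascan(self, rng):
        # v * tau >> beam diameter: adjacent samples are independent speckle
        v = 5000.0  # 50 um per A-scan period >> 18 um beam
        a = sim.simulate_fields(v, 1500, self.beam, self.timing, self.cfg, rng)
        i = np.abs(a) ** 2
        ic = i - i.mean()
        rho1 = (ic[:, 1:] * ic[:, :-1]).mean() / (ic ** 2).mean()
        assert abs(rho1) < 0.05

    def test_ensemble_mean_intensity_independent_of_velocity(self, rng):
        n = 3000
        means, ses = [], []
        for v in (5.0, 200.0):
            a = sim.simulate_fields(v, n, self.beam, self.timing, self.cfg, rng)
            per = (np.abs(a) ** 2).mean(axis=1)
            means.append(per.mean())
            ses.append(per.std(ddof=1) / math.sqrt(n))
        diff = abs(means[0] - means[1])
        assert diff < 3.0 * math.hypot(*ses)

    def test_ensemble_mean_matches_closed_form(self, rng):
        a = sim.simulate_fields(50.0, 4000, self.beam, self.timing, self.cfg, rng)
        measured = (np.abs(a) ** 2).mean()
        expected = sim.ensemble_mean_intensity(self.beam, self.cfg)
        assert measured == pytest.approx(expected, rel=0.05)

    def test_decorrelation_time_monotone_in_velocity(self, rng):
        """Lag-1 intensity autocorrelation is non-increasing on a velocity ladder."""
        rhos = []
        for v in (10.0, 40.0, 150.0, 500.0, 1500.0):
            a = sim.simulate_fields(v, 1000, self.beam, self.timing, self.cfg, rng)
            i = np.abs(a) ** 2
            ic = i - i.mean()
            rhos.append((ic[:, 1:] * ic[:, :-1]).mean() / (ic ** 2).mean())
        assert all(a >= b - 0.02 for a, b in zip(rhos[:-1], rhos[1:]))

    def test_short_strip_raises_coverage_error(self, rng):
        from octflow.exceptions import CoverageError
        with pytest.raises(CoverageError):
            sim.simulate_fields(100.0, 1, self.beam, self.timing, self.cfg,
                                rng, strip_override_um=(-30.0, 30.0))


class TestShotNoise:
    def setup_method(self):
        self.beam = sim.BeamModel()
        self.timing = sim.ScanTiming()
        self.cfg = sim.ScattererConfig()
        self.mean_i = sim.ensemble_mean_intensity(self.beam, self.cfg)

    def test_infinite_snr_is_identity(self, rng):
        ts = sim.simulate_field(20.0, self.beam, self.timing, self.cfg, rng)
        out = sim.add_shot_noise(ts, sim.NOISE_FREE, rng, self.mean_i)
        np.testing.assert_array_equal(out.intensity, ts.intensity)

    def test_zero_db_noise_variance_equals_mean_signal_intensity(self, rng):
        ts = sim.simulate_field(20.0, self.beam, self.timing, self.cfg, rng)
        noises = []
        for _ in range(400):
            out = sim.add_shot_noise(ts, 0.0, rng, self.mean_i)
            noises.append(np.abs(out.field - ts.field) ** 2)
        assert np.mean(noises) == pytest.approx(self.mean_i, rel=0.05)

    def test_requested_snr_recovered_within_tolerance(self, rng):
        """Monte-Carlo re-estimation of a 15 dB ensemble lands within 0.2 dB."""
        n = 10_000
        a = sim.simulate_fields(50.0, n, self.beam, self.timing, self.cfg, rng)
        sigma2 = self.mean_i / 10 ** (15.0 / 10.0)
        noise = math.sqrt(sigma2 / 2) * (rng.standard_normal(a.shape)
                                         + 1j * rng.standard_normal(a.shape))
        snr_est = 10 * np.log10((np.abs(a) ** 2).mean()
                                / (np.abs(noise) ** 2).mean())
        assert abs(snr_est - 15.0) < 0.2


class TestSelfNormalize:
    def test_constant_record_becomes_ones(self):
        ts = sim.TimeSeries(intensity=np.full(128, 7.3))
        np.testing.assert_allclose(sim.self_normalize(ts).intensity, 1.0)

    def test_unity_mean_and_idempotence(self, rng):
        ts = sim.TimeSeries(intensity=rng.exponential(2.0, size=128))
        out = sim.self_normalize(ts)
        assert out.intensity.mean() == pytest.approx(1.0, abs=1e-12)
        again = sim.self_normalize(out)
        np.testing.assert_allclose(again.intensity, out.intensity, rtol=1e-12)

    def test_field_consistency_preserved(self, rng):
        f = rng.standard_normal(128) + 1j * rng.standard_normal(128)
        ts = sim.TimeSeries(intensity=np.abs(f) ** 2, field=f)
        out = sim.self_normalize(ts)
        np.testing.assert_allclose(out.intensity, np.abs(out.field) ** 2)

    def test_zero_record_rejected(self):
        with pytest.raises(NormalizationError):
            sim.self_normalize(sim.TimeSeries(intensity=np.zeros(128)))


class TestLibrary:
    def test_full_configuration_accounting(self):
        spec = sim.LibrarySpec.paper_config()
        assert sim.n_records(spec) == 49_600_000
        assert spec.grid.n_classes == 64
        assert len(spec.snr_levels_db) == 31
        assert spec.train_count == 22_000 and spec.val_count == 3_000

    def test_tiny_library_record_count(self):
        spec = sim.LibrarySpec(
            grid=sim.make_velocity_grid(2, 1, 10), snr_levels_db=(15.0,),
            realizations_per_cell=10, train_count=8, val_count=2, seed=1)
        lib = sim.build_library(spec)
        assert len(lib) == 2 * 1 * 10
        assert lib.is_train.sum() == 16

    def test_split_counts_per_cell(self):
        spec = sim.LibrarySpec(
            grid=sim.make_velocity_grid(3, 1, 100), snr_levels_db=(10.0, 20.0),
            realizations_per_cell=20, train_count=15, val_count=5, seed=1)
        lib = sim.build_library(spec)
        for ci in range(3):
            for snr in (10.0, 20.0):
                cell = (lib.velocity_label == ci) & (lib.snr_label == snr)
                assert lib.is_train[cell].sum() == 15

    def test_determinism_bit_identical(self):
        spec = sim.LibrarySpec(
            grid=sim.make_velocity_grid(2, 5, 50), snr_levels_db=(15.0,),
            realizations_per_cell=12, train_count=10, val_count=2, seed=42)
        a = sim.build_library(spec)
        b = sim.build_library(spec)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_overcommitted_split_rejected(self):
        with pytest.raises(ValueError):
            sim.LibrarySpec(grid=sim.make_velocity_grid(2, 1, 10),
                            snr_levels_db=(15.0,), realizations_per_cell=10,
                            train_count=9, val_count=2)

    def test_hdf5_shard_round_trip(self, tmp_path):
        spec = sim.LibrarySpec(
            grid=sim.make_velocity_grid(2, 5, 50), snr_levels_db=(10.0, 20.0),
            realizations_per_cell=6, train_count=4, val_count=2, seed=7)
        lib = sim.build_library(spec)
        path = str(tmp_path / "lib.h5")
        sim.save_library(lib, path)
        back = sim.load_library(path)
        np.testing.assert_array_equal(back.intensity, lib.intensity)
        np.testing.assert_array_equal(back.velocity_label, lib.velocity_label)
        np.testing.assert_array_equal(back.is_train, lib.is_train)
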