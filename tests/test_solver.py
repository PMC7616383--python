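"""Wave propagator: stencil accuracy, stability, boundaries, filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from svifwi import (
    AcquisitionGeometry,
    DensityModel,
    SolverConfig,
    VelocityModel,
    check_stability,
    laplacian,
    lowpass_filter,
    ricker,
    simulate_shot,
    simulate_shot_variable_density,
)
from svifwi.solver import COURANT_LIMIT


class TestLaplacian:
    def test_constant_field_maps_to_zero(self):
        out = laplacian(np.full((20, 20), 3.7), 1e-3)
        np.testing.assert_allclose(out[5:-5, 5:-5], 0.0, atol=1e-6)

    def test_quadratic_reproduced_exactly(self):
        # x^2 has constant Laplacian 2; the 10th-order stencil is exact
        # on polynomials up to degree 11
        dx = 0.5
        x = np.arange(24) * dx
        field = np.tile(x**2, (24, 1))
        out = laplacian(field, dx)
        np.testing.assert_allclose(out[6:-6, 6:-6], 2.0, rtol=1e-9)

    def test_plane_wave_eigenvalue(self):
        # sin(kx) is an eigenfunction with eigenvalue -k^2; at 10 points
        # per wavelength the 10th-order dispersion error is tiny
        dx = 1.0
        k = 2 * np.pi / (10 * dx)
        x = np.arange(64) * dx
        field = np.tile(np.sin(k * x), (32, 1))
        out = laplacian(field, dx)
        inner = (slice(8, -8), slice(8, -8))
        np.testing.assert_allclose(out[inner], -k**2 * field[inner],
                                   atol=1e-6 * k**2)

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            laplacian(np.zeros((8, 8)), 1.0)


class TestStability:
    def test_in_silico_configuration_is_stable(self):
        # c_max 1540 m/s, dt 0.06 us, dx 0.5 mm -> Courant 0.1848
        m = VelocityModel(np.full((20, 20), 1540.0), 0.5e-3)
        rep = check_stability(m, 0.06e-6)
        assert rep.courant == pytest.approx(0.1848, abs=1e-4)
        assert rep.stable

    def test_zero_dt_rejected(self):
        m = VelocityModel(np.full((20, 20), 1500.0), 1e-3)
        with pytest.raises(ValueError):
            check_stability(m, 0.0)

    def test_dispersion_warning_flags_low_sampling(self):
        m = VelocityModel(np.full((20, 20), 1500.0), 1e-3)
        assert check_stability(m, 1e-7, frequency=1e6).dispersion_warning
        assert not check_stability(m, 1e-7,
                                   frequency=200e3).dispersion_warning

    @pytest.mark.parametrize("factor,ok", [(0.99, True), (1.05, False)])
    def test_energy_growth_probe_at_courant_bound(self, factor, ok):
        # just below the stencil bound the field stays bounded; just
        # above it the explicit scheme blows up
        c = 1500.0
        dx = 1e-3
        m = VelocityModel(np.full((40, 40), c), dx)
        dt = factor * COURANT_LIMIT * dx / c
        geom = AcquisitionGeometry(sources=[[0.020, 0.020]],
                                   receivers=[[0.020, 0.028]])
        wl = ricker(300e3, dt, 400)
        cfg = SolverConfig(sponge_cells=0, check_every=25)
        if ok:
            gather, _ = simulate_shot(m, geom, wl, config=cfg)
            assert np.all(np.isfinite(gather.traces))
        else:
            with pytest.raises((ValueError, RuntimeError)):
                simulate_shot(m, geom, wl, config=cfg)


class TestSimulateShot:
    def test_first_arrival_matches_travel_time(self, small_config):
        # 30 mm offset at 1500 m/s -> 20 us, within one dominant period
        m = VelocityModel(np.full((60, 60), 1500.0), 1e-3)
        geom = AcquisitionGeometry(sources=[[0.030, 0.015]],
                                   receivers=[[0.030, 0.045]])
        wl = ricker(370e3, 0.15e-6, 300)
        gather, _ = simulate_shot(m, geom, wl, config=small_config)
        env = np.abs(gather.traces[:, 0])
        arrival = np.argmax(env > 0.1 * env.max()) * wl.dt
        expected = 0.030 / 1500.0 + 1.5 / 370e3  # travel time + wavelet delay
        assert abs(arrival - expected) < 1 / 370e3

    def test_zero_wavelet_zero_gather(self, homogeneous_model,
                                      small_geometry, small_config):
        wl = ricker(370e3, 0.15e-6, 200).scaled(0.0)
        gather, _ = simulate_shot(homogeneous_model, small_geometry, wl,
                                  config=small_config)
        np.testing.assert_array_equal(gather.traces, 0.0)

    def test_reciprocity_on_homogeneous_model(self, small_config):
        m = VelocityModel(np.full((50, 50), 1500.0), 1e-3)
        a, b = (0.015, 0.020), (0.035, 0.030)
        wl = ricker(370e3, 0.15e-6, 300)
        g1, _ = simulate_shot(m, AcquisitionGeometry([a], [b]), wl,
                              config=small_config)
        g2, _ = simulate_shot(m, AcquisitionGeometry([b], [a]), wl,
                              config=small_config)
        scale = np.abs(g1.traces).max()
        np.testing.assert_allclose(g1.traces, g2.traces, atol=1e-8 * scale)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.floats(min_value=-5.0, max_value=5.0,
                     allow_nan=False, allow_subnormal=False))
    def test_linearity_in_the_source(self, scale):
        m = VelocityModel(np.full((40, 40), 1500.0), 1e-3)
        geom = AcquisitionGeometry(sources=[[0.012, 0.012]],
                                   receivers=[[0.028, 0.028]])
        cfg = SolverConfig(sponge_cells=8, check_every=1000)
        wl = ricker(370e3, 0.15e-6, 150)
        base, _ = simulate_shot(m, geom, wl, config=cfg)
        scaled, _ = simulate_shot(m, geom, wl.scaled(scale), config=cfg)
        np.testing.assert_allclose(scaled.traces, scale * base.traces,
                                   atol=1e-12)

    def test_wavefield_energy_absorbed_after_transit(self, small_config):
        # once the direct wave has left a homogeneous domain, the sponge
        # should have soaked up nearly all field energy
        m = VelocityModel(np.full((40, 40), 1500.0), 1e-3)
        geom = AcquisitionGeometry(sources=[[0.020, 0.020]],
                                   receivers=[[0.020, 0.028]])
        wl = ricker(370e3, 0.15e-6, 500)  # 75 us >> 40 mm transit
        _, store = simulate_shot(m, geom, wl, record_wavefield=True,
                                 config=small_config)
        energy = np.sum(store.snapshots**2, axis=(1, 2))
        assert energy[-1] < 0.05 * energy.max()


class TestVariableDensity:
    def test_uniform_density_matches_constant_density_solver(
            self, heterogeneous_model, small_geometry, small_wavelet,
            small_config):
        rho = DensityModel(np.full((40, 40), 1.010), 1e-3)
        ref, _ = simulate_shot(heterogeneous_model, small_geometry,
                               small_wavelet, config=small_config)
        var = simulate_shot_variable_density(
            heterogeneous_model, rho, small_geometry, small_wavelet,
            config=small_config)
        scale = np.abs(ref.traces).max()
        np.testing.assert_allclose(var.traces, ref.traces,
                                   atol=1e-9 * scale)

    def test_density_contrast_increases_backscatter(self, small_config):
        # impedance contrast at the circle boundary reflects energy back
        # towards a receiver beside the source
        n, dx = 60, 1e-3
        c = np.full((n, n), 1500.0)
        zz, xx = np.meshgrid(np.arange(n) * dx, np.arange(n) * dx,
                             indexing="ij")
        circle = (zz - 0.030) ** 2 + (xx - 0.030) ** 2 <= 0.010**2
        rho_u = np.full((n, n), 1.010)
        rho_c = rho_u.copy()
        rho_c[circle] = 1.220
        m = VelocityModel(c, dx)
        geom = AcquisitionGeometry(sources=[[0.030, 0.012]],
                                   receivers=[[0.034, 0.012]])
        wl = ricker(370e3, 0.15e-6, 400)
        uniform = simulate_shot_variable_density(
            m, DensityModel(rho_u, dx), geom, wl, config=small_config)
        contrast = simulate_shot_variable_density(
            m, DensityModel(rho_c, dx), geom, wl, config=small_config)
        # energy in the late (reflected) window
        window = slice(200, 400)
        e_u = np.sum(uniform.traces[window] ** 2)
        e_c = np.sum(contrast.traces[window] ** 2)
        assert e_c > e_u

    def test_zero_wavelet_zero_gather(self, heterogeneous_model,
                                      small_geometry, small_config):
        rho = DensityModel(np.full((40, 40), 1.1), 1e-3)
        wl = ricker(370e3, 0.15e-6, 100).scaled(0.0)
        g = simulate_shot_variable_density(
            heterogeneous_model, rho, small_geometry, wl,
            config=small_config)
        np.testing.assert_array_equal(g.traces, 0.0)


class TestLowpass:
    def _sine_gather(self, freq, dt=1e-7, nt=4000):
        t = np.arange(nt) * dt
        from svifwi import ShotGather
        return ShotGather(np.sin(2 * np.pi * freq * t)[:, None], dt)

    def test_passband_amplitude_preserved(self):
        g = self._sine_gather(100e3)
        out = lowpass_filter(g, 700e3)
        assert np.abs(out.traces).max() == pytest.approx(1.0, rel=1e-3)

    def test_stopband_attenuation(self):
        g = self._sine_gather(1.4e6)
        out = lowpass_filter(g, 700e3)
        # 8th-order Butterworth magnitude at 2x cutoff: ~1/2^8
        assert np.abs(out.traces[100:-100]).max() < 2 ** -7

    def test_double_filtering_close_to_single(self):
        g = self._sine_gather(200e3)
        once = lowpass_filter(g, 700e3)
        twice = lowpass_filter(once, 700e3)
        np.testing.assert_allclose(twice.traces, once.traces, atol=2e-3)

    def test_cutoff_above_nyquist_rejected(self):
        g = self._sine_gather(100e3)
        with pytest.raises(ValueError):
            lowpass_filter(g, 6e6)
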