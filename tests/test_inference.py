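"""Variational updates, the inversion loop, and its contracts."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import svifwi.solver as solver_module
from svifwi import (
    AcquisitionGeometry,
    GradientImage,
    InversionConfig,
    InversionReport,
    PriorSpec,
    SVIWaveTomography,
    SolverConfig,
    VariationalParams,
    VelocityModel,
    init_from_prior,
    ricker,
    run_fwi,
    run_inversion,
    sample_model,
    simulate_shot,
    update_mean,
    update_sigma,
    variance_image,
)
from svifwi.inference import SampleDraw


class TestPriorInitialisation:
    def test_stated_prior_broadcasts(self):
        # mean 1480 m/s, variance 4 (m/s)^2 -> sigma 2 everywhere
        p = init_from_prior(PriorSpec(1480.0, 4.0), (8, 9))
        np.testing.assert_array_equal(p.mu, 1480.0)
        np.testing.assert_array_equal(p.sigma, 2.0)

    def test_zero_variance_degenerates(self):
        p = init_from_prior(PriorSpec(1480.0, 0.0), (5, 5))
        np.testing.assert_array_equal(p.sigma, 0.0)

    def test_grid_valued_prior_round_trips(self):
        rng = np.random.default_rng(0)
        mu = 1450 + rng.random((6, 7))
        var = rng.random((6, 7))
        p = init_from_prior(PriorSpec(mu, var), (6, 7))
        np.testing.assert_array_equal(p.mu, mu)
        np.testing.assert_allclose(p.sigma, np.sqrt(var))

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(1480.0, -1.0)


class TestSampling:
    def test_deterministic_draw_returns_mean(self):
        p = VariationalParams(np.full((4, 4), 1480.0), np.full((4, 4), 2.0))
        d = sample_model(p, np.random.default_rng(0), deterministic=True)
        np.testing.assert_array_equal(d.model_sample, p.mu)
        np.testing.assert_array_equal(d.epsilon, 0.0)

    def test_reparameterisation_arithmetic(self):
        p = VariationalParams(np.full((3, 3), 1480.0), np.full((3, 3), 2.0))
        d = sample_model(p, np.random.default_rng(1))
        np.testing.assert_array_equal(d.model_sample,
                                      1480.0 + 2.0 * d.epsilon)

    def test_moments_of_many_draws(self):
        p = VariationalParams(np.array([[1480.0]]), np.array([[2.0]]))
        rng = np.random.default_rng(2)
        draws = np.array([sample_model(p, rng).model_sample[0, 0]
                          for _ in range(10_000)])
        se_mean = 2.0 / np.sqrt(draws.size)
        assert abs(draws.mean() - 1480.0) < 3 * se_mean
        se_std = 2.0 / np.sqrt(2 * (draws.size - 1))
        assert abs(draws.std(ddof=1) - 2.0) < 3 * se_std

    def test_clipping_counts_events(self):
        p = VariationalParams(np.full((4, 4), 1790.0), np.full((4, 4), 50.0))
        d = sample_model(p, np.random.default_rng(3), clip=(1300.0, 1800.0))
        assert d.clipped > 0
        assert d.model_sample.max() <= 1800.0


class TestUpdates:
    def test_zero_gradient_leaves_mean(self):
        p = VariationalParams(np.full((4, 4), 1480.0), np.full((4, 4), 2.0))
        out = update_mean(p, GradientImage(np.zeros((4, 4)), 1e-3), 0.1)
        np.testing.assert_array_equal(out.mu, p.mu)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_successive_mean_updates_compose_linearly(self, seed):
        rng = np.random.default_rng(seed)
        p = VariationalParams(1500 + rng.random((5, 5)), rng.random((5, 5)))
        g1 = GradientImage(rng.standard_normal((5, 5)), 1e-3)
        g2 = GradientImage(rng.standard_normal((5, 5)), 1e-3)
        a, b = rng.random(2)
        two_step = update_mean(update_mean(p, g1, a), g2, b)
        combined = update_mean(
            p, GradientImage(a * g1.delta_m + b * g2.delta_m, 1e-3), 1.0)
        np.testing.assert_allclose(two_step.mu, combined.mu, atol=1e-12)

    def test_sigma_untouched_by_mean_update(self):
        p = VariationalParams(np.full((3, 3), 1500.0), np.full((3, 3), 2.0))
        out = update_mean(p, GradientImage(np.ones((3, 3)), 1e-3), 0.5)
        np.testing.assert_array_equal(out.sigma, p.sigma)

    def test_sigma_update_elementwise_arithmetic(self):
        # eps = [1, -1], delta_m = [0.5, 0.5], step 1, sigma starts at 0
        p = VariationalParams(np.zeros((1, 2)), np.zeros((1, 2)))
        eps = np.array([[1.0, -1.0]])
        draw = SampleDraw(eps, p.mu + p.sigma * eps)
        g = GradientImage(np.array([[0.5, 0.5]]), 1e-3)
        out = update_sigma(p, g, draw, 1.0)
        np.testing.assert_array_equal(out.sigma, [[-0.5, 0.5]])
        np.testing.assert_array_equal(variance_image(out), [[0.25, 0.25]])

    def test_zero_epsilon_freezes_sigma(self):
        p = VariationalParams(np.full((3, 3), 1500.0), np.full((3, 3), 2.0))
        draw = SampleDraw(np.zeros((3, 3)), p.mu.copy())
        g = GradientImage(np.ones((3, 3)), 1e-3)
        out = update_sigma(p, g, draw, 0.7)
        np.testing.assert_array_equal(out.sigma, p.sigma)

    def test_variance_image_sign_invariant(self):
        rng = np.random.default_rng(5)
        sigma = rng.standard_normal((6, 6))
        p = VariationalParams(np.zeros((6, 6)), sigma)
        q = VariationalParams(np.zeros((6, 6)), -sigma)
        assert np.all(variance_image(p) >= 0)
        np.testing.assert_array_equal(variance_image(p), variance_image(q))


@pytest.fixture(scope="module")
def tiny_problem():
    """A 40x40 single-inclusion problem small enough for loop tests."""
    grid, dx = (40, 40), 1e-3
    c = np.full(grid, 1500.0)
    c[16:24, 16:24] = 1520.0
    truth = VelocityModel(c, dx)
    geom = AcquisitionGeometry(
        sources=[[0.012, 0.012], [0.028, 0.012], [0.020, 0.028]],
        receivers=[[0.012, 0.028], [0.028, 0.028], [0.020, 0.012],
                   [0.028, 0.020]])
    cfg = SolverConfig(sponge_cells=8, check_every=1000)
    wl = ricker(370e3, 0.15e-6, 250)
    observed = []
    for s in range(geom.n_sources):
        g, _ = simulate_shot(truth, geom, wl, s, config=cfg)
        observed.append(g)
    return dict(grid=grid, dx=dx, geom=geom, wl=wl, observed=observed,
                solver=cfg)


def _loop_config(tp, **kw):
    base = dict(cutoff=None, step_fraction=0.02, iterations=10,
                batch_size=1, seed=5, solver=tp["solver"])
    base.update(kw)
    return InversionConfig(**base)


class TestInversionLoop:
    def test_deterministic_mode_reduces_to_classical_fwi(self, tiny_problem):
        """With eps forced to zero the mu trajectory equals plain FWI
        gradient descent bit for bit."""
        tp = tiny_problem
        svi = run_inversion(tp["observed"], tp["geom"], tp["wl"],
                            tp["grid"], tp["dx"],
                            _loop_config(tp, deterministic=True),
                            PriorSpec(1495.0, 4.0))
        fwi = run_fwi(tp["observed"], tp["geom"], tp["wl"], tp["grid"],
                      tp["dx"], _loop_config(tp), PriorSpec(1495.0, 4.0))
        np.testing.assert_array_equal(svi.mu, fwi.mu)
        np.testing.assert_array_equal(svi.misfit, fwi.misfit)
        np.testing.assert_array_equal(svi.sigma, 2.0)  # frozen at prior

    def test_fixed_seed_is_bit_reproducible(self, tiny_problem):
        tp = tiny_problem
        kw = dict(config=_loop_config(tp), prior=PriorSpec(1495.0, 4.0))
        r1 = run_inversion(tp["observed"], tp["geom"], tp["wl"],
                           tp["grid"], tp["dx"], **kw)
        r2 = run_inversion(tp["observed"], tp["geom"], tp["wl"],
                           tp["grid"], tp["dx"], **kw)
        np.testing.assert_array_equal(r1.mu, r2.mu)
        np.testing.assert_array_equal(r1.sigma, r2.sigma)
        np.testing.assert_array_equal(r1.misfit, r2.misfit)

    def test_checkpoint_resume_continues_identically(self, tiny_problem,
                                                     tmp_path):
        tp = tiny_problem
        kw = dict(config=_loop_config(tp), prior=PriorSpec(1495.0, 4.0))
        full = run_inversion(tp["observed"], tp["geom"], tp["wl"],
                             tp["grid"], tp["dx"], **kw)
        ck = tmp_path / "ck.npz"
        partial_cfg = _loop_config(tp, iterations=5)
        run_inversion(tp["observed"], tp["geom"], tp["wl"], tp["grid"],
                      tp["dx"], partial_cfg, PriorSpec(1495.0, 4.0),
                      checkpoint_path=ck, checkpoint_every=5)
        resumed = run_inversion(tp["observed"], tp["geom"], tp["wl"],
                                tp["grid"], tp["dx"], _loop_config(tp),
                                PriorSpec(1495.0, 4.0),
                                checkpoint_path=ck)
        np.testing.assert_array_equal(resumed.mu, full.mu)
        np.testing.assert_array_equal(resumed.sigma, full.sigma)

    def test_sigma_update_runs_no_simulation_inside_loop(self):
        """update_sigma is pure recycling: the propagation counter must
        not move."""
        rng = np.random.default_rng(0)
        p = VariationalParams(1500 + rng.random((120, 120)),
                              rng.random((120, 120)))
        g = GradientImage(rng.standard_normal((120, 120)), 1e-3)
        draw = SampleDraw(rng.standard_normal((120, 120)),
                          p.mu + p.sigma * 0)
        before = solver_module.simulation_counter
        for _ in range(20):
            update_sigma(p, g, draw, 0.1)
        assert solver_module.simulation_counter == before

    def test_round_robin_batches_cycle_all_sources(self, tiny_problem):
        tp = tiny_problem
        rep = run_inversion(tp["observed"], tp["geom"], tp["wl"],
                            tp["grid"], tp["dx"],
                            _loop_config(tp, iterations=6),
                            PriorSpec(1495.0, 4.0))
        flat = [s for b in rep.batches for s in b]
        assert flat == [0, 1, 2, 0, 1, 2]

    def test_report_round_trip(self, tiny_problem, tmp_path):
        tp = tiny_problem
        rep = run_inversion(tp["observed"], tp["geom"], tp["wl"],
                            tp["grid"], tp["dx"],
                            _loop_config(tp, iterations=3),
                            PriorSpec(1495.0, 4.0))
        for name in ("rep.h5", "rep.json"):
            path = tmp_path / name
            rep.save(path)
            back = InversionReport.load(path)
            np.testing.assert_allclose(back.mu, rep.mu)
            np.testing.assert_allclose(back.mean_variance,
                                       rep.mean_variance)
            assert back.seed == rep.seed


class TestModelResultsSurface:
    def test_fit_returns_summary_and_images(self, tiny_problem):
        tp = tiny_problem
        model = SVIWaveTomography(tp["observed"], tp["geom"], tp["wl"],
                                  tp["grid"], tp["dx"],
                                  prior=PriorSpec(1495.0, 4.0),
                                  config=_loop_config(tp, iterations=4))
        res = model.fit(seed=9)
        assert res.mean_model.shape == tp["grid"]
        assert res.variance.min() >= 0
        assert len(res.misfit_trace) == 4
        text = res.summary()
        assert "iterations" in text and "mean variance" in text
        assert f"seed                 9" in text

    def test_geometry_outside_margin_rejected(self, tiny_problem):
        tp = tiny_problem
        bad_geom = AcquisitionGeometry(sources=[[0.001, 0.02]],
                                       receivers=[[0.02, 0.02]])
        with pytest.raises(ValueError, match="absorbing margin"):
            SVIWaveTomography(tp["observed"][:1], bad_geom, tp["wl"],
                              tp["grid"], tp["dx"],
                              config=_loop_config(tp))
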