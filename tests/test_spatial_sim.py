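"""Lattice simulator: growth, conservation, diffusion, relays, feedback."""

import numpy as np
import pytest
from dataclasses import replace

from orthosignal.core_model import simplified_rate
from orthosignal.spatial_sim import (GompertzGrowth, GridLayout, GridState,
                                     SpatialParameters, StabilityError,
                                     bifurcation_scan, checkerboard_layout,
                                     fit_gompertz, gompertz_capacity,
                                     run_stripe_experiment,
                                     sender_receiver_layout, simulate, step,
                                     stripe_layout)


class TestGompertz:
    def test_asymptote_and_inflection_identities(self):
        g = GompertzGrowth(K_cap=3.0, k_g=0.01, t_i=300.0)
        assert gompertz_capacity(g, 1e7) == pytest.approx(3.0)
        assert gompertz_capacity(g, g.t_i) == pytest.approx(3.0 / np.e)

    def test_initial_fraction_roundtrip(self):
        g = GompertzGrowth.from_initial_fraction(1.0, 0.01, 1e-3)
        assert g.initial_fraction == pytest.approx(1e-3, rel=1e-9)
        assert gompertz_capacity(g, 0.0) == pytest.approx(1e-3, rel=1e-9)

    def test_refit_recovers_noiseless_parameters(self):
        g = GompertzGrowth(K_cap=2.5, k_g=0.009, t_i=420.0)
        t = np.arange(0.0, 1501.0, 10.0)
        fit = fit_gompertz(t, gompertz_capacity(g, t))
        assert fit.K_cap == pytest.approx(g.K_cap, rel=1e-6)
        assert fit.k_g == pytest.approx(g.k_g, rel=1e-6)
        assert fit.t_i == pytest.approx(g.t_i, rel=1e-6)


class TestStep:
    def _inert_params(self):
        # no synthesis, no decay: only diffusion moves signal around
        return SpatialParameters(k_syn6=0.0, k_syn12=0.0, k_deg6=0.0,
                                 k_deg12=0.0)

    def test_mass_conserved_without_production_or_decay(self):
        p = self._inert_params()
        rng = np.random.default_rng(0)
        init = rng.uniform(0, 100, (8, 8))
        layout = GridLayout(devices=np.full((8, 8), "receiver",
                                            dtype=object),
                            init_c6=init, init_c12=2 * init)
        state = GridState.initial(layout, p)
        t6, t12 = state.total_signal()
        dt = 0.2 * p.stability_limit(layout.pitch_mm)
        for _ in range(1000):
            state = step(state, layout, p, dt)
        e6, e12 = state.total_signal()
        assert abs(e6 - t6) / t6 < 1e-9
        assert abs(e12 - t12) / t12 < 1e-9

    def test_uniform_field_stays_uniform(self):
        p = self._inert_params()
        layout = GridLayout(devices=np.full((6, 6), "empty", dtype=object),
                            init_c6=np.full((6, 6), 42.0))
        state = GridState.initial(layout, p)
        for _ in range(200):
            state = step(state, layout, p, 5.0)
        assert np.ptp(state.c6) == pytest.approx(0.0, abs=1e-12)

    def test_oversized_step_raises_with_bound(self, spatial_params):
        layout = GridLayout(devices=np.full((4, 4), "empty", dtype=object))
        state = GridState.initial(layout, spatial_params)
        limit = spatial_params.stability_limit(layout.pitch_mm)
        with pytest.raises(StabilityError, match="maximum admissible"):
            step(state, layout, spatial_params, 2.1 * limit)

    def test_point_release_matches_finer_timestep_reference(self):
        # 4x-finer-step oracle for the explicit scheme, 1% tolerance;
        # pure transport (no production or decay) isolates diffusion
        p = SpatialParameters(k_syn6=0.0, k_syn12=0.0, k_deg6=0.0,
                              k_deg12=0.0)
        n = 11
        init = np.zeros((n, n))
        init[n // 2, n // 2] = 1000.0
        layout = GridLayout(devices=np.full((n, n), "empty", dtype=object),
                            init_c6=init)
        dt = 0.1 * p.stability_limit(layout.pitch_mm)

        def run(step_size):
            state = GridState.initial(layout, p)
            k = int(round(600.0 / step_size))
            for _ in range(k):
                state = step(state, layout, p, step_size)
            return state.c6

        coarse = run(dt)
        fine = run(dt / 4.0)
        assert np.max(np.abs(coarse - fine)) / np.max(fine) < 0.01
        # radial symmetry of the spread profile
        assert np.allclose(coarse, coarse[::-1, :], rtol=1e-12)
        assert np.allclose(coarse, coarse.T, rtol=1e-12)


class TestSimulate:
    def test_reflected_layout_gives_reflected_trajectory(self,
                                                         spatial_params):
        lay = sender_receiver_layout(n_rows=6, n_cols=5)
        mirrored = GridLayout(devices=lay.devices[:, ::-1].copy(),
                              pitch_mm=lay.pitch_mm)
        a = simulate(lay, spatial_params, 400.0, save_every_min=200)
        b = simulate(mirrored, spatial_params, 400.0, save_every_min=200)
        # identical up to summation order in the mirrored Laplacian
        np.testing.assert_allclose(a.final().c6, b.final().c6[:, ::-1],
                                   rtol=1e-12)
        np.testing.assert_allclose(a.final().cfp, b.final().cfp[:, ::-1],
                                   rtol=1e-12)

    def test_deterministic_rerun_is_bit_identical(self, spatial_params):
        lay = sender_receiver_layout(n_rows=4, n_cols=4)
        a = simulate(lay, spatial_params, 300.0)
        b = simulate(lay, spatial_params, 300.0)
        np.testing.assert_array_equal(a.final().cfp, b.final().cfp)

    def test_all_empty_layout_stays_basal(self, spatial_params):
        lay = GridLayout(devices=np.full((5, 5), "empty", dtype=object))
        traj = simulate(lay, spatial_params, 500.0)
        assert np.all(traj.final().cfp == 0.0)
        assert np.all(traj.final().c6 == 0.0)

    def test_sender_gradient_decreases_with_distance(self, spatial_params):
        lay = sender_receiver_layout(n_rows=8, n_cols=7)
        traj = simulate(lay, spatial_params, 1500.0)
        prof = traj.normalized("cfp")[-1][:, 1:].mean(axis=0)
        assert np.all(np.diff(prof) < 0)

    def test_clamped_single_square_reproduces_liquid_dose_response(
            self, spatial_params):
        # a lone population in a uniform, non-decaying signal bath must
        # report the liquid-culture transfer function at every dose
        p = replace(spatial_params, k_deg6=0.0, k_deg12=0.0,
                    k_syn6=0.0, k_syn12=0.0)
        for c6 in (0.0, 50.0, 500.0):
            lay = GridLayout(devices=np.array([["receiver"]], dtype=object),
                             init_c6=np.array([[c6]]))
            state = GridState.initial(lay, p)
            dt = 1.0
            s2 = step(state, lay, p, dt)
            cap = state.capacity[0, 0]
            expected = simplified_rate(p.cfp_params, c6, 0.0) * cap * dt
            assert s2.cfp[0, 0] == pytest.approx(expected, rel=1e-12)


class TestRelaysAndFeedback:
    def test_relay_bath_uniform_received_channel_with_sent_gradient(
            self, spatial_params):
        # pLas81-LuxI relay rows in a uniform 3OC12HSL bath: the received
        # (YFP) response is uniform across all populated squares, while
        # the sent signal (3OC6HSL -> CFP) peaks at the relay squares and
        # decays with distance from them
        n_rows, n_cols = 8, 6
        dev = np.full((n_rows, n_cols), "receiver", dtype=object)
        dev[0:2, :] = "relay_C12toC6"
        lay = GridLayout(devices=dev,
                         init_c12=np.full((n_rows, n_cols), 400.0))
        # slow the bath's decay so induction stays uniform over the run
        p = replace(spatial_params, k_deg12=0.0)
        traj = simulate(lay, p, 1200.0)
        yfp = traj.normalized("yfp")[-1]
        assert np.ptp(yfp) / yfp.mean() < 0.05
        cfp_profile = traj.normalized("cfp")[-1].mean(axis=1)
        assert cfp_profile[0] == max(cfp_profile)
        assert np.all(np.diff(cfp_profile[1:]) < 0)

    def test_alternating_relay_stripes_propagate(self, spatial_params):
        rep = run_stripe_experiment(stripe_layout(5, 2, 6), spatial_params,
                                    horizon_min=3000.0)
        assert rep.propagated
        times = [t for t in rep.activation_times if t is not None]
        assert times == sorted(times)

    def test_relay_with_empty_partner_does_not_propagate(self,
                                                         spatial_params):
        lay = stripe_layout(4, 2, 6, relay_b="empty")
        rep = run_stripe_experiment(lay, spatial_params, horizon_min=3000.0)
        assert not rep.propagated
        # only the stripe(s) adjacent to the plated signal band respond
        relay_times = [t for d, t in zip(rep.stripe_devices,
                                         rep.activation_times)
                       if d.startswith("relay_")]
        assert any(t is None for t in relay_times)

    def test_zero_initial_signal_activates_nothing(self, spatial_params):
        lay = stripe_layout(3, 2, 6, init_c12_band_nM=0.0)
        rep = run_stripe_experiment(lay, spatial_params, horizon_min=1500.0)
        assert all(t is None for t in rep.activation_times)

    def test_bifurcation_scan_brackets_threshold(self, spatial_params):
        res = bifurcation_scan(spatial_params, [0.0, 0.25, 0.5, 1.0],
                               refine_resolution=0.05,
                               horizon_min=20000.0)
        assert not res.on[0]  # zero production can never switch on
        assert res.on[-1]
        assert res.threshold is not None
        # bisection refinement stays inside the coarse bracket
        flip = int(np.flatnonzero(res.on[1:] != res.on[:-1])[0])
        assert res.scales[flip] <= res.threshold <= res.scales[flip + 1]
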