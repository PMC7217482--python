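"""Stochastic cable simulator: lattice construction, stepping scheme,
boundary handling, threshold-reset semantics and statistical calibration
against the analytic results.
"""

import math

import numpy as np
import pytest

from neurice.closed import one_dendrite_stats, two_dendrite_stats
from neurice.exceptions import MisalignedTriggerError, StabilityError
from neurice.params import build_morphology
from neurice.sim import (apply_boundaries, build_lattice, detect_and_reset,
                         em_step, init_state, run_simulation)
from neurice.spectral import stats_from_psd


class TestBuildLattice:
    def test_node_count_for_default_truncation(self):
        m, _ = build_morphology(mu=5.0, sigma_s=1.0, lambda_1=100.0)
        lat = build_lattice(m, dx=20.0)
        assert lat.n_nodes == (50,)  # L = 1000 um / 20 um
        m2, _ = build_morphology(mu=5.0, sigma_s=1.0, lambda_1=200.0)
        assert build_lattice(m2, dx=20.0).n_nodes == (100,)  # 10 lambda

    def test_truncation_extends_with_lambda(self):
        m, _ = build_morphology(mu=5.0, sigma_s=1.0, lambda_1=150.0,
                                tau_1=40.0)
        lat = build_lattice(m, dx=20.0)
        assert lat.n_nodes == (75,)  # 10 lambda = 1500 um

    def test_trigger_node_for_axon_initial_segment(self, dendrite_axon):
        m, _ = dendrite_axon
        lat = build_lattice(m)
        assert lat.trigger_neurite == 1
        assert lat.trigger_node == 1  # node centres at 10, 30, 50 ... um

    def test_junction_trigger_for_zero_offset(self, two_dendrite):
        m, _ = two_dendrite
        lat = build_lattice(m)
        assert lat.junction == "nominal"
        assert lat.trigger_node == -1

    def test_misaligned_trigger_rejected(self):
        m, _ = build_morphology(mu=5.0, sigma_s=3.0, a_ratio=0.25, x_th=25.0)
        with pytest.raises(MisalignedTriggerError):
            build_lattice(m, dx=20.0)

    def test_paper_step_sizes_accepted_but_stiff_config_rejected(self):
        m, _ = build_morphology(mu=5.0, sigma_s=1.0)
        build_lattice(m, dx=20.0, dt=0.02)  # verified-stable configuration
        m4, _ = build_morphology(mu=5.0, sigma_s=1.0, lambda_1=400.0)
        with pytest.raises(StabilityError):
            build_lattice(m4, dx=20.0, dt=0.02)
        build_lattice(m4, dx=20.0, dt=0.005)


class TestStepping:
    def test_uniform_voltage_decays_without_noise_or_drive(self):
        m, d = build_morphology(mu=0.0, sigma_s=0.0)
        lat = build_lattice(m)
        state = init_state(lat)
        state.v[:] = 3.0
        state = apply_boundaries(state, lat, m, d)
        assert np.allclose(state.dxv, 0.0)
        from neurice.sim import _compile
        arr = _compile(m, d, lat)
        nxt = em_step(state, lat, m, d, noise=np.zeros(arr.n_driven))
        assert np.allclose(nxt.v, 3.0 * (1.0 - lat.dt / 10.0))

    def test_kernel_matches_reference_step(self, dendrite_axon):
        """The compiled chunk kernel and the numpy reference implementation
        must produce the same trajectory for the same noise stream."""
        m, d = dendrite_axon
        lat = build_lattice(m, seed=7)
        n_steps = 200
        rng = np.random.default_rng(7)
        from neurice.sim import _compile, _kernel
        arr = _compile(m, d, lat)
        noise = rng.standard_normal((n_steps, arr.n_driven))
        state = init_state(lat)
        for i in range(n_steps):
            state = em_step(state, lat, m, d, noise=noise[i])
        v_ref = state.v.copy()
        ref_state = init_state(lat)
        v0 = np.array([0.0])
        vn = np.empty_like(ref_state.v)
        trace = np.empty(n_steps)
        spikes = np.empty(n_steps, dtype=np.int64)
        sel = np.empty(0, dtype=np.int64)
        _kernel(ref_state.v, ref_state.s, ref_state.dxv, v0, vn, noise,
                spikes, trace, sel, np.zeros(0), np.zeros(0), arr.off,
                arr.nn, arr.doff, arr.drv, arr.dt_tau, arr.lam2dx, arr.mu,
                arr.amp, arr.wj, arr.rho_lam, arr.joined, lat.dx, lat.dt,
                d.tau_s, arr.tau0, arr.jkind, arr.trig_idx, 1e9, 0.0, 0)
        assert np.allclose(ref_state.v, v_ref, rtol=1e-12, atol=1e-12)

    def test_synaptic_field_stationary_variance(self):
        """Discrete OU variance per site: 2 sigma_s^2 lambda / dx, with the
        O(dt/tau_s) Euler correction 1/(1 - dt/(2 tau_s))."""
        m, d = build_morphology(mu=0.0, sigma_s=1.0)
        lat = build_lattice(m, seed=42)
        state = init_state(lat)
        rng = np.random.default_rng(42)
        from neurice.sim import _compile
        arr = _compile(m, d, lat)
        samples = []
        for i in range(30000):
            state = em_step(state, lat, m, d,
                            noise=rng.standard_normal(arr.n_driven))
            if i >= 2000 and i % 25 == 0:
                samples.append(state.s.copy())
        var = np.concatenate(samples).var()
        a = lat.dt / d.tau_s
        expected = 2.0 * 200.0 / 20.0 / (1.0 - a / 2.0)
        assert var == pytest.approx(expected, rel=0.05)

    def test_blowup_detected_for_unstable_step(self):
        from neurice.exceptions import NumericalBlowupError
        m, d = build_morphology(mu=5.0, sigma_s=1.0)
        lat = build_lattice(m, dt=0.02)
        bad = type(lat)(dx=lat.dx, dt=1.0, n_nodes=lat.n_nodes,
                        junction=lat.junction,
                        trigger_neurite=lat.trigger_neurite,
                        trigger_node=lat.trigger_node, seed=0)
        with pytest.raises(NumericalBlowupError):
            run_simulation(m, d, bad, duration=2000.0, seed=0)


class TestBoundariesAndReset:
    def test_mirror_symmetric_junction_has_zero_flux(self, two_dendrite):
        m, d = two_dendrite
        lat = build_lattice(m)
        state = init_state(lat)
        n = lat.n_nodes[0]
        profile = np.exp(-np.arange(n) / 7.0)
        state.v[:n] = profile
        state.v[n:] = profile
        state = apply_boundaries(state, lat, m, d)
        from neurice.sim import _compile
        arr = _compile(m, d, lat)
        flux = sum(arr.wj[k] * state.dxv[arr.doff[k]] for k in range(2))
        assert flux == pytest.approx(0.0, abs=1e-12)
        # each neurite's end gradient vanishes by symmetry
        assert state.dxv[arr.doff[0]] == pytest.approx(0.0, abs=1e-12)

    def test_reset_clears_voltage_everywhere_but_not_synapses(self,
                                                              dendrite_axon):
        m, d = dendrite_axon
        lat = build_lattice(m)
        state = init_state(lat)
        state.v[:] = 11.0  # above threshold everywhere
        state.s[:] = 2.5
        out, spiked = detect_and_reset(state, lat, m, d)
        assert spiked
        assert np.allclose(out.v, m.threshold.v_re)
        assert np.allclose(out.s, 2.5)

    def test_subthreshold_state_untouched(self, dendrite_axon):
        m, d = dendrite_axon
        lat = build_lattice(m)
        state = init_state(lat)
        state.v[:] = m.threshold.v_th - 1e-6
        out, spiked = detect_and_reset(state, lat, m, d)
        assert not spiked
        assert out is state


class TestRunStatistics:
    def test_silent_without_noise_below_threshold(self):
        m, d = build_morphology(mu=5.0, sigma_s=0.0)
        lat = build_lattice(m, seed=0)
        res = run_simulation(m, d, lat, duration=2000.0, seed=0)
        assert res.spikes.count == 0
        assert res.rate_hz == 0.0

    def test_reset_and_free_runs_coincide_until_first_spike(self):
        m, d = build_morphology(mu=8.0, sigma_s=3.0)
        lat = build_lattice(m, seed=3)
        kw = dict(duration=4000.0, transient=0.0, seed=3, record_trace=True)
        r_reset = run_simulation(m, d, lat, mode="reset", **kw)
        r_free = run_simulation(m, d, lat, mode="no-reset", **kw)
        assert r_reset.spikes.count > 0
        first = int(round(r_reset.spikes.times[0] / lat.dt)) - 1
        assert np.array_equal(r_reset.trace[:first + 1],
                              r_free.trace[:first + 1])
        assert not np.array_equal(r_reset.trace, r_free.trace)

    def test_sealed_end_variance_matches_closed_form(self, one_dendrite):
        m, d = one_dendrite
        lat = build_lattice(m, seed=5)
        cf = one_dendrite_stats(d, 10.0)
        vs = [run_simulation(m, d, lat, duration=20000.0, mode="no-reset",
                             seed=s).var for s in range(5, 9)]
        se = np.std(vs, ddof=1) / math.sqrt(len(vs))
        assert np.mean(vs) == pytest.approx(cf.variance, abs=3 * se)

    def test_junction_variance_matches_spectral_engine(self, dendrite_axon):
        m, d = dendrite_axon
        st = stats_from_psd(m, d)
        lat = build_lattice(m, seed=11)
        res = [run_simulation(m, d, lat, duration=20000.0, mode="no-reset",
                              seed=s) for s in (11, 12, 13)]
        vs = [r.var for r in res]
        se = np.std(vs, ddof=1) / math.sqrt(3)
        # 3 SE plus a 2% allowance for the O(dx) junction discretization
        assert abs(np.mean(vs) - st.variance) < 3 * se + 0.02 * st.variance
        ms = [r.stats.mean for r in res]
        assert np.mean(ms) == pytest.approx(st.mean, rel=0.02)

    def test_axonal_mean_decays_electrotonically(self):
        m, d = build_morphology(mu=5.0, sigma_s=1.0, a_ratio=0.25, x_th=30.0)
        lat = build_lattice(m, seed=17)
        # axon voltage nodes follow the dendrite block
        n_dend = lat.n_nodes[0]
        nodes = [n_dend + j for j in (0, 2, 4, 8)]
        res = run_simulation(m, d, lat, duration=30000.0, mode="no-reset",
                             seed=17, record_nodes=nodes)
        lam_a = m.axon.lam
        x = (np.array([0, 2, 4, 8]) + 0.5) * lat.dx
        expected = np.exp(-(x - x[0]) / lam_a)
        measured = res.node_means / res.node_means[0]
        assert np.allclose(measured, expected, rtol=0.03)

    def test_grid_refinement_leaves_variance_unchanged(self, one_dendrite):
        """Halving dx and quartering dt changes the sealed-end variance by
        less than the Monte-Carlo uncertainty."""
        m, d = one_dendrite
        coarse = run_simulation(m, d, build_lattice(m, dx=20.0, dt=0.02),
                                duration=20000.0, mode="no-reset", seed=23)
        fine = run_simulation(m, d, build_lattice(m, dx=10.0, dt=0.005),
                              duration=20000.0, mode="no-reset", seed=24)
        tol = 3 * math.hypot(coarse.var_se, fine.var_se)
        assert abs(coarse.var - fine.var) < tol

    def test_two_dendrite_junction_variance_is_half(self, two_dendrite):
        m2, d = two_dendrite
        cf = two_dendrite_stats(d, 10.0)
        lat = build_lattice(m2, seed=31)
        vs = [run_simulation(m2, d, lat, duration=20000.0, mode="no-reset",
                             seed=s).var for s in (31, 32, 33)]
        se = np.std(vs, ddof=1) / math.sqrt(3)
        assert np.mean(vs) == pytest.approx(cf.variance, abs=3 * se)
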