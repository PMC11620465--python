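"""Network integration: determinism, LFP extraction, regime equivalence."""

import numpy as np
import pytest

import ephapsim as es
from ephapsim import _kernels
from ephapsim.dynamics import NetworkState, SynapseParams, draw_neuron_params, euler_step
from ephapsim.simulator import SimulationDivergenceError, compute_lfp


def small_cfg(**kw):
    base = dict(n_neurons=10, nb=2, rp=0.2, duration=2.0, transient=0.5, seed=3)
    base.update(kw)
    return es.SimulationConfig(**base)


class TestRunNetwork:
    def test_same_seed_bit_identical(self):
        a = es.run_network(small_cfg())
        b = es.run_network(small_cfg())
        assert np.array_equal(a.x, b.x)

    def test_factor_zero_equals_off_bit_identical(self):
        on0 = es.run_network(small_cfg(ephaptic_enabled=True, ephaptic_factor=0.0))
        off = es.run_network(small_cfg(ephaptic_enabled=False))
        assert np.array_equal(on0.x, off.x)

    def test_default_protocol_sample_count(self, default_run):
        # 60 s at 1 ms with 10 s transient -> 50 000 samples
        assert len(default_run.lfp) == 50_000
        assert default_run.lfp.t[0] == pytest.approx(10.0 + 1e-3)
        assert default_run.lfp.t[-1] == pytest.approx(60.0)

    def test_lfp_is_mean_of_traces(self):
        r = es.run_network(small_cfg(), return_traces=True)
        assert np.allclose(r.traces.mean(axis=1), r.lfp.x, atol=1e-12)

    def test_single_neuron_lfp_is_its_own_trace(self):
        cfg = es.SimulationConfig(n_neurons=1, nb=0, omega=0.0,
                                  ephaptic_enabled=False, duration=2.0,
                                  transient=0.0, seed=0)
        r = es.run_network(cfg, return_traces=True)
        assert np.array_equal(r.lfp.x, r.traces[:, 0])

    def test_matched_seed_shares_topology_and_params(self):
        on = es.run_network(small_cfg(ephaptic_enabled=True), full_result=True)
        off = es.run_network(small_cfg(ephaptic_enabled=False), full_result=True)
        assert on.graph.edges == off.graph.edges
        assert np.array_equal(on.params.a, off.params.a)
        assert np.array_equal(on.v0, off.v0)

    def test_divergence_reports_step_and_neuron(self):
        # an absurd threshold lets the quadratic field run away unchecked
        cfg = small_cfg(v_thresh=1e9)
        with pytest.raises(SimulationDivergenceError, match="step .*neuron"):
            es.run_network(cfg)

    def test_invalid_protocol_rejected(self):
        with pytest.raises(ValueError):
            es.SimulationConfig(transient=60.0, duration=60.0)
        with pytest.raises(ValueError):
            es.SimulationConfig(dt=0.0)

    def test_per_millisecond_convention_collapses_dynamics(self):
        # reading the same coefficients as mV/ms produces a 2-step spike
        # cycle: every neuron alternates reset value and overshoot
        cfg = small_cfg(unit_convention="per_millisecond", omega=0.0,
                        ephaptic_enabled=False, transient=1.0)
        r = es.run_network(cfg, return_traces=True)
        v = r.traces
        above = v >= 90.0
        assert np.all(above[:-1] != above[1:])  # strict alternation


class TestKernelMatchesReference:
    def test_long_run_agrees_with_pure_python_step(self):
        n, steps, dt = 10, 1500, 1e-3
        g = es.build_small_world(n, 4, 0.3, seed=5)
        w = es.build_ephaptic_weights(n, 1e-2)
        p = draw_neuron_params(n, 0.2, seed=7)
        rng = np.random.default_rng(3)
        v0 = rng.uniform(-5, 89, n)
        syn = SynapseParams(omega=5.0)

        state = NetworkState.initial(v0)
        ref = np.empty(steps)
        for k in range(steps):
            state = euler_step(state, p, w, g, syn, dt)
            ref[k] = state.v.mean()

        lfp = np.empty(steps)
        dummy = np.empty((1, 1))
        status, _, _, _ = _kernels.euler_loop(
            v0.copy(), p.a, p.b, p.sign, p.i_bias, w.c, w.c.sum(1),
            g.adjacency(), syn.omega, syn.tau_syn, dt, 1.0, steps,
            p.v_thresh, p.v_reset, False, lfp, dummy, False, 1e6)
        assert status == _kernels.OK
        assert np.allclose(lfp, ref, atol=1e-8)

    def test_all_spikes_kernel_matches_single_spike_before_second_spike(self):
        # until any neuron spikes twice, the full-history kernel must agree
        # with the most-recent-spike kernel (up to the exp/recursion rounding);
        # the shortest intrinsic period is ~0.46 s, so stop well before it
        cfg = small_cfg(duration=0.35, transient=0.0)
        a = es.run_network(cfg)
        b = es.run_network(es.SimulationConfig(**{**cfg.to_dict(), "all_spikes": True}))
        assert np.allclose(a.x, b.x, rtol=1e-6, atol=1e-9)


class TestSymmetries:
    def test_ring_rotation_maps_solutions_to_solutions(self):
        # rp=0 lattice is rotation invariant: rotating params and initial
        # conditions rotates the whole trajectory
        n, steps, dt, shift = 10, 1000, 1e-3, 3
        g = es.build_small_world(n, 4, 0.0, seed=0)
        w = es.build_ephaptic_weights(n, 1e-2)
        p = draw_neuron_params(n, 0.0, seed=1)
        rng = np.random.default_rng(2)
        v0 = rng.uniform(-5, 89, n)
        syn = SynapseParams(omega=5.0)

        def run(a, b, sign, v0):
            lfp = np.empty(steps)
            traces = np.empty((steps, n))
            _kernels.euler_loop(v0.copy(), a, b, sign, p.i_bias, w.c,
                                w.c.sum(1), g.adjacency(), syn.omega,
                                syn.tau_syn, dt, 1.0, steps, p.v_thresh,
                                p.v_reset, False, lfp, traces, True, 1e6)
            return traces

        base = run(p.a, p.b, p.sign, v0)
        rot = run(np.roll(p.a, shift), np.roll(p.b, shift),
                  np.roll(p.sign, shift), np.roll(v0, shift))
        assert np.allclose(rot, np.roll(base, shift, axis=1), atol=1e-9)

    def test_transient_independence_of_initial_conditions(self):
        # the tonic attractor forgets V(0): post-transient spike rates from
        # two different initial-condition draws agree within sampling error
        n, dt = 50, 1e-3
        steps, trans = 30_000, 10_000
        g = es.build_small_world(n, 4, 0.1, seed=0)
        w = es.build_ephaptic_weights(n, 1e-2)
        p = draw_neuron_params(n, 0.0, seed=1)
        syn = SynapseParams(omega=5.0)

        def spike_rate(v0):
            lfp = np.empty(steps)
            traces = np.empty((steps, n))
            _kernels.euler_loop(v0.copy(), p.a, p.b, p.sign, p.i_bias, w.c,
                                w.c.sum(1), g.adjacency(), syn.omega,
                                syn.tau_syn, dt, 1.0, steps, p.v_thresh,
                                p.v_reset, False, lfp, traces, True, 1e6)
            return float((traces[trans:] >= 90.0).sum()) / (n * (steps - trans) * dt)

        # each tonic neuron contributes a +-1 edge-effect miscount, so the
        # rate difference is bounded by n / total spikes (~4% here)
        r1 = spike_rate(np.random.default_rng(10).uniform(-5, 90, n))
        r2 = spike_rate(np.full(n, -5.0))
        assert r1 == pytest.approx(r2, rel=0.06)


class TestComputeLfp:
    def test_identical_neurons_equal_any_trace(self):
        tr = np.tile(np.sin(np.arange(100.0))[:, None], (1, 7))
        lfp = compute_lfp(tr, dt=1e-3)
        assert np.allclose(lfp.x, tr[:, 0])

    def test_antisymmetric_pair_cancels(self):
        v = np.random.default_rng(0).normal(size=200)
        lfp = compute_lfp(np.column_stack([v, -v]), dt=1e-3)
        assert np.allclose(lfp.x, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_lfp(np.empty((0, 3)), dt=1e-3)
        with pytest.raises(ValueError):
            compute_lfp(np.empty((5, 0)), dt=1e-3)


class TestLfpIO:
    def test_csv_roundtrip(self, tmp_path):
        lfp = es.run_network(small_cfg())
        path = tmp_path / "lfp.csv"
        lfp.to_csv(path)
        back = es.LFPSeries.from_csv(path)
        assert np.allclose(back.x, lfp.x)
        assert back.dt == pytest.approx(lfp.dt)
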