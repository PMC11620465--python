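"""Full-network simulation: Euler integration, transient removal, LFP.

:func:`run_network` draws a topology, heterogeneous neuron parameters and
initial conditions from a single seed, integrates the coupled QIF-E system
with explicit Euler, discards the transient, and returns the local field
potential (LFP) — here the spatial average of all membrane potentials,
``x(t) = (1/N) sum_i V_i(t)``.

The default protocol is 60 s of simulated time at dt = 1 ms with the first
10 s discarded, yielding a 50 000-sample LFP.  Potentials enter the LFP
before reset substitution on spike steps (the reset acts on the following
step), so spikes appear as single-sample excursions above threshold.

Matched-seed discipline: the topology and parameter draws depend only on
``seed``, never on the ephaptic regime, so an ephaptic-on and an
ephaptic-off run at the same seed share their synaptic graph, neuron
parameters and initial conditions exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

from . import _kernels
from .dynamics import (I_BIAS, TAU_SYN, V_RESET, V_THRESH, NeuronParams,
                       draw_neuron_params)
from .topology import (DEFAULT_EPHAPTIC_FACTOR, SynapticGraph,
                       EphapticWeightMatrix, build_ephaptic_weights,
                       build_small_world)

__all__ = ["SimulationConfig", "LFPSeries", "SimulationResult",
           "SimulationDivergenceError", "run_network", "compute_lfp"]

#: Explicit Euler of a quadratic field can blow up; abort past this |V|.
DIVERGENCE_GUARD = 1e6


class SimulationDivergenceError(RuntimeError):
    """Non-finite or runaway state during integration."""


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one network realisation.

    Defaults reproduce the reference protocol: N=100 neurons, nb=4 first
    neighbours, rewiring probability 0.1, synaptic intensity omega=5,
    ephaptic factor 1e-2, 60 s at dt=1e-3 s with a 10 s transient.
    """

    n_neurons: int = 100
    nb: int = 4
    rp: float = 0.1
    omega: float = 5.0
    ephaptic_enabled: bool = True
    ephaptic_factor: float = DEFAULT_EPHAPTIC_FACTOR
    inhib_fraction: float = 0.0
    dt: float = 1e-3
    duration: float = 60.0
    transient: float = 10.0
    seed: int = 0
    tau_syn: float = TAU_SYN
    i_bias: float = I_BIAS
    v_thresh: float = V_THRESH
    v_reset: float = V_RESET
    all_spikes: bool = False
    unit_convention: str = "per_second"  # or "per_millisecond"

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if not (0.0 <= self.transient < self.duration):
            raise ValueError(
                f"need 0 <= transient < duration, got {self.transient}, {self.duration}")
        if self.unit_convention not in ("per_second", "per_millisecond"):
            raise ValueError(f"unknown unit convention {self.unit_convention!r}")

    @property
    def n_steps(self) -> int:
        return round(self.duration / self.dt)

    @property
    def n_transient_steps(self) -> int:
        return round(self.transient / self.dt)

    @property
    def time_factor(self) -> float:
        return 1000.0 if self.unit_convention == "per_millisecond" else 1.0

    def to_dict(self) -> dict:
        return asdict(self)

    def with_regime(self, ephaptic_enabled: bool) -> "SimulationConfig":
        return replace(self, ephaptic_enabled=ephaptic_enabled)


@dataclass
class LFPSeries:
    """Post-transient LFP samples ``x`` (mV) at times ``t`` (s), step ``dt``."""

    t: np.ndarray
    x: np.ndarray
    dt: float

    def __len__(self) -> int:
        return self.x.shape[0]

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.t, self.x])
        np.savetxt(path, arr, delimiter=",", header="time_s,lfp_mV", comments="")

    @classmethod
    def from_csv(cls, path) -> "LFPSeries":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        t, x = arr[:, 0], arr[:, 1]
        dt = float(t[1] - t[0]) if len(t) > 1 else float("nan")
        return cls(t=t, x=x, dt=dt)


@dataclass
class SimulationResult:
    """LFP plus provenance of one run; traces only when requested."""

    lfp: LFPSeries
    config: SimulationConfig
    graph: SynapticGraph
    weights: EphapticWeightMatrix
    params: NeuronParams
    n_spikes: int
    v0: np.ndarray = field(repr=False)
    traces: np.ndarray | None = field(default=None, repr=False)


def _derive_rngs(seed: int):
    """Three independent streams (topology, parameters, initial V) from one seed."""
    ss = np.random.SeedSequence(seed)
    g, p, v = ss.spawn(3)
    graph_seed = int(g.generate_state(1)[0] % np.int64(2**31))
    return graph_seed, np.random.default_rng(p), np.random.default_rng(v)


def run_network(config: SimulationConfig, return_traces: bool = False,
                full_result: bool = False):
    """Simulate one network realisation and return its LFP.

    With ``return_traces`` (or ``full_result``) a :class:`SimulationResult`
    is returned carrying the drawn topology, parameters, spike count and —
    if requested — the full post-transient per-neuron trace matrix
    ``(n_samples, n_neurons)``.  Identical configs give bit-identical output;
    ``ephaptic_enabled=False`` and ``ephaptic_factor=0`` are the same regime.
    """
    graph_seed, rng_par, rng_v0 = _derive_rngs(config.seed)
    if config.nb == 0 or config.n_neurons == 1:
        # synapse-free network (single neuron or nb=0): empty edge set
        graph = SynapticGraph(n_neurons=config.n_neurons, nb=0, rp=config.rp,
                              seed=graph_seed, edges=frozenset())
    else:
        graph = build_small_world(config.n_neurons, config.nb, config.rp, graph_seed)
    if config.n_neurons == 1:
        weights = EphapticWeightMatrix(n_neurons=1, factor=0.0, enabled=False,
                                       c=np.zeros((1, 1)))
    else:
        weights = build_ephaptic_weights(
            config.n_neurons,
            factor=config.ephaptic_factor if config.ephaptic_enabled else 0.0,
            enabled=config.ephaptic_enabled)
    params = draw_neuron_params(config.n_neurons, config.inhib_fraction, rng_par)
    params = replace(params, i_bias=config.i_bias, v_thresh=config.v_thresh,
                     v_reset=config.v_reset)
    v0 = rng_v0.uniform(config.v_reset, config.v_thresh, config.n_neurons)

    n_steps = config.n_steps
    lfp_full = np.empty(n_steps)
    store = bool(return_traces)
    traces_full = np.empty((n_steps, config.n_neurons)) if store else np.empty((1, 1))

    status, step, neuron, n_spikes = _kernels.euler_loop(
        v0.copy(), params.a, params.b, params.sign, params.i_bias,
        weights.c, weights.c.sum(axis=1), graph.adjacency(),
        config.omega, config.tau_syn, config.dt, config.time_factor,
        n_steps, config.v_thresh, config.v_reset, config.all_spikes,
        lfp_full, traces_full, store, DIVERGENCE_GUARD)
    if status != _kernels.OK:
        raise SimulationDivergenceError(
            f"|V| exceeded {DIVERGENCE_GUARD:g} at step {step} "
            f"(t = {step * config.dt:.4f} s), neuron {neuron}")

    k0 = config.n_transient_steps
    t = (np.arange(k0, n_steps) + 1) * config.dt
    lfp = LFPSeries(t=t, x=lfp_full[k0:], dt=config.dt)
    if not (return_traces or full_result):
        return lfp
    return SimulationResult(lfp=lfp, config=config, graph=graph, weights=weights,
                            params=params, n_spikes=int(n_spikes), v0=v0,
                            traces=traces_full[k0:] if store else None)


def compute_lfp(traces: np.ndarray, dt: float, t_start: float = 0.0) -> LFPSeries:
    """Spatial average of per-neuron traces: ``x(t) = mean_i V_i(t)``.

    ``traces`` has shape (n_samples, n_neurons) with at least one neuron.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[1] < 1 or traces.shape[0] < 1:
        raise ValueError(f"need a non-empty (n_samples, n_neurons) array, got {traces.shape}")
    x = traces.mean(axis=1)
    t = t_start + (np.arange(traces.shape[0]) + 1) * dt
    return LFPSeries(t=t, x=x, dt=dt)
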