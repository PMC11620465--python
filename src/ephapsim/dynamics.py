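"""Single-step QIF-E membrane dynamics: currents, derivative, reset.

The membrane potential of neuron ``i`` evolves as

    dV_i/dt = a_i V_i^2 + b_i V_i + e_i(t) + s_i(t) + I

with the ephaptic drive ``e_i = -sum_{j != i} c[i, j] (V_i - V_j)``, the
current-based (CUBA) synaptic drive ``s_i`` as an exponentially decaying
kernel triggered by presynaptic spikes, and a constant bias ``I``.  A neuron
spikes when ``V >= v_thresh`` (90 mV); on the following step its potential is
substituted by ``v_reset`` (-5 mV), a hyperpolarisation reset standing in for
the action-potential downstroke.

The quadratic coefficients are heterogeneous across the population,
``a ~ U(25 +/- 5%)`` and ``b ~ U(30 +/- 5%)``, mimicking biological
variability between neurons.  At the default bias ``I = 9.5`` the
discriminant ``b^2 - 4 a I`` is negative, so every uncoupled neuron fires
tonically; the resulting intrinsic period has the closed form implemented in
:func:`uncoupled_period` (about 0.88 s at the parameter centres, i.e. a
~1.1 Hz pacemaker).

Everything here is a transparent NumPy reference implementation operating on
one :class:`NetworkState`; the production integration loop lives in
``ephapsim._kernels`` and is checked against these functions in the tests.

Units: potentials in mV, time in seconds, derivative in mV/s.  A
``per_millisecond`` convention (same printed numbers read as mV/ms) is
available through the simulator for comparison, but collapses the dynamics
to a trivial two-step spike cycle at the default step size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "A_CENTER", "A_HALFWIDTH", "B_CENTER", "B_HALFWIDTH", "I_BIAS",
    "V_THRESH", "V_RESET", "TAU_SYN",
    "NeuronParams", "SynapseParams", "NetworkState",
    "draw_neuron_params", "ephaptic_coupling_current", "synaptic_current",
    "qife_derivative", "apply_reset", "euler_step", "uncoupled_period",
]

A_CENTER = 25.0
A_HALFWIDTH = 1.25
B_CENTER = 30.0
B_HALFWIDTH = 1.5
I_BIAS = 9.5
V_THRESH = 90.0
V_RESET = -5.0
TAU_SYN = 0.006  # s

#: Sentinel for "has never spiked": exp(-(t - NEVER)/tau) underflows to 0.
NEVER_SPIKED = -np.inf


@dataclass
class NeuronParams:
    """Per-neuron membrane parameters.

    ``a`` and ``b`` are arrays of quadratic/linear coefficients, ``sign`` is
    +1 for excitatory and -1 for inhibitory neurons (it flips the sign of the
    neuron's outgoing synaptic kernel, not its membrane dynamics).
    """

    a: np.ndarray
    b: np.ndarray
    sign: np.ndarray
    i_bias: float = I_BIAS
    v_thresh: float = V_THRESH
    v_reset: float = V_RESET

    @property
    def n_neurons(self) -> int:
        return self.a.shape[0]


@dataclass
class SynapseParams:
    """CUBA synapse: intensity magnitude ``omega`` and decay constant ``tau_syn`` (s).

    ``all_spikes=False`` (default) evaluates the kernel from each neuron's
    most recent spike only; ``True`` sums the kernel over the full spike
    history.
    """

    omega: float = 5.0
    tau_syn: float = TAU_SYN
    all_spikes: bool = False

    def __post_init__(self):
        if self.omega < 0:
            raise ValueError(f"omega is a magnitude, must be >= 0; got {self.omega}")
        if self.tau_syn <= 0:
            raise ValueError(f"tau_syn must be > 0; got {self.tau_syn}")


@dataclass
class NetworkState:
    """Snapshot of the network at time ``t``: potentials, spike bookkeeping."""

    t: float
    v: np.ndarray
    last_spike: np.ndarray
    spiked_prev: np.ndarray

    @classmethod
    def initial(cls, v0: np.ndarray) -> "NetworkState":
        n = v0.shape[0]
        return cls(t=0.0, v=np.asarray(v0, dtype=float).copy(),
                   last_spike=np.full(n, NEVER_SPIKED),
                   spiked_prev=np.zeros(n, dtype=bool))


def draw_neuron_params(n_neurons: int, inhib_fraction: float = 0.0,
                       seed: int | np.random.Generator = 0) -> NeuronParams:
    """Draw heterogeneous membrane parameters for a population.

    ``a_i ~ U(23.75, 26.25)`` and ``b_i ~ U(28.5, 31.5)`` independently per
    neuron.  Exactly ``round(n_neurons * inhib_fraction)`` neurons are marked
    inhibitory (sign -1), chosen uniformly without replacement.
    """
    if not (0.0 <= inhib_fraction < 1.0):
        raise ValueError(f"inhib_fraction must be in [0, 1), got {inhib_fraction}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = rng.uniform(A_CENTER - A_HALFWIDTH, A_CENTER + A_HALFWIDTH, n_neurons)
    b = rng.uniform(B_CENTER - B_HALFWIDTH, B_CENTER + B_HALFWIDTH, n_neurons)
    sign = np.ones(n_neurons)
    n_inhib = round(n_neurons * inhib_fraction)
    if n_inhib:
        sign[rng.choice(n_neurons, size=n_inhib, replace=False)] = -1.0
    return NeuronParams(a=a, b=b, sign=sign)


def ephaptic_coupling_current(v: np.ndarray, weights) -> np.ndarray:
    """Field drive ``e_i = -sum_{j != i} c[i, j] (v_i - v_j)``.

    ``weights`` is an :class:`~ephapsim.topology.EphapticWeightMatrix` or a
    plain square array.  For a symmetric matrix the pairwise contributions
    are antisymmetric, so the drive sums to zero over the population.
    """
    c = getattr(weights, "c", weights)
    v = np.asarray(v, dtype=float)
    if c.shape != (v.shape[0], v.shape[0]):
        raise ValueError(f"weight matrix {c.shape} does not match {v.shape[0]} neurons")
    return c @ v - c.sum(axis=1) * v


def synaptic_current(t: float, state: NetworkState, graph, syn: SynapseParams,
                     sign: np.ndarray) -> np.ndarray:
    """CUBA drive ``s_i = sum_{k adj i} sign_k * omega * exp(-(t - t0_k)/tau)``.

    Only neighbours that have spiked contribute (the never-spiked sentinel
    makes the kernel vanish).  With the default single-spike kernel ``t0_k``
    is the most recent spike of neuron ``k``.
    """
    adj = graph.adjacency() if hasattr(graph, "adjacency") else np.asarray(graph)
    with np.errstate(over="ignore"):
        emit = sign * syn.omega * np.exp(-(t - state.last_spike) / syn.tau_syn)
    emit = np.where(np.isfinite(state.last_spike), emit, 0.0)
    return adj @ emit


def qife_derivative(state: NetworkState, params: NeuronParams,
                    eph: np.ndarray, syn: np.ndarray) -> np.ndarray:
    """Membrane derivative ``a V^2 + b V + eph + syn + I`` (mV/s)."""
    v = state.v
    return params.a * v * v + params.b * v + eph + syn + params.i_bias


def apply_reset(state: NetworkState, params: NeuronParams) -> NetworkState:
    """Register threshold crossings at the end of a step.

    Neurons with ``v >= v_thresh`` have their spike time recorded as the
    current state time and are flagged so that the *next* Euler step
    substitutes ``v_reset`` for their potential (the reset acts at t+1).
    """
    spiked = state.v >= params.v_thresh
    last = np.where(spiked, state.t, state.last_spike)
    return replace(state, last_spike=last, spiked_prev=spiked)


def euler_step(state: NetworkState, params: NeuronParams, weights, graph,
               syn: SynapseParams, dt: float, time_factor: float = 1.0) -> NetworkState:
    """One explicit Euler step of the full network equation.

    Drives are evaluated at the current state; neurons flagged by the
    previous step's threshold crossing are reset instead of integrated.
    ``time_factor`` rescales the derivative for the alternative
    per-millisecond unit reading (1.0 = mV/s).
    """
    eph = ephaptic_coupling_current(state.v, weights)
    s = synaptic_current(state.t, state, graph, syn, params.sign)
    dv = qife_derivative(state, params, eph, s)
    v_new = np.where(state.spiked_prev, params.v_reset, state.v + dt * time_factor * dv)
    new = NetworkState(t=state.t + dt, v=v_new, last_spike=state.last_spike.copy(),
                       spiked_prev=state.spiked_prev.copy())
    return apply_reset(new, params)


def uncoupled_period(a: float = A_CENTER, b: float = B_CENTER, i_bias: float = I_BIAS,
                     v_reset: float = V_RESET, v_thresh: float = V_THRESH) -> float:
    """Closed-form inter-spike interval of an isolated tonic QIF neuron.

    Integrates ``dV / (a V^2 + b V + I)`` from ``v_reset`` to ``v_thresh``:

        T = (1/sqrt(aB)) * [arctan(sqrt(a/B) (V + b/2a))]_{v_reset}^{v_thresh},
        B = I - b^2/(4a)

    valid in the tonic regime ``b^2 - 4 a I < 0`` (B > 0).
    """
    B = i_bias - b * b / (4.0 * a)
    if B <= 0:
        raise ValueError("not in the tonic regime: b^2 - 4aI >= 0")
    s = np.sqrt(a / B)
    hi = np.arctan(s * (v_thresh + b / (2 * a)))
    lo = np.arctan(s * (v_reset + b / (2 * a)))
    return float((hi - lo) / np.sqrt(a * B))
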