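"""Numba-jitted inner loops for the Euler integration and sample entropy.

These kernels are the performance path; their semantics are pinned to the
NumPy reference implementations in :mod:`ephapsim.dynamics` and the naive
pair-enumeration entropy used in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the Euler kernel
OK = 0
DIVERGED = 1


@njit(cache=True)
def euler_loop(v, a, b, sign, i_bias, c, c_rowsum, adj, omega, tau_syn,
               dt, time_factor, n_steps, v_thresh, v_reset, all_spikes,
               lfp_out, traces_out, store_traces, guard):
    """Forward-Euler integration of the coupled QIF-E network.

    State update per step (drives evaluated at the current state):
      v <- v + dt*tf*(a v^2 + b v + eph + syn + I), except neurons that
      crossed threshold on the previous step, which are substituted with
      ``v_reset``.  Crossings at the end of a step record the spike time.

    Writes the population-mean potential of every step into ``lfp_out`` and,
    if ``store_traces``, the full per-neuron matrix into ``traces_out``.
    Returns (status, step, neuron, n_spikes); status != OK signals a
    |V| > guard divergence at the reported step/neuron.
    """
    n = v.shape[0]
    last_spike = np.full(n, -np.inf)
    spiked = np.zeros(n, np.bool_)
    acc = np.zeros(n)  # running kernel sum for the all-spikes variant
    decay = np.exp(-dt / tau_syn)
    n_spikes = 0
    dt_eff = dt * time_factor

    for k in range(n_steps):
        t = k * dt
        # per-neuron synaptic emission at time t
        emit = np.zeros(n)
        if all_spikes:
            for m in range(n):
                emit[m] = sign[m] * omega * acc[m]
        else:
            for m in range(n):
                if last_spike[m] > -np.inf:
                    emit[m] = sign[m] * omega * np.exp(-(t - last_spike[m]) / tau_syn)
        syn = adj @ emit
        eph = c @ v - c_rowsum * v

        mean_v = 0.0
        t_new = t + dt
        for m in range(n):
            if spiked[m]:
                v[m] = v_reset
            else:
                dv = a[m] * v[m] * v[m] + b[m] * v[m] + eph[m] + syn[m] + i_bias
                v[m] = v[m] + dt_eff * dv
            if np.abs(v[m]) > guard or np.isnan(v[m]):
                return DIVERGED, k, m, n_spikes
            mean_v += v[m]

        for m in range(n):
            crossed = v[m] >= v_thresh
            spiked[m] = crossed
            if crossed:
                last_spike[m] = t_new
                n_spikes += 1
        if all_spikes:
            for m in range(n):
                acc[m] = acc[m] * decay
                if spiked[m]:
                    acc[m] += 1.0

        lfp_out[k] = mean_v / n
        if store_traces:
            for m in range(n):
                traces_out[k, m] = v[m]

    return OK, n_steps, -1, n_spikes


@njit(cache=True)
def sampen_counts_chebyshev(x, m, r):
    """Template-match pair counts for sample entropy, Chebyshev distance.

    Uses the ``n - m`` templates common to both lengths; self-matches
    excluded; match iff max coordinate difference <= r.  Returns (A, B):
    matched pairs at length m+1 and m.
    """
    n = x.shape[0]
    nt = n - m
    A = 0
    B = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            match = True
            for k in range(m):
                if np.abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                B += 1
                if np.abs(x[i + m] - x[j + m]) <= r:
                    A += 1
    return A, B


@njit(cache=True)
def sampen_counts_euclidean(x, m, r):
    """Template-match pair counts with true Euclidean template distance."""
    n = x.shape[0]
    nt = n - m
    A = 0
    B = 0
    r2 = r * r
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            s = 0.0
            for k in range(m):
                d = x[i + k] - x[j + k]
                s += d * d
                if s > r2:
                    break
            if s <= r2:
                B += 1
                d = x[i + m] - x[j + m]
                if s + d * d <= r2:
                    A += 1
    return A, B
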