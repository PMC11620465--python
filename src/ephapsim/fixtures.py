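"""Validation signals and a hand-checkable miniature network.

Seed-deterministic generators for the signal classes used to validate the
entropy pipeline — Gaussian white noise, 1/f ("pink") noise, periodic and
constant series — plus a four-neuron homogeneous ring small enough for
step-by-step Euler arithmetic by hand.
"""

from __future__ import annotations

import numpy as np

from .dynamics import NeuronParams, draw_neuron_params  # noqa: F401  (re-export convenience)
from .topology import (EphapticWeightMatrix, SynapticGraph,
                       build_ephaptic_weights, build_small_world)

__all__ = ["gen_white_noise", "gen_pink_noise", "gen_periodic", "gen_constant",
           "gen_signal", "tiny_network_fixture"]


def gen_white_noise(length: int, sd: float = 1.0, seed: int = 0) -> np.ndarray:
    """iid Gaussian samples, mean 0 and standard deviation ``sd``."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, sd, length)


def gen_pink_noise(length: int, seed: int = 0) -> np.ndarray:
    """Gaussian noise with a 1/f power spectrum, normalised to unit SD.

    Built by spectral shaping: a flat-phase-random Fourier spectrum whose
    amplitude falls as f^(-1/2) (power as 1/f), inverted to the time domain.
    The DC component is zero.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(length)
    spec = np.zeros(len(freqs), dtype=complex)
    amp = np.zeros(len(freqs))
    amp[1:] = freqs[1:] ** -0.5
    phases = rng.uniform(0, 2 * np.pi, len(freqs))
    mags = rng.normal(0, 1, len(freqs))
    spec[1:] = amp[1:] * np.abs(mags[1:]) * np.exp(1j * phases[1:])
    x = np.fft.irfft(spec, n=length)
    return x / x.std()


def gen_periodic(length: int, period: int = 20, amplitude: float = 1.0) -> np.ndarray:
    """Sinusoid of the given integer period, sampled once per step."""
    if length < 1 or period < 2:
        raise ValueError("need length >= 1 and period >= 2")
    return amplitude * np.sin(2 * np.pi * np.arange(length) / period)


def gen_constant(length: int, value: float = 0.0) -> np.ndarray:
    return np.full(length, float(value))


def gen_signal(kind: str, length: int, amplitude: float = 1.0, seed: int = 0,
               period: int = 20) -> np.ndarray:
    """Dispatch by kind: 'white', 'pink', 'periodic' or 'constant'."""
    if kind == "white":
        return gen_white_noise(length, sd=amplitude, seed=seed)
    if kind == "pink":
        return amplitude * gen_pink_noise(length, seed=seed)
    if kind == "periodic":
        return gen_periodic(length, period=period, amplitude=amplitude)
    if kind == "constant":
        return gen_constant(length, amplitude)
    raise ValueError(f"unknown signal kind {kind!r}")


def tiny_network_fixture() -> tuple[SynapticGraph, EphapticWeightMatrix, NeuronParams]:
    """Four-neuron homogeneous ring for hand-checked Euler traces.

    N=4 ring with nb=2, homogeneous a=25, b=30, I=9.5, all excitatory,
    ephaptic factor 1e-2.  Every quantity in a step of this network can be
    verified with scalar arithmetic.
    """
    graph = build_small_world(4, 2, 0.0, seed=0)
    weights = build_ephaptic_weights(4, factor=1e-2, enabled=True)
    params = NeuronParams(a=np.full(4, 25.0), b=np.full(4, 30.0), sign=np.ones(4))
    return graph, weights, params
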