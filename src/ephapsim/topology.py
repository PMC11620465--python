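"""Network structure: small-world synaptic graphs and ephaptic weight matrices.

Two coupling layers coexist in the model.  Chemical synapses live on a
Watts-Strogatz small-world graph: a ring lattice in which every neuron is
wired to its ``nb`` nearest neighbours and each lattice edge is rewired with
probability ``rp``.  Ephaptic (electric-field) coupling is all-to-all, with a
weight for each neuron pair that falls off as the inverse of their distance
along the ring, ``c[i, j] = factor / ring_distance(i, j)``.

Neurons are treated as evenly spaced on a ring, so the relevant distance is
the minimum arc length between two indices.  The physiological constants of
the field model (membrane capacitance and resistance, extracellular
resistance) are absorbed into the single scalar ``factor``; the default
``1e-2`` corresponds to an inter-neuron spacing of ~50 um.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "TopologyError",
    "SynapticGraph",
    "EphapticWeightMatrix",
    "ring_distance",
    "build_small_world",
    "build_ephaptic_weights",
    "DEFAULT_EPHAPTIC_FACTOR",
    "TABLE_EPHAPTIC_FACTOR",
]

#: Default numerator of the inverse-distance ephaptic weight law (1/s).
DEFAULT_EPHAPTIC_FACTOR = 1e-2

#: Alternative weight law written as 5e-2 / (d * |i-k|) with d = 50 um.
#: Collapses to a plain inverse-distance factor of 1e-3.
TABLE_EPHAPTIC_FACTOR = 5e-2 / 50.0


class TopologyError(ValueError):
    """Raised for inconsistent network-construction arguments."""


def ring_distance(i, j, n_neurons: int):
    """Minimum arc distance between neuron indices on a ring of ``n_neurons``.

    Accepts scalars or arrays; returns ``min(|i - j|, n - |i - j|)``, which is
    0 iff ``i == j``.
    """
    i = np.asarray(i)
    j = np.asarray(j)
    if np.any(i < 0) or np.any(j < 0) or np.any(i >= n_neurons) or np.any(j >= n_neurons):
        raise TopologyError(
            f"neuron indices must lie in [0, {n_neurons}); got i={i}, j={j}"
        )
    d = np.abs(i - j)
    out = np.minimum(d, n_neurons - d)
    if out.ndim == 0:
        return int(out)
    return out


@dataclass(frozen=True)
class SynapticGraph:
    """Undirected synaptic connectivity of the small-world layer.

    ``edges`` holds unordered 0-based index pairs stored as sorted tuples.
    Synapses act bidirectionally: a spike of either endpoint drives the other.
    """

    n_neurons: int
    nb: int
    rp: float
    seed: int
    edges: frozenset = field(repr=False)

    def adjacency(self, dtype=np.float64) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix."""
        a = np.zeros((self.n_neurons, self.n_neurons), dtype=dtype)
        for i, j in self.edges:
            a[i, j] = 1
            a[j, i] = 1
        return a

    def degrees(self) -> np.ndarray:
        return self.adjacency().sum(axis=1).astype(int)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_edgelist(self, path) -> None:
        """Write edges as two whitespace-separated integer columns."""
        arr = np.array(sorted(self.edges), dtype=int).reshape(-1, 2)
        np.savetxt(path, arr, fmt="%d")

    @classmethod
    def from_edgelist(cls, path, n_neurons: int, nb: int = -1, rp: float = float("nan"),
                      seed: int = -1) -> "SynapticGraph":
        """Read a two-column edge list; metadata fields are optional."""
        arr = np.loadtxt(path, dtype=int, ndmin=2)
        edges = frozenset(tuple(sorted((int(i), int(j)))) for i, j in arr)
        return cls(n_neurons=n_neurons, nb=nb, rp=rp, seed=seed, edges=edges)


def build_small_world(n_neurons: int, nb: int, rp: float, seed: int) -> SynapticGraph:
    """Watts-Strogatz small-world graph over ``n_neurons`` neurons.

    Starts from a ring lattice where every neuron connects to its ``nb``
    nearest neighbours (``nb/2`` on each side) and rewires each lattice edge
    independently with probability ``rp`` to a uniformly chosen target,
    avoiding self-loops and duplicates, so the edge count ``n_neurons*nb/2``
    is conserved for every ``rp``.  ``rp=0`` returns the exact ring lattice;
    ``rp=1`` an essentially random graph.  Deterministic given ``seed``.
    """
    if nb % 2 != 0:
        raise TopologyError(f"nb must be even, got {nb}")
    if not (2 <= nb < n_neurons):
        raise TopologyError(f"need 2 <= nb < n_neurons, got nb={nb}, N={n_neurons}")
    if not (0.0 <= rp <= 1.0):
        raise TopologyError(f"rewiring probability must be in [0, 1], got {rp}")
    g = nx.watts_strogatz_graph(n_neurons, nb, rp, seed=int(seed))
    edges = frozenset(tuple(sorted(e)) for e in g.edges())
    return SynapticGraph(n_neurons=n_neurons, nb=nb, rp=float(rp), seed=int(seed),
                         edges=edges)


@dataclass(frozen=True)
class EphapticWeightMatrix:
    """Symmetric all-to-all ephaptic coupling constants (units 1/s).

    ``c[i, j] = factor / ring_distance(i, j)`` off the diagonal; the diagonal
    is zero.  An all-zero matrix represents the ephaptic-off regime.  ``d``
    is the physical reference spacing in micrometres and is metadata only.
    """

    n_neurons: int
    factor: float
    enabled: bool
    c: np.ndarray = field(repr=False)
    d: float = 50.0

    def to_text(self, path) -> None:
        np.savetxt(path, self.c)


def build_ephaptic_weights(n_neurons: int, factor: float = DEFAULT_EPHAPTIC_FACTOR,
                           enabled: bool = True, d: float = 50.0) -> EphapticWeightMatrix:
    """Inverse-ring-distance coupling matrix; all zeros when ``enabled`` is False."""
    if n_neurons < 2:
        raise TopologyError(f"need at least 2 neurons, got {n_neurons}")
    if factor < 0:
        raise TopologyError(f"ephaptic factor must be >= 0, got {factor}")
    idx = np.arange(n_neurons)
    diff = np.abs(idx[:, None] - idx[None, :])
    dist = np.minimum(diff, n_neurons - diff).astype(float)
    if enabled:
        with np.errstate(divide="ignore"):
            c = np.where(dist > 0, factor / np.where(dist > 0, dist, 1.0), 0.0)
    else:
        c = np.zeros((n_neurons, n_neurons))
    return EphapticWeightMatrix(n_neurons=n_neurons, factor=float(factor),
                                enabled=bool(enabled), c=c, d=float(d))
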