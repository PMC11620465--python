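# Methods

## Model

`ephapsim` simulates a population of N quadratic integrate-and-fire neurons
coupled through two distinct layers and asks how each layer shapes the
complexity of the population signal.

Each neuron's membrane potential (mV) obeys

    dV_i/dt = a_i V_i^2 + b_i V_i + e_i(t) + s_i(t) + I

with a hard spike rule: when `V_i >= 90` mV at the end of an Euler step, the
spike time is recorded and on the *following* step the potential is
substituted by the hyperpolarisation value −5 mV. The quadratic nonlinearity
stands in for the spike upstroke; no axonal propagation, conductances or
spatial compartments are modelled, and neurons are treated as point somata
evenly spaced on a ring.

**Ephaptic layer.** Electric-field interactions are all-to-all and
diffusive: `e_i = −Σ_{j≠i} c[i,j] (V_i − V_j)` with
`c[i,j] = factor / d_ring(i,j)`, where `d_ring` is the minimum arc distance
between ring indices. The membrane/extracellular circuit constants are
absorbed into the single `factor` (default `1e-2` s⁻¹ at a reference
spacing of 50 μm; an alternative reading of the same circuit algebra,
`5e-2/50 = 1e-3`, is available as `TABLE_EPHAPTIC_FACTOR`). Because the
matrix is symmetric the ephaptic drive conserves the population total
exactly: `Σ_i e_i = 0`. The "ephaptic-off" regime is the all-zero matrix;
`factor = 0` is bit-identical to it.

**Synaptic layer.** Chemical synapses live on a Watts–Strogatz small-world
graph: ring lattice with `nb` nearest neighbours per neuron, each lattice
edge rewired with probability `rp` (edge count `N·nb/2` is conserved for
every `rp`). Synapses are current-based (CUBA) and bidirectional: a spike
of neuron k at t₀ injects `sign_k · ω · exp(−(t−t₀)/T)` into each
neighbour, with decay constant T = 6 ms and `sign = −1` for the optional
inhibitory subpopulation (a fraction, default 0, marked at random). By
default the kernel is evaluated from each neuron's most recent spike only —
the kernel carries a single spike time per presynaptic neuron; with T = 6 ms
three orders of magnitude below the firing period, a full spike-history sum
(`all_spikes=True`) is numerically indistinguishable, and a test pins the
two variants against each other.

**Heterogeneity.** `a_i ~ U(25 ± 5%)`, `b_i ~ U(30 ± 5%)`, independent per
neuron. At the centres the discriminant `b² − 4aI = 900 − 950` is negative,
so the typical neuron is an intrinsic pacemaker with period

    T_isi = ∫_{−5}^{90} dV/(aV² + bV + I) ≈ 0.88 s  (≈1.1 Hz),

implemented in closed form (`uncoupled_period`) and cross-checked against
numerical quadrature and against the Euler simulation (within 2% at
dt = 1e-4 s). Note the printed heterogeneity intervals are wide enough that
a minority of draws (large b, small a) are excitable rather than tonic;
they fire only when driven by their neighbours.

**Units.** Time is in seconds and the derivative in mV/s; this is the only
reading under which the printed coefficients produce structured dynamics.
The alternative (`unit_convention="per_millisecond"`, same numbers read as
mV/ms) collapses every neuron into a trivial two-step reset/overshoot cycle
at dt = 1 ms — a test asserts exactly that — and is kept only to document
the choice.

## Simulation protocol

Explicit forward Euler, all drives evaluated at the current state, no
sub-stepping. Defaults: dt = 1 ms, 60 s of simulated time, first 10 s
discarded as transient, giving a 50 000-sample LFP defined as the spatial
average `x(t) = (1/N) Σ_i V_i(t)`. Samples enter the LFP before reset
substitution, so each spike appears as a single over-threshold excursion.
Initial potentials are drawn `U(−5, 90)` per neuron (the tonic attractor
makes post-transient statistics insensitive to this; a test compares spike
rates from disparate initial-condition draws). A divergence guard aborts
with step and neuron index if `|V| > 1e6`, since explicit Euler of a
quadratic field can run away for pathological configurations.

One seed drives three independent streams (topology, parameter draws,
initial conditions) via `SeedSequence.spawn`, and none of them depends on
the ephaptic regime — so an on/off pair at the same seed shares its graph,
parameters and initial state exactly (matched-seed discipline; enforced by
test).

## Complexity analysis

Sample entropy uses the standard conventions: Chebyshev template distance
(max coordinate difference; the package also exposes a true Euclidean
option), self-matches excluded, the `n − m` templates common to lengths m
and m+1 used for both counts, match iff distance ≤ r. `S_E = −ln(A/B)`;
zero counts flag the scale as missing rather than producing infinities.

Multiscale entropy coarse-grains by non-overlapping block averages at
scales τ = 2..100 and holds `r = 0.15 · SD` fixed from the unscaled series
(so the curve is invariant under positive rescaling of the signal). Scales
whose coarse series is shorter than 10·(m+1) samples are flagged missing.
The complexity score K is the trapezoidal integral of the curve over τ,
taken piecewise over maximal runs of finite scales; a constant signal gives
K = 0, and a flat unit-entropy curve over τ = 2..100 gives K = 98.

The optimized (numba) entropy kernel is pinned bit-for-bit against a naive
O(n²) pair-enumeration reference on random series, and against the iid
closed form `−ln(2Φ(0.15/√2) − 1) ≈ 2.47` for Gaussian white noise
(within 3% at M = 1e5).

## Experiments and statistics

A condition = full configuration minus seed; running it scores
`n_seeds` realisations (seeds `seed_base + i`) with K each. Regime
contrasts use the two-sided Wilcoxon rank-sum test (exact null for combined
n ≤ 20 without ties, normal approximation with tie correction otherwise)
with the usual star labels. `n_seeds` defaults to 20 for shipped grids; the
number of realisations behind the published-style comparisons is not fixed
by the protocol, so it is a package choice. Sweeps write a long-format
(condition, seed, K) table that doubles as a resumable run ledger keyed on
a hash of the physics parameters plus the seed.

Desk-scale test protocol (the package's own choice for the automated
suite): 30 s simulated / 10 s transient (20 000-sample LFPs), 10 matched
seeds for the synaptic-intensity comparisons and 8 for the network-size and
neighbourhood trends, with the nb = 4 vs 12 contrast run at N = 200.

## Validation signals

The `fixtures` module generates the signals the entropy pipeline is
validated on: seeded Gaussian white noise (known SD, known iid entropy),
1/f pink noise by spectral shaping (periodogram slope −1 ± 0.2 over two
decades; its MSE stays above white noise at large scales — the canonical
multiscale contrast), sinusoids, constants, and a four-neuron homogeneous
ring whose Euler steps are checked against hand-unrolled scalar arithmetic.
These signals exercise the estimator's contracts; they do not emulate the
spectral content of real neural recordings, so passing them validates the
statistics, not any claim about empirical LFP/EEG data.

## Sensitivity to the ephaptic coupling constant

The regime contrasts depend strongly — and non-monotonically — on the
ephaptic factor. At the default `1e-2` the on/off difference in K at
ω = 5 is of order 1% and statistically indistinguishable over 10 matched
seeds, although the characteristic MSE-curve signature (on above off at
short scales, slightly below at intermediate scales) is already present. At
~10–50× that coupling the phenomenology is pronounced: ≈ +4% at factor
0.1, ≈ +11% at 0.5 together with a clear ordering reversal at ω = 30
(≈ −18%), and at factor 1.0 over-synchronisation collapses complexity in
both senses. Within each regime, K reliably falls with synaptic intensity
(ω = 5 → 30), rises with network size (N = 50 → 200), and falls with
neighbourhood size (nb = 4 → 12) — these orderings hold already at the
default coupling. Users studying the on/off contrast itself should treat
`ephaptic_factor` as the decisive knob and report it alongside results.

## Known limitations

- Explicit Euler with a hard threshold makes the spike-peak value
  step-size dependent (the overshoot sample varies by phase); ISIs converge
  to the closed form as dt → 0 but the LFP's spike amplitudes do not.
- The ring geometry is index-based; no 2-D/3-D embedding, so "distance" is
  purely ordinal.
- Sample entropy at large τ uses few hundred samples at desk scale; the
  missing-scale guard (10·(m+1)) is a pragmatic floor, not a bias
  correction.
- No multiple-testing correction across grid comparisons (deliberate, to
  match the analysis style the grids reproduce).
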