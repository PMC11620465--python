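"""Compare ephaptic-on vs ephaptic-off complexity over matched seeds.

Runs a few paired realisations of the weak-synapse network, computes the
integrated multiscale-entropy complexity K of each LFP and tests the regime
difference with the Wilcoxon rank-sum test.  Matched seeds mean both
regimes share topology, neuron parameters and initial conditions exactly.
"""

import numpy as np

import ephapsim as es

spec_on, spec_off = es.ConditionSpec(duration=30.0, n_seeds=5).paired()
on = es.run_condition(spec_on)
off = es.run_condition(spec_off)

print("seed   K (ephaptic on)   K (ephaptic off)")
for seed, k1, k0 in zip(on.seeds, on.k_values, off.k_values):
    print(f"{seed:4d}   {k1:15.2f}   {k0:16.2f}")

gain = 100 * (on.k_mean - off.k_mean) / off.k_mean
c = es.wilcoxon_compare(on.k_values, off.k_values)
print(f"\nmean K: on {on.k_mean:.2f} vs off {off.k_mean:.2f} "
      f"({gain:+.2f}%)  rank-sum p={c.p_value:.3f} [{c.stars}]")

# At the default coupling factor (1e-2) the two regimes differ by ~1% in K,
# within seed-to-seed noise; the contrast grows sharply at stronger ephaptic
# coupling (see docs/methods.md on coupling-constant sensitivity).
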