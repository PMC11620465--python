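# Complexity vs neighbourhood size at N=200, omega=5
n_neurons: 200
nb: 4
rp: 0.1
omega: 5.0
n_seeds: 20
sweep:
  nb: [4, 12]
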