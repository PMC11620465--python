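# Complexity vs network size, rp=0.1, omega=5 (full protocol)
nb: 4
rp: 0.1
omega: 5.0
n_seeds: 20
sweep:
  n_neurons: [50, 100, 150, 200]
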