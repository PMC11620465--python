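# Complexity vs rewiring probability, N=100, omega=5 (decade grid)
n_neurons: 100
nb: 4
omega: 5.0
n_seeds: 20
sweep:
  rp: [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
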