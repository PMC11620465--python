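# Complexity vs synaptic intensity, N=100, rp=0.1 (full protocol)
n_neurons: 100
nb: 4
rp: 0.1
n_seeds: 20
sweep:
  omega: [5.0, 10.0, 15.0, 20.0, 30.0]
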