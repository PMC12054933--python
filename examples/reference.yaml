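# Reference two-memory training experiment (mixed inhibitory plasticity).
# All omitted parameters take the built-in reference defaults.
network:
  N: 100
  Ne: 80
  Nhi: 10
  Nai: 10
  ghi: 200
  gai: 400
  dt: 0.001

stdp:
  e:
    gamma_l: 0.005
    lam: 100

experiment:
  M: 2
  regime: mixed
  rest: 5.0
  n_epochs: 35
  consolidation: 20.0
  alternation: random
  seed: 5
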