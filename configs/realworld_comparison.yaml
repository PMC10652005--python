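scenario: realworld_comparison
parameters:
  phi: 0.4
  theta: 2.0
  i: 0.03251
  lam: 0.07692
  mu: 0.0003343
  alpha: 1.0
  beta: 1.2
  gamma: 1.673
targets:
  target_prev_D: 0.0780
  target_prev_S: 0.186
  target_population: 1000000
interventions:
  - kind: universal
    effect: 0.21
  - kind: selective
    effect: 0.44
  - kind: indicated
    effect: 0.31
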