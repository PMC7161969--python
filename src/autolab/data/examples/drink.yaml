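procedure: drink
planner: bayesian
budget: 25
target: null
seed: 1
instrument:
  hidden_pref: [0.45, 0.10, 0.30, 0.10, 0.05]
  rater_noise: 0.1
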