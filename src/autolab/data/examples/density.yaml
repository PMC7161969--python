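procedure: density
planner: bayesian
budget: 25
target: 1.0
seed: 1
instrument:
  stocks: builtin
  total_volume: 10.0
  noise_sd: 0.0
channels: [console]
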