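procedure: color
planner: bayesian
budget: 25
target: [0.16, 0.56, 0.28]
seed: 1
instrument:
  stocks: builtin
  noise_sd: 0.005
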