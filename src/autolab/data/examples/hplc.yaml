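procedure: hplc
planner: bayesian
budget: 100
target: null
seed: 1
instrument:
  noise_sd: 0.05
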