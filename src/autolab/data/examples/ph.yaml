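procedure: ph
planner: bayesian
budget: 25
target: 7.0
seed: 1
instrument:
  stocks: builtin
  ph_model: buffered_linear
  noise_sd: 0.0
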