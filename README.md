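# autolab

A desk-scale, configuration-driven framework for closed-loop autonomous
experimentation. A session pairs an experiment **planner** with a (virtual)
**instrument** and a **characterization** stage, and iterates

    propose -> enqueue -> dequeue -> execute -> characterize -> record

until the experiment budget is spent. Requests and observations are stored
in distinct SQLite tables operating on a first-in-first-out principle, with
a CSV mirror for ad-hoc analysis. Everything is a pure function of the
session seed, so runs are exactly reproducible.

## What is included

| module | role |
| --- | --- |
| `autolab.session` / `store` / `config` / `records` / `space` | workflow manager: config parsing, FIFO queues, the closed loop, status reports |
| `autolab.planners` | uniform random search, two-stage full-factorial DoE, and a native kernel-density Bayesian planner with alternating exploration/exploitation bias; plug-in registry for external optimizers |
| `autolab.virtual_lab` | abstract-to-hardware parameter mapping (simplex fractions, 8-pump layout, calibration, total volume) and simulators: color / pH / density mixing, a six-parameter HPLC peak-area surface, and a five-star drink rater |
| `autolab.characterization` | losses: max-norm RGB distance, absolute scalar deviation, response maximization, star-rating loss |
| `autolab.emulator` | Gaussian-process surrogate (mean + uncertainty) trained from logged parameter/response tables, for cheap planner benchmarking |
| `autolab.analysis` | best-so-far traces, repeated-execution planner benchmarks (mean ± standard error), pairwise-distance distributions, plots |
| `autolab.intents` / `channels` / `cli` | deterministic intent parser, console and drop-folder message channels, `autolab` command-line interface |

The five bundled stocks (normalized RGB triples, pH values, densities) ship
as `src/autolab/data/stocks.csv`; example session configurations for every
procedure live in `src/autolab/data/examples/`.

## Run a session

```sh
autolab run --config src/autolab/data/examples/density.yaml --db lab.db
autolab status --session density-bayesian-s1 --db lab.db
autolab report --session density-bayesian-s1 --db lab.db --out report.json
autolab benchmark --config src/autolab/data/examples/hplc.yaml \
    --planners bayesian,random,doe --runs 20 --out bench.csv --plot bench.png
```

A session configuration is a single YAML file:

```yaml
procedure: density        # color | ph | density | drink | hplc | custom
planner: bayesian         # random | doe | bayesian | <registered name>
budget: 25                # successful experiments to run
target: 1.0               # RGB triple for color, scalar for ph/density,
                          # null for maximize-style procedures
seed: 1
channels: [console]
instrument:
  stocks: builtin         # or a CSV path (columns label,r,g,b,ph,density)
  total_volume: 10.0
  noise_sd: 0.0
  ph_model: buffered_linear
```

Unknown keys are rejected. Failed experiments (e.g. an all-zero recipe the
liquid handler cannot dispense) are logged and skipped; the budget counts
successful experiments only.

## Python API sketch

```python
from autolab import load_config, run_session, status_report

config = load_config(open("session.yaml").read())
history = run_session(config)
print(status_report(history))
```

Register an external optimizer:

```python
from autolab.planners import register_planner

register_planner("my_opt", lambda budget, state: MyPlanner())
```

where `MyPlanner.propose(space, history, iteration, rng)` returns a
parameter vector in `[0, 1]^d` and a bias-mode tag.
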