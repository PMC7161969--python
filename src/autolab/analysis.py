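"""Analysis and planner benchmarking.

Best-so-far traces, repeated-execution planner benchmarks (mean trace with
standard error), and the pairwise L2 distance distribution of the sampled
parameter points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .characterization import TargetSpec
from .emulator import SurrogateModel
from .errors import ConfigurationError, InstrumentError, PreconditionError
from .planners import PlannerState, available_planners, make_planner
from .records import History, Observation, ProposalRequest
from .space import ParameterSpace

DISTANCE_HISTOGRAM_BINS = 30


def best_so_far(objectives: Sequence[float]) -> np.ndarray:
    """Running minimum of an objective sequence (monotone non-increasing)."""
    arr = np.asarray(objectives, dtype=float)
    if arr.size == 0:
        raise PreconditionError("best_so_far requires a non-empty sequence")
    return np.minimum.accumulate(arr)


def pairwise_distances(history: History) -> np.ndarray:
    """All n(n-1)/2 Euclidean distances between proposal vectors."""
    if len(history) < 2:
        raise PreconditionError(
            "pairwise_distances requires at least 2 experiments"
        )
    return pdist(history.params_matrix())


# -- objective surfaces ------------------------------------------------------


class ObjectiveSurface:
    """A minimizable response surface with an attached parameter space."""

    space: ParameterSpace

    def evaluate(self, params: np.ndarray,
                 rng: np.random.Generator) -> float:
        raise NotImplementedError


class FunctionSurface(ObjectiveSurface):
    """Wrap a plain ``f(x) -> loss`` callable."""

    def __init__(self, fn: Callable[[np.ndarray], float], n_dims: int):
        self.fn = fn
        self.space = ParameterSpace(n_dims=n_dims)

    def evaluate(self, params, rng):
        return float(self.fn(np.asarray(params, dtype=float)))


class InstrumentSurface(ObjectiveSurface):
    """An instrument plus its characterization stage."""

    def __init__(self, instrument, objective_fn):
        self.instrument = instrument
        self.objective_fn = objective_fn
        self.space = instrument.space

    def evaluate(self, params, rng):
        return float(self.objective_fn(self.instrument.measure(params, rng)))


class SurrogateSurface(ObjectiveSurface):
    """A trained emulator; by default its mean response is maximized."""

    def __init__(self, model: SurrogateModel, maximize: bool = True):
        self.model = model
        self.maximize = maximize
        self.space = ParameterSpace(n_dims=model.n_dims)

    def evaluate(self, params, rng):
        mean, _ = self.model.predict(np.asarray(params, dtype=float))
        return -mean if self.maximize else mean


def as_surface(surface: Union[ObjectiveSurface, SurrogateModel, Callable],
               n_dims: Optional[int] = None) -> ObjectiveSurface:
    if isinstance(surface, ObjectiveSurface):
        return surface
    if isinstance(surface, SurrogateModel):
        return SurrogateSurface(surface)
    if callable(surface):
        if n_dims is None:
            raise ConfigurationError(
                "n_dims is required to wrap a bare callable"
            )
        return FunctionSurface(surface, n_dims)
    raise ConfigurationError(f"cannot interpret surface {surface!r}")


# -- closed-loop runs on a surface -------------------------------------------


def run_loop(surface: ObjectiveSurface, planner_name: str, budget: int,
             seed: int, planner_state: Optional[PlannerState] = None
             ) -> History:
    """One lightweight closed-loop run of a planner against a surface."""
    space = surface.space
    planner = make_planner(planner_name, budget, planner_state)
    seeds = np.random.SeedSequence(seed).spawn(2)
    planner_rng = np.random.default_rng(seeds[0])
    surface_rng = np.random.default_rng(seeds[1])
    history = History(space, target=TargetSpec("maximize"),
                      session_id=f"bench-{planner_name}-s{seed}")
    attempts = 0
    consecutive_failures = 0
    while len(history) < budget and attempts < 10 * budget:
        iteration = len(history)
        if consecutive_failures >= 3:
            params, mode = planner_rng.uniform(size=space.n_dims), "none"
        else:
            params, mode = planner.propose(space, history, iteration,
                                           planner_rng)
        params = space.validate(np.asarray(params, dtype=float))
        attempts += 1
        try:
            objective = surface.evaluate(params, surface_rng)
        except InstrumentError:
            consecutive_failures += 1
            continue
        consecutive_failures = 0
        request = ProposalRequest(
            request_id=f"{history.session_id}-r{attempts - 1:04d}",
            session_id=history.session_id,
            params=tuple(params), mode=mode, created_at=attempts - 1,
        )
        history.record(request, Observation(
            request_id=request.request_id, objective=objective,
            measured_at=attempts - 1,
        ))
    return history


@dataclass(frozen=True)
class BenchmarkResult:
    """Per-planner mean best-so-far trace with standard errors."""

    budget: int
    n_runs: int
    mean_traces: Dict[str, np.ndarray]
    sem_traces: Dict[str, np.ndarray]
    mean_objective_traces: Dict[str, np.ndarray]
    runs: pd.DataFrame  # tidy: planner, run, iteration, objective, best_so_far

    def final_best(self, planner: str) -> float:
        return float(self.mean_traces[planner][-1])

    def to_csv(self, path) -> None:
        self.runs.to_csv(path, index=False)


def benchmark_planners(surface, planners: Sequence[str], budget: int,
                       n_runs: int, seed: int = 0,
                       planner_states: Optional[Dict[str, PlannerState]] = None,
                       n_dims: Optional[int] = None) -> BenchmarkResult:
    """Average planner performance over repeated seeded executions.

    Each planner is run ``n_runs`` times with independent seeds spawned
    from the master ``seed``; the per-iteration mean best-so-far trace and
    its standard error are reported alongside the raw tidy table.
    """
    if n_runs < 2:
        raise PreconditionError("n_runs must be >= 2")
    surface = as_surface(surface, n_dims)
    for name in planners:
        if name not in available_planners():
            raise ConfigurationError(
                f"unknown planner {name!r}; registered planners: "
                f"{', '.join(available_planners())}"
            )
    states = planner_states or {}
    run_seeds = np.random.SeedSequence(seed).generate_state(n_runs)

    rows = []
    mean_traces, sem_traces, mean_obj = {}, {}, {}
    for name in planners:
        traces = np.empty((n_runs, budget))
        objs = np.empty((n_runs, budget))
        for r in range(n_runs):
            history = run_loop(surface, name, budget, int(run_seeds[r]),
                               states.get(name))
            objectives = history.objectives()
            objs[r] = objectives
            traces[r] = best_so_far(objectives)
            for i in range(budget):
                rows.append((name, r, i, objs[r, i], traces[r, i]))
        mean_traces[name] = traces.mean(axis=0)
        sem_traces[name] = traces.std(axis=0, ddof=1) / np.sqrt(n_runs)
        mean_obj[name] = objs.mean(axis=0)

    runs = pd.DataFrame(
        rows, columns=["planner", "run", "iteration", "objective",
                       "best_so_far"])
    return BenchmarkResult(
        budget=budget, n_runs=n_runs, mean_traces=mean_traces,
        sem_traces=sem_traces, mean_objective_traces=mean_obj, runs=runs,
    )


# -- plotting ----------------------------------------------------------------


def plot_benchmark(result: BenchmarkResult, path) -> None:
    """Mean best-so-far traces with standard-error bands."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    iterations = np.arange(1, result.budget + 1)
    for name, mean in result.mean_traces.items():
        sem = result.sem_traces[name]
        ax.plot(iterations, mean, label=name)
        ax.fill_between(iterations, mean - sem, mean + sem, alpha=0.25)
    ax.set_xlabel("experiment")
    ax.set_ylabel("mean best-so-far objective")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_distance_histogram(distances: np.ndarray, n_dims: int, path,
                            label: str = "") -> None:
    """Histogram of pairwise distances over 30 equal bins on [0, sqrt(d)]."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    bins = np.linspace(0.0, np.sqrt(n_dims), DISTANCE_HISTOGRAM_BINS + 1)
    ax.hist(distances, bins=bins, density=True, alpha=0.8, label=label or None)
    ax.set_xlabel("pairwise L2 distance")
    ax.set_ylabel("density")
    if label:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
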