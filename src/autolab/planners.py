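"""Experiment-planning strategies.

Three planners share a single ``propose(space, history, iteration, rng)``
entry point: uniform random search, a two-stage full-factorial design of
experiments, and a native density-based Bayesian planner that alternates
between an exploration and an exploitation bias.

The Bayesian acquisition is a kernel-weighted merit over the observed
objectives,

    score(x) = (sum_k f_k K(x, x_k) + w0 fbar) / (sum_k K(x, x_k) + w0)

with an isotropic Gaussian kernel ``K`` and a prior weight ``w0`` that pulls
the score toward the mean objective ``fbar`` away from data. Small ``w0``
(exploitation) lets the score hug the observed minima; large ``w0``
(exploration) flattens the landscape so proposals drift toward unexplored
regions. Lower score is always more desirable.

In exploitation mode the kernel width acts as a self-adapting step size:
replaying the history's exploitation outcomes, the width grows after every
proposal that improved the best-so-far objective and shrinks after every one
that did not (a one-fifth-success-style rule), clipped to
``[width_min, width_max]``. The width therefore tracks the remaining error
scale without needing the objective's offset or units, and is a
deterministic function of the history.

External optimizers plug in through :func:`register_planner`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, GridSizeError, PreconditionError
from .records import History
from .space import ParameterSpace

# -- planner state -----------------------------------------------------------

DEFAULT_BIAS_SCHEDULE = ("exploit", "exploit", "exploit", "explore")
DEFAULT_GRID_CAP = 65536


@dataclass(frozen=True)
class PlannerState:
    """Tunable knobs shared by the planner implementations.

    ``kernel_width`` is the fixed width used by :func:`acquisition_value`;
    the Bayesian planner overrides it per iteration with the trust-region
    width described in the module docstring.
    """

    kind: str = "bayesian"
    rng_seed: int = 0
    bias_schedule: Tuple[str, ...] = DEFAULT_BIAS_SCHEDULE
    doe_levels: int = 2
    kernel_width: float = 0.1
    w0_exploit: float = 0.01
    w0_explore: float = 5.0
    n_uniform_candidates: int = 512
    n_local_candidates: int = 64
    refinement_sigmas: Tuple[float, ...] = (0.15, 0.05, 0.015, 0.005)
    width_grow: float = 1.5
    width_shrink: float = 0.7
    width_min: float = 0.02
    width_max: float = 0.3
    explore_width_floor: float = 0.2
    grid_cap: int = DEFAULT_GRID_CAP

    def __post_init__(self):
        if self.kernel_width <= 0:
            raise ConfigurationError("kernel_width must be > 0")
        if self.w0_exploit <= 0 or self.w0_explore <= 0:
            raise ConfigurationError("prior weights must be > 0")
        if self.doe_levels < 2:
            raise ConfigurationError("doe_levels must be >= 2")
        for m in self.bias_schedule:
            if m not in ("explore", "exploit"):
                raise ConfigurationError(f"invalid bias mode {m!r}")


# -- random search -----------------------------------------------------------

def propose_random(space: ParameterSpace, state: PlannerState,
                   rng: np.random.Generator) -> np.ndarray:
    """One uniform draw on ``[0, 1]^d``; advances the generator state."""
    return rng.uniform(size=space.n_dims)


# -- two-stage full factorial ------------------------------------------------

def full_factorial_grid(bounds: Sequence[Tuple[float, float]],
                        levels: int, cap: int = DEFAULT_GRID_CAP
                        ) -> np.ndarray:
    """All combinations of ``levels`` equally spaced values per dimension.

    Endpoints are included; ordering is the lexicographic product order and
    therefore deterministic.
    """
    d = len(bounds)
    n_points = levels ** d
    if n_points > cap:
        raise GridSizeError(n_points, cap)
    axes = [np.linspace(lo, hi, levels) for lo, hi in bounds]
    return np.array(list(itertools.product(*axes)), dtype=float)


def refine_subregion(history: History, space: ParameterSpace
                     ) -> Tuple[Tuple[float, float], ...]:
    """Per-dimension interval of half the parent range around the incumbent.

    The box is clipped to ``[0, 1]`` without re-centering, so an incumbent
    near a boundary keeps a one-sided (shorter) interval.
    """
    if len(history) == 0:
        raise PreconditionError("refine_subregion requires a non-empty history")
    best = history.best()[0].params
    half = 0.25  # quarter range either side -> half-range box
    return tuple(
        (max(0.0, b - half), min(1.0, b + half)) for b in best
    )


def propose_factorial(space: ParameterSpace, state: PlannerState,
                      stage: int, history: Optional[History] = None
                      ) -> np.ndarray:
    """Ordered batch of grid points for the requested DoE stage.

    Stage 1 covers the full unit hypercube; stage 2 covers the refined
    subregion around the stage-1 incumbent.
    """
    if stage == 1:
        bounds = space.bounds
    elif stage == 2:
        if history is None or len(history) == 0:
            raise PreconditionError(
                "stage 2 requires a completed stage-1 history"
            )
        bounds = refine_subregion(history, space)
    else:
        raise PreconditionError(f"stage must be 1 or 2, got {stage}")
    return full_factorial_grid(bounds, state.doe_levels, state.grid_cap)


# -- density-based Bayesian planner ------------------------------------------

def _kernel_scores(candidates: np.ndarray, X: np.ndarray, f: np.ndarray,
                   w0: float, width: float) -> np.ndarray:
    d2 = ((candidates[:, None, :] - X[None, :, :]) ** 2).sum(axis=-1)
    K = np.exp(-d2 / (2.0 * width * width))
    fbar = f.mean()
    return (K @ f + w0 * fbar) / (K.sum(axis=1) + w0)


def acquisition_value(x: Sequence[float], history: History, mode: str,
                      state: PlannerState) -> float:
    """Kernel-density-weighted merit of a single point (lower is better).

    With an empty history every point scores identically (uniform merit).
    """
    if mode not in ("explore", "exploit"):
        raise ConfigurationError(f"mode must be explore or exploit, got {mode!r}")
    x = history.space.validate(x)
    if len(history) == 0:
        return 0.0
    X = history.params_matrix()
    f = history.objectives()
    w0 = state.w0_explore if mode == "explore" else state.w0_exploit
    return float(_kernel_scores(x[None, :], X, f, w0, state.kernel_width)[0])


def _adaptive_width(history: History, state: PlannerState) -> float:
    """Success-driven kernel width, replayed from the recorded history.

    Starting at ``width_max``, the width is multiplied by ``width_grow``
    for every past exploitation proposal that improved the running best
    objective and by ``width_shrink`` for every one that did not, clipping
    to ``[width_min, width_max]`` after each update.
    """
    width = state.width_max
    best = np.inf
    for request, obs in history:
        if request.mode == "exploit":
            factor = (state.width_grow if obs.objective < best
                      else state.width_shrink)
            width = min(max(width * factor, state.width_min),
                        state.width_max)
        best = min(best, obs.objective)
    return width


def _candidate_set(space: ParameterSpace, X: np.ndarray, f: np.ndarray,
                   width: float, state: PlannerState,
                   rng: np.random.Generator) -> np.ndarray:
    """Uniform draws, a local cloud around the incumbent, and reflections
    of the incumbent away from its worse neighbours."""
    d = space.n_dims
    i_best = int(np.argmin(f))
    inc = X[i_best]
    parts: List[np.ndarray] = [
        rng.uniform(size=(state.n_uniform_candidates, d)),
        np.clip(inc + rng.normal(0.0, max(width, 0.02),
                                 size=(state.n_local_candidates, d)), 0, 1),
    ]
    if len(f) >= 2:
        dist = ((X - inc) ** 2).sum(axis=1)
        dist[i_best] = np.inf
        for j in np.argsort(dist)[:5]:
            if f[j] > f[i_best]:
                direction = inc - X[j]
                for alpha in (0.3, 0.6, 1.0, 1.8):
                    parts.append(np.clip(
                        inc + alpha * direction
                        + rng.normal(0.0, 0.01, size=(4, d)), 0, 1))
    return np.vstack(parts)


def propose_bayesian(space: ParameterSpace, history: History,
                     state: PlannerState, rng: np.random.Generator,
                     iteration: int) -> Tuple[np.ndarray, str]:
    """Minimize the acquisition over a seeded candidate set.

    The bias mode follows ``state.bias_schedule`` cyclically. An empty
    history yields a uniform draw. After scoring the initial candidate set,
    a few rounds of Gaussian perturbations with shrinking scale refine the
    running argmin; ties break toward the lowest candidate index.
    """
    mode = state.bias_schedule[iteration % len(state.bias_schedule)]
    if len(history) == 0:
        return rng.uniform(size=space.n_dims), mode

    X = history.params_matrix()
    f = history.objectives()

    if mode == "explore":
        # Candidates biased toward sparsely sampled territory: keep the
        # quarter of the uniform draws farthest from any observation, then
        # let the (flattened) acquisition pick among them.
        width = max(_adaptive_width(history, state),
                    state.explore_width_floor)
        candidates = rng.uniform(
            size=(state.n_uniform_candidates, space.n_dims))
        d2 = ((candidates[:, None, :] - X[None, :, :]) ** 2).sum(axis=-1)
        nearest = d2.min(axis=1)
        keep = np.argsort(-nearest)[: max(state.n_uniform_candidates // 4, 1)]
        keep.sort()  # preserve draw order for deterministic tie-breaking
        candidates = candidates[keep]
        scores = _kernel_scores(candidates, X, f, state.w0_explore, width)
        return candidates[int(np.argmin(scores))], mode

    width = _adaptive_width(history, state)
    w0 = state.w0_exploit
    candidates = _candidate_set(space, X, f, width, state, rng)
    scores = _kernel_scores(candidates, X, f, w0, width)
    best_idx = int(np.argmin(scores))
    best, best_score = candidates[best_idx], scores[best_idx]
    for sigma in state.refinement_sigmas:
        cloud = np.clip(
            best + rng.normal(0.0, sigma, size=(state.n_local_candidates,
                                                space.n_dims)), 0, 1)
        cloud_scores = _kernel_scores(cloud, X, f, w0, width)
        i = int(np.argmin(cloud_scores))
        if cloud_scores[i] < best_score:
            best, best_score = cloud[i], cloud_scores[i]
    return best, mode


# -- planner objects and registry --------------------------------------------

class Planner:
    """Minimal planner interface: stateless between sessions."""

    name = "base"

    def propose(self, space: ParameterSpace, history: History,
                iteration: int, rng: np.random.Generator
                ) -> Tuple[np.ndarray, str]:
        raise NotImplementedError


class RandomPlanner(Planner):
    name = "random"

    def __init__(self, state: Optional[PlannerState] = None):
        self.state = state or PlannerState(kind="random")

    def propose(self, space, history, iteration, rng):
        return propose_random(space, self.state, rng), "none"


class DoEPlanner(Planner):
    """Two-stage full factorial design fitted to a session budget.

    The number of levels per stage is the smallest ``k >= doe_levels`` whose
    grid covers the stage budget, and the ordered grid is truncated to the
    stage budget; stage 1 gets ``ceil(budget / 2)`` points, stage 2 the rest
    on the refined subregion around the stage-1 incumbent.
    """

    name = "doe"

    def __init__(self, budget: int, state: Optional[PlannerState] = None):
        if budget < 1:
            raise PreconditionError("budget must be >= 1")
        self.state = state or PlannerState(kind="doe")
        self.budget = int(budget)
        self.stage1_budget = (self.budget + 1) // 2
        self._stage2_batch: Optional[np.ndarray] = None

    def _levels_for(self, n_points: int, d: int) -> int:
        k = self.state.doe_levels
        while k ** d < n_points:
            k += 1
        return k

    def propose(self, space, history, iteration, rng):
        d = space.n_dims
        if iteration < self.stage1_budget:
            k = self._levels_for(self.stage1_budget, d)
            grid = full_factorial_grid(space.bounds, k, self.state.grid_cap)
            return grid[iteration], "none"
        if self._stage2_batch is None:
            n2 = self.budget - self.stage1_budget
            k = self._levels_for(max(n2, 1), d)
            bounds = refine_subregion(history, space)
            self._stage2_batch = full_factorial_grid(
                bounds, k, self.state.grid_cap)
        return self._stage2_batch[iteration - self.stage1_budget], "none"


class BayesianPlanner(Planner):
    name = "bayesian"

    def __init__(self, state: Optional[PlannerState] = None):
        self.state = state or PlannerState(kind="bayesian")

    def propose(self, space, history, iteration, rng):
        return propose_bayesian(space, history, self.state, rng, iteration)


PlannerFactory = Callable[..., Planner]
_REGISTRY: Dict[str, PlannerFactory] = {}


def register_planner(name: str, factory: PlannerFactory) -> None:
    """Attach an external optimizer under ``name``.

    The factory receives ``budget`` and ``state`` keyword arguments and must
    return an object with the :class:`Planner` ``propose`` signature.
    """
    _REGISTRY[name] = factory


def available_planners() -> Tuple[str, ...]:
    return ("random", "doe", "bayesian") + tuple(sorted(_REGISTRY))


def make_planner(name: str, budget: int,
                 state: Optional[PlannerState] = None) -> Planner:
    if name == "random":
        return RandomPlanner(state)
    if name == "doe":
        return DoEPlanner(budget, state)
    if name == "bayesian":
        return BayesianPlanner(state)
    if name in _REGISTRY:
        return _REGISTRY[name](budget=budget, state=state)
    raise ConfigurationError(
        f"unknown planner {name!r}; registered planners: "
        f"{', '.join(available_planners())}"
    )
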