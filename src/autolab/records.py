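"""Session records: proposals, observations, histories and status reports.

Timestamps are logical counters assigned by the session loop, not wall-clock
times, so that every run is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .errors import IntegrityError, ValidationError
from .space import ParameterSpace

MODES = ("explore", "exploit", "none")


@dataclass(frozen=True)
class ProposalRequest:
    """A queued experiment proposal."""

    request_id: str
    session_id: str
    params: Tuple[float, ...]
    mode: str = "none"
    created_at: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValidationError(
                f"mode must be one of {MODES}, got {self.mode!r}"
            )
        params = tuple(float(v) for v in self.params)
        if not params:
            raise ValidationError("params must be non-empty")
        for v in params:
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"param {v} outside [0, 1]")
        object.__setattr__(self, "params", params)
        object.__setattr__(self, "created_at", int(self.created_at))


@dataclass(frozen=True)
class Observation:
    """The characterized outcome of one executed proposal.

    ``objective`` is the session loss (lower is better); ``raw`` holds the
    measured quantities the loss was computed from (RGB triple, pH, density,
    peak area, star rating, dispensed volumes, ...).
    """

    request_id: str
    objective: float
    raw: Dict[str, Any] = field(default_factory=dict)
    measured_at: int = 0

    def __post_init__(self):
        obj = float(self.objective)
        if not math.isfinite(obj):
            raise ValidationError(f"objective must be finite, got {obj}")
        object.__setattr__(self, "objective", obj)
        object.__setattr__(self, "measured_at", int(self.measured_at))


class History:
    """Chronologically ordered record of (request, observation) pairs."""

    def __init__(self, space: ParameterSpace, target: Any = None,
                 session_id: str = ""):
        self.space = space
        self.target = target
        self.session_id = session_id
        self._pairs: List[Tuple[ProposalRequest, Observation]] = []
        self._ids: set[str] = set()

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self) -> Iterator[Tuple[ProposalRequest, Observation]]:
        return iter(self._pairs)

    @property
    def pairs(self) -> Tuple[Tuple[ProposalRequest, Observation], ...]:
        return tuple(self._pairs)

    def record(self, request: ProposalRequest, obs: Observation) -> "History":
        """Append one pair, enforcing uniqueness and chronological order."""
        if obs.request_id != request.request_id:
            raise IntegrityError(
                f"observation for {obs.request_id!r} does not match request "
                f"{request.request_id!r}"
            )
        if request.request_id in self._ids:
            raise IntegrityError(
                f"request {request.request_id!r} already recorded"
            )
        if self._pairs and request.created_at < self._pairs[-1][0].created_at:
            raise IntegrityError(
                "requests must be recorded in creation order"
            )
        self.space.validate(request.params)
        self._pairs.append((request, obs))
        self._ids.add(request.request_id)
        return self

    def objectives(self) -> np.ndarray:
        return np.array([o.objective for _, o in self._pairs], dtype=float)

    def params_matrix(self) -> np.ndarray:
        if not self._pairs:
            return np.empty((0, self.space.n_dims))
        return np.array([r.params for r, _ in self._pairs], dtype=float)

    def best(self) -> Optional[Tuple[ProposalRequest, Observation]]:
        if not self._pairs:
            return None
        return min(self._pairs, key=lambda p: p[1].objective)


def record_observation(history: History, request: ProposalRequest,
                       obs: Observation) -> History:
    """Functional alias for :meth:`History.record`."""
    return history.record(request, obs)


@dataclass(frozen=True)
class Report:
    """Point-in-time session summary."""

    session_id: str
    n_completed: int
    best_request: Optional[ProposalRequest]
    best_objective: Optional[float]
    objective_trace: Tuple[float, ...]
    timestamp: int = 0

    def __post_init__(self):
        if self.n_completed != len(self.objective_trace):
            raise ValidationError(
                "n_completed must equal the trace length"
            )
        if self.objective_trace:
            if self.best_objective != min(self.objective_trace):
                raise ValidationError(
                    "best_objective must be the minimum of the trace"
                )


def status_report(history: History, timestamp: int = 0) -> Report:
    """Summarize a history; an empty history yields an empty report."""
    trace = tuple(float(o.objective) for _, o in history)
    best = history.best()
    return Report(
        session_id=history.session_id,
        n_completed=len(trace),
        best_request=best[0] if best else None,
        best_objective=best[1].objective if best else None,
        objective_trace=trace,
        timestamp=int(timestamp),
    )
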