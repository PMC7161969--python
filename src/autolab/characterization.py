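"""Turning raw measurements into the session objective (a loss to minimize)."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Callable, Dict, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError

_NORM_TOL = 1e-6


@dataclass(frozen=True)
class TargetSpec:
    """What the researcher asked for: an RGB triple, a scalar, or 'maximize'."""

    kind: str                    # rgb | scalar | maximize
    value: Any = None

    def __post_init__(self):
        if self.kind == "rgb":
            triple = tuple(float(v) for v in self.value)
            if len(triple) != 3 or abs(sum(triple) - 1.0) > _NORM_TOL \
                    or any(v < 0 for v in triple):
                raise ValidationError(
                    "rgb target must be a normalized triple"
                )
            object.__setattr__(self, "value", triple)
        elif self.kind == "scalar":
            v = float(self.value)
            if not math.isfinite(v):
                raise ValidationError("scalar target must be finite")
            object.__setattr__(self, "value", v)
        elif self.kind == "maximize":
            object.__setattr__(self, "value", None)
        else:
            raise ValidationError(f"unknown target kind {self.kind!r}")


def _check_normalized(triple: Sequence[float], label: str) -> np.ndarray:
    arr = np.asarray(triple, dtype=float)
    if arr.shape != (3,):
        raise ValidationError(f"{label} must have 3 components")
    if np.any(arr < 0) or abs(arr.sum() - 1.0) > _NORM_TOL:
        raise ValidationError(
            f"{label} must be normalized (sum 1, entries >= 0); "
            f"got {arr.tolist()}"
        )
    return arr


def rgb_loss(measured: Sequence[float], target: Sequence[float]) -> float:
    """Maximum-norm distance between two normalized RGB triples.

    Both triples must sum to one with non-negative entries; the result lies
    in ``[0, 1]`` and vanishes iff the triples are equal.
    """
    m = _check_normalized(measured, "measured RGB")
    t = _check_normalized(target, "target RGB")
    return float(np.max(np.abs(m - t)))


def scalar_loss(measured: float, target: float) -> float:
    """Absolute deviation of a scalar measurement from its target."""
    m, t = float(measured), float(target)
    if not (math.isfinite(m) and math.isfinite(t)):
        raise ValidationError("scalar_loss requires finite inputs")
    return abs(m - t)


def maximize_objective(measured: float) -> float:
    """Negate a non-negative response so the minimizing loop maximizes it."""
    m = float(measured)
    if m < 0:
        raise ValidationError(
            f"maximize_objective expects a non-negative response, got {m}"
        )
    return -m


def rating_to_loss(stars: int) -> float:
    """Map a 1..5 star rating onto a loss in [0, 1] (5 stars -> 0)."""
    s = int(stars)
    if not 1 <= s <= 5:
        raise ValidationError(f"stars must be in 1..5, got {s}")
    return (5 - s) / 4.0


def make_target(procedure: str, target: Any) -> TargetSpec:
    if procedure == "color":
        return TargetSpec("rgb", target)
    if procedure in ("ph", "density"):
        return TargetSpec("scalar", target)
    if procedure in ("drink", "hplc"):
        return TargetSpec("maximize")
    raise ConfigurationError(
        f"no default target mapping for procedure {procedure!r}"
    )


def make_objective(procedure: str, target: TargetSpec
                   ) -> Callable[[Dict[str, Any]], float]:
    """Build the raw-measurement -> objective function for a procedure."""
    if procedure == "color":
        def objective(raw):
            return rgb_loss(raw["rgb"], target.value)
    elif procedure == "ph":
        def objective(raw):
            return scalar_loss(raw["ph"], target.value)
    elif procedure == "density":
        def objective(raw):
            return scalar_loss(raw["density"], target.value)
    elif procedure == "hplc":
        def objective(raw):
            return maximize_objective(raw["peak_area"])
    elif procedure == "drink":
        def objective(raw):
            return rating_to_loss(raw["stars"])
    else:
        raise ConfigurationError(
            f"no objective available for procedure {procedure!r}"
        )
    return objective
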