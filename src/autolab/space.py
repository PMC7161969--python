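"""Abstract normalized parameter spaces.

Planners always operate on the unit hypercube ``[0, 1]^d``; instrument
bindings carry the per-dimension physical ranges used to translate abstract
parameters into hardware settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class ParameterSpace:
    """A ``d``-dimensional search space normalized to the unit hypercube.

    Parameters
    ----------
    n_dims :
        Number of abstract parameters, at least 1.
    dim_names :
        Optional identifiers, one per dimension. Defaults to ``p1..pd``.
    hardware_scalars :
        Per-dimension ``(low, high)`` physical ranges used by instrument
        bindings; purely informational on the abstract side. Defaults to
        ``(0.0, 1.0)`` everywhere.
    """

    n_dims: int
    dim_names: Tuple[str, ...] = field(default=())
    hardware_scalars: Tuple[Tuple[float, float], ...] = field(default=())

    def __post_init__(self):
        if int(self.n_dims) < 1:
            raise ValidationError(f"n_dims must be >= 1, got {self.n_dims}")
        object.__setattr__(self, "n_dims", int(self.n_dims))
        names = tuple(self.dim_names) or tuple(
            f"p{i + 1}" for i in range(self.n_dims)
        )
        if len(names) != self.n_dims:
            raise ValidationError(
                f"expected {self.n_dims} dim_names, got {len(names)}"
            )
        object.__setattr__(self, "dim_names", names)
        scalars = tuple(
            (float(lo), float(hi)) for lo, hi in self.hardware_scalars
        ) or tuple((0.0, 1.0) for _ in range(self.n_dims))
        if len(scalars) != self.n_dims:
            raise ValidationError(
                f"expected {self.n_dims} hardware_scalars, got {len(scalars)}"
            )
        for lo, hi in scalars:
            if not lo < hi:
                raise ValidationError(
                    f"hardware scalar low must be < high, got ({lo}, {hi})"
                )
        object.__setattr__(self, "hardware_scalars", scalars)

    @property
    def bounds(self) -> Tuple[Tuple[float, float], ...]:
        """Abstract bounds — always the closed unit interval per dimension."""
        return tuple((0.0, 1.0) for _ in range(self.n_dims))

    def contains(self, params: Sequence[float]) -> bool:
        x = np.asarray(params, dtype=float)
        return x.shape == (self.n_dims,) and bool(
            np.all(x >= 0.0) and np.all(x <= 1.0)
        )

    def validate(self, params: Sequence[float]) -> np.ndarray:
        """Return ``params`` as an array, or raise :class:`ValidationError`."""
        x = np.asarray(params, dtype=float)
        if x.shape != (self.n_dims,):
            raise ValidationError(
                f"expected {self.n_dims} parameters, got shape {x.shape}"
            )
        if not np.all(np.isfinite(x)):
            raise ValidationError("parameters must be finite")
        if np.any(x < 0.0) or np.any(x > 1.0):
            raise ValidationError(f"parameters outside [0, 1]: {x.tolist()}")
        return x

    def to_hardware(self, params: Sequence[float]) -> np.ndarray:
        """Map abstract ``[0, 1]`` parameters onto the physical ranges."""
        x = self.validate(params)
        lo = np.array([s[0] for s in self.hardware_scalars])
        hi = np.array([s[1] for s in self.hardware_scalars])
        return lo + x * (hi - lo)
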