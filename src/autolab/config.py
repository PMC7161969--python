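"""Session configuration: a single YAML file drives a whole session.

Top-level keys: ``procedure``, ``planner``, ``budget``, ``target``,
``instrument``, ``channels``, ``seed``. Unknown keys are rejected so typos
fail loudly instead of silently falling back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional, Sequence, Tuple

import yaml

from .errors import ConfigurationError, ValidationError

PROCEDURES = ("color", "ph", "density", "drink", "hplc", "custom")
PLANNERS = ("random", "doe", "bayesian", "external")

DEFAULT_SEED = 0
DEFAULT_TOTAL_VOLUME_ML = 10.0

_TOP_KEYS = {"procedure", "planner", "budget", "target", "instrument",
             "channels", "seed", "session_id"}
_INSTRUMENT_KEYS = {"name", "stocks", "pump_layout", "calibration",
                    "total_volume", "noise_sd", "ph_model", "hidden_pref",
                    "rater_noise"}


@dataclass(frozen=True)
class InstrumentBinding:
    """Everything the virtual lab needs to build an instrument."""

    name: str = ""
    stocks: str = "builtin"          # "builtin" or a CSV path
    pump_layout: Tuple[int, ...] = (0, 1, 2, 3, 4)  # stock i -> pump index
    calibration: Tuple[float, ...] = (1.0,) * 8
    total_volume: float = DEFAULT_TOTAL_VOLUME_ML
    noise_sd: float = 0.0
    ph_model: str = "buffered_linear"
    hidden_pref: Optional[Tuple[float, ...]] = None
    rater_noise: float = 0.0

    def __post_init__(self):
        if self.total_volume <= 0:
            raise ValidationError("total_volume must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if any(c <= 0 for c in self.calibration):
            raise ValidationError("calibration factors must be > 0")


@dataclass(frozen=True)
class SessionConfig:
    """Validated, fully defaulted configuration for one session."""

    procedure: str
    planner: str
    budget: int
    target: Any
    instrument: InstrumentBinding = field(default_factory=InstrumentBinding)
    channels: Tuple[str, ...] = ("console",)
    seed: int = DEFAULT_SEED
    session_id: str = ""

    def __post_init__(self):
        if self.procedure not in PROCEDURES:
            raise ConfigurationError(
                f"unknown procedure {self.procedure!r}; "
                f"registered procedures: {', '.join(PROCEDURES)}"
            )
        if self.planner not in PLANNERS:
            raise ConfigurationError(
                f"unknown planner {self.planner!r}; "
                f"registered planners: {', '.join(PLANNERS)}"
            )
        if int(self.budget) < 1:
            raise ConfigurationError(
                f"budget must be >= 1, got {self.budget}"
            )
        object.__setattr__(self, "budget", int(self.budget))
        object.__setattr__(self, "seed", int(self.seed))
        object.__setattr__(self, "channels", tuple(self.channels))
        _validate_target(self.procedure, self.target)
        if not self.session_id:
            object.__setattr__(
                self, "session_id",
                f"{self.procedure}-{self.planner}-s{self.seed}",
            )


def _validate_target(procedure: str, target: Any) -> None:
    if procedure == "color":
        try:
            triple = [float(v) for v in target]
        except (TypeError, ValueError):
            raise ConfigurationError(
                "color procedure requires an RGB-triple target"
            ) from None
        if len(triple) != 3:
            raise ConfigurationError(
                f"color target must have 3 components, got {len(triple)}"
            )
        if abs(sum(triple) - 1.0) > 1e-6 or any(v < 0 for v in triple):
            raise ConfigurationError(
                "color target must be a normalized RGB triple (sum 1, >= 0)"
            )
    elif procedure in ("ph", "density"):
        try:
            float(target)
        except (TypeError, ValueError):
            raise ConfigurationError(
                f"{procedure} procedure requires a scalar target"
            ) from None
    elif procedure in ("drink", "hplc"):
        if target is not None:
            raise ConfigurationError(
                f"{procedure} procedure maximizes its response; "
                "target must be omitted or null"
            )
    # custom: anything goes


def load_config(text: str) -> SessionConfig:
    """Parse YAML configuration text into a :class:`SessionConfig`.

    Raises
    ------
    ConfigurationError
        On YAML syntax errors (naming the offending line), unknown keys,
        unregistered planner/procedure names or invalid budgets/targets.
    """
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigurationError(f"configuration parse failure{line}: {exc}")
    if data is None:
        raise ConfigurationError("configuration file is empty")
    if not isinstance(data, dict):
        raise ConfigurationError("configuration must be a mapping")

    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(
            f"unknown configuration keys: {', '.join(sorted(unknown))}"
        )
    for key in ("procedure", "planner", "budget"):
        if key not in data:
            raise ConfigurationError(f"missing required key {key!r}")

    inst_data = data.get("instrument") or {}
    if not isinstance(inst_data, dict):
        raise ConfigurationError("'instrument' must be a mapping")
    unknown = set(inst_data) - _INSTRUMENT_KEYS
    if unknown:
        raise ConfigurationError(
            f"unknown instrument keys: {', '.join(sorted(unknown))}"
        )
    kwargs: Dict[str, Any] = dict(inst_data)
    if "pump_layout" in kwargs:
        kwargs["pump_layout"] = tuple(int(v) for v in kwargs["pump_layout"])
    if "calibration" in kwargs:
        kwargs["calibration"] = tuple(float(v) for v in kwargs["calibration"])
    if "hidden_pref" in kwargs and kwargs["hidden_pref"] is not None:
        kwargs["hidden_pref"] = tuple(float(v) for v in kwargs["hidden_pref"])
    try:
        instrument = InstrumentBinding(**kwargs)
    except (ValidationError, TypeError) as exc:
        raise ConfigurationError(f"invalid instrument binding: {exc}")

    return SessionConfig(
        procedure=str(data["procedure"]),
        planner=str(data["planner"]),
        budget=data["budget"],
        target=data.get("target"),
        instrument=instrument,
        channels=tuple(data.get("channels") or ("console",)),
        seed=int(data.get("seed", DEFAULT_SEED)),
        session_id=str(data.get("session_id", "")),
    )


def load_config_file(path: str | Path) -> SessionConfig:
    return load_config(Path(path).read_text())
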