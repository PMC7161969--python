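"""Virtual instruments: parameter mapping and response simulators.

Every simulator is a pure function of its inputs and the supplied random
generator. The mixing models are deliberately simple idealizations — linear
RGB blending, linearly additive buffered pH (with an optional hydrogen-ion
mixing alternative) and ideal volume-additive density — and define the
ground truth for this framework's closed-loop procedures and benchmarks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import InstrumentBinding, SessionConfig
from .errors import (ConfigurationError, DegenerateRecipeError,
                     InstrumentError, MappingError, ValidationError)
from .space import ParameterSpace

_SIMPLEX_TOL = 1e-9

# -- stock library -----------------------------------------------------------


@dataclass(frozen=True)
class StockLibrary:
    """Per-stock properties: normalized RGB triple, pH and density."""

    labels: Tuple[str, ...]
    rgb: Tuple[Tuple[float, float, float], ...]
    ph: Tuple[float, ...]
    density: Tuple[float, ...]

    def __post_init__(self):
        n = len(self.labels)
        if not (len(self.rgb) == len(self.ph) == len(self.density) == n):
            raise ValidationError("stock property lengths disagree")
        for triple in self.rgb:
            if any(v < 0 for v in triple):
                raise ValidationError("rgb entries must be non-negative")
            if abs(sum(triple) - 1.0) > _SIMPLEX_TOL:
                raise ValidationError(
                    f"rgb triple {triple} does not sum to 1"
                )
        if any(d <= 0 for d in self.density):
            raise ValidationError("densities must be > 0")

    @property
    def n_stocks(self) -> int:
        return len(self.labels)

    def rgb_matrix(self) -> np.ndarray:
        return np.array(self.rgb, dtype=float)

    def ph_vector(self) -> np.ndarray:
        return np.array(self.ph, dtype=float)

    def density_vector(self) -> np.ndarray:
        return np.array(self.density, dtype=float)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StockLibrary":
        frame = pd.read_csv(path)
        required = {"label", "r", "g", "b", "ph", "density"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(
                f"stock CSV missing columns: {', '.join(sorted(missing))}"
            )
        return cls(
            labels=tuple(frame["label"].astype(str)),
            rgb=tuple(
                (float(r), float(g), float(b))
                for r, g, b in zip(frame["r"], frame["g"], frame["b"])
            ),
            ph=tuple(float(v) for v in frame["ph"]),
            density=tuple(float(v) for v in frame["density"]),
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "label": self.labels,
            "r": [t[0] for t in self.rgb],
            "g": [t[1] for t in self.rgb],
            "b": [t[2] for t in self.rgb],
            "ph": self.ph,
            "density": self.density,
        }).to_csv(path, index=False)


def default_stocks() -> StockLibrary:
    """The five bundled stocks used by the color/pH/density procedures."""
    with resources.as_file(
        resources.files("autolab.data") / "stocks.csv"
    ) as path:
        return StockLibrary.from_csv(path)


# -- recipes and hardware mapping --------------------------------------------


@dataclass(frozen=True)
class MixtureRecipe:
    """A simplex fraction vector plus the total volume to dispense."""

    fractions: Tuple[float, ...]
    total_volume: float = 10.0

    def __post_init__(self):
        fr = tuple(float(v) for v in self.fractions)
        if any(v < 0 for v in fr):
            raise ValidationError("fractions must be non-negative")
        if abs(sum(fr) - 1.0) > _SIMPLEX_TOL:
            raise ValidationError(
                f"fractions sum to {sum(fr)!r}, expected 1"
            )
        if self.total_volume <= 0:
            raise ValidationError("total_volume must be > 0")
        object.__setattr__(self, "fractions", fr)

    def fraction_array(self) -> np.ndarray:
        return np.array(self.fractions, dtype=float)


@dataclass(frozen=True)
class PumpLayout:
    """Injective assignment of stocks to pumps with per-pump calibration."""

    n_pumps: int = 8
    stock_to_pump: Tuple[int, ...] = (0, 1, 2, 3, 4)
    calibration: Tuple[float, ...] = (1.0,) * 8

    def __post_init__(self):
        if len(set(self.stock_to_pump)) != len(self.stock_to_pump):
            raise ValidationError("stock_to_pump must be injective")
        if any(p < 0 or p >= self.n_pumps for p in self.stock_to_pump):
            raise ValidationError("pump index out of range")
        if len(self.calibration) != self.n_pumps:
            raise ValidationError(
                f"expected {self.n_pumps} calibration factors"
            )
        if any(c <= 0 for c in self.calibration):
            raise ValidationError("calibration factors must be > 0")


def normalize_to_fractions(raw: Sequence[float]) -> np.ndarray:
    """Project planner output in ``[0, 1]^n`` onto the simplex.

    Raises
    ------
    DegenerateRecipeError
        If the vector is all-zero: an instrument cannot dispense nothing.
    """
    x = np.asarray(raw, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValidationError(f"raw values outside [0, 1]: {x.tolist()}")
    total = x.sum()
    if total <= 0.0:
        raise DegenerateRecipeError(
            "all-zero parameter vector maps to an empty recipe"
        )
    return x / total


def map_to_hardware(recipe: MixtureRecipe, layout: PumpLayout) -> np.ndarray:
    """Per-pump volumes in mL: fraction x total volume x pump calibration."""
    fractions = recipe.fraction_array()
    if len(fractions) > len(layout.stock_to_pump):
        raise MappingError(
            f"layout assigns {len(layout.stock_to_pump)} pumps but the "
            f"recipe has {len(fractions)} stocks"
        )
    volumes = np.zeros(layout.n_pumps)
    for stock_idx, frac in enumerate(fractions):
        pump = layout.stock_to_pump[stock_idx]
        volumes[pump] = frac * recipe.total_volume * layout.calibration[pump]
    return volumes


# -- simulators --------------------------------------------------------------


def simulate_color(recipe: MixtureRecipe, stocks: StockLibrary,
                   noise_sd: float = 0.0,
                   rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Linear blending of the stock RGB triples, renormalized after noise."""
    fractions = recipe.fraction_array()
    truth = fractions @ stocks.rgb_matrix()
    if noise_sd > 0.0:
        rng = rng or np.random.default_rng()
        truth = truth + rng.normal(0.0, noise_sd, size=3)
    truth = np.clip(truth, 0.0, None)
    total = truth.sum()
    if total <= 0.0:
        # noise wiped out every channel; report a flat gray reading
        return np.full(3, 1.0 / 3.0)
    return truth / total


PH_MODELS = ("buffered_linear", "hydrogen_mixing")


def simulate_ph(recipe: MixtureRecipe, stocks: StockLibrary,
                model: str = "buffered_linear", noise_sd: float = 0.0,
                rng: Optional[np.random.Generator] = None) -> float:
    fractions = recipe.fraction_array()
    ph = stocks.ph_vector()
    if model == "buffered_linear":
        value = float(fractions @ ph)
    elif model == "hydrogen_mixing":
        value = float(-np.log10(fractions @ np.power(10.0, -ph)))
    else:
        raise ConfigurationError(
            f"unknown pH model {model!r}; choose from {PH_MODELS}"
        )
    if noise_sd > 0.0:
        rng = rng or np.random.default_rng()
        value += float(rng.normal(0.0, noise_sd))
    return value


def simulate_density(recipe: MixtureRecipe, stocks: StockLibrary,
                     noise_sd: float = 0.0,
                     rng: Optional[np.random.Generator] = None) -> float:
    """Ideal volume-additive mixing of the stock densities."""
    value = float(recipe.fraction_array() @ stocks.density_vector())
    if noise_sd > 0.0:
        rng = rng or np.random.default_rng()
        value += float(rng.normal(0.0, noise_sd))
    return value


# HPLC response surface. Six normalized parameters: two draw volumes, two
# wait times, two push rates. The analytic maximum AREA_MAX is reached at
# HPLC_OPTIMUM; the response is identically zero when the first draw volume
# is zero (nothing reaches the detector).
HPLC_AREA_MAX = 1000.0
HPLC_OPTIMUM = (1.0, 1.0, 0.6, 0.4, 0.5, 0.5)
_HPLC_WINDOW_CENTERS = (0.6, 0.4)
_HPLC_WINDOW_WIDTH = 0.5
_SAT_RATE = 5.0
_SAT_NORM = 1.0 - math.exp(-_SAT_RATE)


@dataclass(frozen=True)
class HPLCParams:
    """Six normalized sampling-sequence parameters."""

    values: Tuple[float, ...]
    hardware_scalars: Tuple[Tuple[float, float], ...] = (
        (0.0, 1.0),) * 6

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        if len(vals) != 6:
            raise ValidationError(
                f"HPLC sequence has exactly 6 parameters, got {len(vals)}"
            )
        if any(v < 0 or v > 1 for v in vals):
            raise ValidationError("HPLC parameters must lie in [0, 1]")
        object.__setattr__(self, "values", vals)


def _saturating(x: float) -> float:
    return (1.0 - math.exp(-_SAT_RATE * x)) / _SAT_NORM


def hplc_true_area(p: HPLCParams) -> float:
    """Noiseless ground-truth peak area for a parameter point."""
    v1, v2, t1, t2, r1, r2 = p.values
    draw = _saturating(v1)                      # zero sample drawn -> zero
    push = 0.3 + 0.7 * _saturating(v2)
    windows = math.exp(-((t1 - _HPLC_WINDOW_CENTERS[0])
                         / _HPLC_WINDOW_WIDTH) ** 2)
    windows *= math.exp(-((t2 - _HPLC_WINDOW_CENTERS[1])
                          / _HPLC_WINDOW_WIDTH) ** 2)
    rates = 1.0 - 0.15 * ((2 * r1 - 1) ** 4 + (2 * r2 - 1) ** 4)
    return HPLC_AREA_MAX * draw * push * windows * rates


def simulate_hplc(p: HPLCParams, noise_sd: float = 0.0,
                  rng: Optional[np.random.Generator] = None) -> float:
    """Peak area with multiplicative log-normal noise of scale ``noise_sd``."""
    area = hplc_true_area(p)
    if noise_sd > 0.0 and area > 0.0:
        rng = rng or np.random.default_rng()
        area *= float(np.exp(rng.normal(0.0, noise_sd)))
    return area


# Star-rating quantization: similarity s = 1 - L1/2 in [0, 1] is binned at
# edges 0.2, 0.4, 0.6, 0.8 onto {1..5}.
def simulate_rating(recipe: MixtureRecipe, hidden_pref: Sequence[float],
                    rng: Optional[np.random.Generator] = None,
                    rater_noise: float = 0.0) -> int:
    pref = np.asarray(hidden_pref, dtype=float)
    if np.any(pref < 0) or abs(pref.sum() - 1.0) > _SIMPLEX_TOL:
        raise ValidationError("hidden_pref must be a simplex vector")
    fractions = recipe.fraction_array()
    if len(fractions) != len(pref):
        raise ValidationError("recipe and preference lengths disagree")
    similarity = 1.0 - float(np.abs(fractions - pref).sum()) / 2.0
    stars = min(5, 1 + int(similarity * 5.0))
    if rater_noise > 0.0:
        rng = rng or np.random.default_rng()
        if rng.uniform() < rater_noise:
            stars += int(rng.choice([-1, 1]))
    return int(np.clip(stars, 1, 5))


# -- instruments -------------------------------------------------------------


class Instrument:
    """Executes an abstract proposal and returns raw measurements."""

    #: the abstract space this instrument expects proposals from
    space: ParameterSpace

    def measure(self, params: Sequence[float],
                rng: np.random.Generator) -> Dict[str, object]:
        raise NotImplementedError


class MixingInstrument(Instrument):
    """Five-pump liquid handler measured by one of three sensors."""

    def __init__(self, kind: str, stocks: StockLibrary, layout: PumpLayout,
                 total_volume: float = 10.0, noise_sd: float = 0.0,
                 ph_model: str = "buffered_linear"):
        if kind not in ("color", "ph", "density"):
            raise ConfigurationError(f"unknown mixing sensor {kind!r}")
        if ph_model not in PH_MODELS:
            raise ConfigurationError(f"unknown pH model {ph_model!r}")
        self.kind = kind
        self.stocks = stocks
        self.layout = layout
        self.total_volume = float(total_volume)
        self.noise_sd = float(noise_sd)
        self.ph_model = ph_model
        self.space = ParameterSpace(
            n_dims=stocks.n_stocks,
            dim_names=tuple(stocks.labels),
        )

    def measure(self, params, rng):
        fractions = normalize_to_fractions(params)
        recipe = MixtureRecipe(tuple(fractions), self.total_volume)
        volumes = map_to_hardware(recipe, self.layout)
        raw: Dict[str, object] = {
            "fractions": list(np.round(fractions, 12)),
            "pump_volumes_ml": list(np.round(volumes, 12)),
        }
        if self.kind == "color":
            rgb = simulate_color(recipe, self.stocks, self.noise_sd, rng)
            raw["rgb"] = list(np.round(rgb, 12))
        elif self.kind == "ph":
            raw["ph"] = simulate_ph(recipe, self.stocks, self.ph_model,
                                    self.noise_sd, rng)
        else:
            raw["density"] = simulate_density(recipe, self.stocks,
                                              self.noise_sd, rng)
        return raw


class DrinkInstrument(Instrument):
    """Bob: mixes a five-ingredient drink and collects a simulated rating."""

    def __init__(self, stocks: StockLibrary, layout: PumpLayout,
                 hidden_pref: Sequence[float],
                 total_volume: float = 10.0, rater_noise: float = 0.0):
        self.stocks = stocks
        self.layout = layout
        self.hidden_pref = tuple(float(v) for v in hidden_pref)
        self.total_volume = float(total_volume)
        self.rater_noise = float(rater_noise)
        self.space = ParameterSpace(n_dims=len(self.hidden_pref))

    def measure(self, params, rng):
        fractions = normalize_to_fractions(params)
        recipe = MixtureRecipe(tuple(fractions), self.total_volume)
        volumes = map_to_hardware(recipe, self.layout)
        stars = simulate_rating(recipe, self.hidden_pref, rng,
                                self.rater_noise)
        return {
            "fractions": list(np.round(fractions, 12)),
            "pump_volumes_ml": list(np.round(volumes, 12)),
            "stars": stars,
        }


class HplcInstrument(Instrument):
    """Six-parameter sampling sequence scored by chromatogram peak area."""

    def __init__(self, noise_sd: float = 0.0):
        self.noise_sd = float(noise_sd)
        self.space = ParameterSpace(
            n_dims=6,
            dim_names=("draw_volume", "push_volume", "wait_pre",
                       "wait_post", "draw_rate", "push_rate"),
        )

    def measure(self, params, rng):
        p = HPLCParams(tuple(self.space.validate(params)))
        return {"peak_area": simulate_hplc(p, self.noise_sd, rng)}


def build_instrument(config: SessionConfig) -> Instrument:
    """Instantiate the instrument a session configuration binds to."""
    binding = config.instrument
    if config.procedure == "hplc":
        return HplcInstrument(noise_sd=binding.noise_sd)

    stocks = (default_stocks() if binding.stocks == "builtin"
              else StockLibrary.from_csv(binding.stocks))
    layout = PumpLayout(
        stock_to_pump=tuple(binding.pump_layout),
        calibration=tuple(binding.calibration),
    )
    if config.procedure == "drink":
        pref = binding.hidden_pref or (0.45, 0.1, 0.3, 0.1, 0.05)
        return DrinkInstrument(stocks, layout, pref,
                               total_volume=binding.total_volume,
                               rater_noise=binding.rater_noise)
    if config.procedure in ("color", "ph", "density"):
        return MixingInstrument(config.procedure, stocks, layout,
                                total_volume=binding.total_volume,
                                noise_sd=binding.noise_sd,
                                ph_model=binding.ph_model)
    raise ConfigurationError(
        f"no instrument available for procedure {config.procedure!r}"
    )
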