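"""Probabilistic surrogate of a response surface for planner benchmarking.

The surrogate contract is a probabilistic regressor: for any point in the
unit hypercube it returns a predictive mean and a non-negative uncertainty.
The implementation is a Gaussian-process regressor (anisotropy-free RBF
plus a small white-noise term); the contract, not the architecture, is what
the benchmarking methodology depends on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .errors import InsufficientDataError, StateError, ValidationError

MIN_TRAINING_POINTS = 10


@dataclass
class SurrogateModel:
    """Trained probabilistic emulator of a logged response surface."""

    n_dims: int
    n_train: int = 0
    holdout_rmse: float = float("nan")
    holdout_r2: float = float("nan")
    trained: bool = False
    _gp: Optional[GaussianProcessRegressor] = field(default=None, repr=False)

    def predict(self, x) -> Tuple[float, float]:
        """Predictive ``(mean, uncertainty)`` at one point in ``[0, 1]^d``."""
        if not self.trained:
            raise StateError("surrogate must be fitted before predicting")
        arr = np.asarray(x, dtype=float)
        if arr.shape != (self.n_dims,):
            raise ValidationError(
                f"expected {self.n_dims} parameters, got shape {arr.shape}"
            )
        if np.any(arr < 0.0) or np.any(arr > 1.0):
            raise ValidationError(f"point outside [0, 1]^d: {arr.tolist()}")
        mean, std = self._gp.predict(arr[None, :], return_std=True)
        return float(mean[0]), float(max(std[0], 0.0))

    def predict_batch(self, X) -> Tuple[np.ndarray, np.ndarray]:
        if not self.trained:
            raise StateError("surrogate must be fitted before predicting")
        X = np.asarray(X, dtype=float)
        mean, std = self._gp.predict(X, return_std=True)
        return mean, np.maximum(std, 0.0)


def fit_surrogate(X, y, seed: int = 0,
                  holdout_fraction: float = 0.2) -> SurrogateModel:
    """Fit a surrogate on logged ``(parameters, response)`` data.

    A deterministic tail split of the shuffled data provides the held-out
    fit metric recorded on the model; the final regressor is re-fitted on
    all points.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValidationError(f"X must be 2-D, got shape {X.shape}")
    if len(X) != len(y):
        raise ValidationError(
            f"X has {len(X)} rows but y has {len(y)} values"
        )
    if len(X) < MIN_TRAINING_POINTS:
        raise InsufficientDataError(
            f"need at least {MIN_TRAINING_POINTS} points, got {len(X)}"
        )
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValidationError("training data must be finite (no missing values)")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(X))
    n_hold = max(2, int(round(holdout_fraction * len(X))))
    hold, train = perm[:n_hold], perm[n_hold:]

    def _make_gp():
        kernel = (ConstantKernel(1.0, (1e-3, 1e3))
                  * RBF(0.3, (1e-2, 1e1))
                  + WhiteKernel(1e-6, (1e-10, 1e-1)))
        return GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=int(seed),
            n_restarts_optimizer=1,
        )

    gp = _make_gp()
    gp.fit(X[train], y[train])
    pred = gp.predict(X[hold])
    resid = pred - y[hold]
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    var = float(np.var(y[hold]))
    r2 = 1.0 - float(np.mean(resid ** 2)) / var if var > 0 else 1.0

    final = _make_gp()
    final.fit(X, y)
    return SurrogateModel(
        n_dims=X.shape[1], n_train=len(X),
        holdout_rmse=rmse, holdout_r2=r2,
        trained=True, _gp=final,
    )


def predict(model: SurrogateModel, x) -> Tuple[float, float]:
    """Functional alias for :meth:`SurrogateModel.predict`."""
    return model.predict(x)


# -- CSV round trip for logged training data ---------------------------------

def training_data_to_csv(X, y, path: str | Path) -> None:
    X = np.asarray(X, dtype=float)
    frame = pd.DataFrame(
        X, columns=[f"p{i + 1}" for i in range(X.shape[1])])
    frame["response"] = np.asarray(y, dtype=float)
    frame.to_csv(path, index=False)


def training_data_from_csv(path: str | Path) -> Tuple[np.ndarray, np.ndarray]:
    frame = pd.read_csv(path)
    if "response" not in frame.columns:
        raise ValidationError("training CSV must have a 'response' column")
    cols = [c for c in frame.columns if c != "response"]
    return frame[cols].to_numpy(float), frame["response"].to_numpy(float)
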