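import numpy as np
import pytest

from autolab.config import load_config
from autolab.records import History, Observation, ProposalRequest
from autolab.space import ParameterSpace
from autolab.virtual_lab import StockLibrary, default_stocks


@pytest.fixture(scope="session")
def stocks() -> StockLibrary:
    return default_stocks()


@pytest.fixture
def space5() -> ParameterSpace:
    return ParameterSpace(n_dims=5)


@pytest.fixture
def space2() -> ParameterSpace:
    return ParameterSpace(n_dims=2)


def make_history(space, points, objectives, modes=None, session_id="t"):
    """Build a history from raw arrays (test helper)."""
    history = History(space, session_id=session_id)
    modes = modes or ["none"] * len(points)
    for i, (x, f, m) in enumerate(zip(points, objectives, modes)):
        request = ProposalRequest(
            request_id=f"{session_id}-r{i:04d}", session_id=session_id,
            params=tuple(np.asarray(x, dtype=float)), mode=m, created_at=i,
        )
        history.record(request, Observation(
            request_id=request.request_id, objective=float(f), measured_at=i))
    return history


@pytest.fixture
def history_factory():
    return make_history


def config_text(procedure="density", planner="bayesian", budget=25,
                target="1.0", seed=1, extra=""):
    target_line = f"target: {target}" if target != "null" else "target: null"
    return (
        f"procedure: {procedure}\n"
        f"planner: {planner}\n"
        f"budget: {budget}\n"
        f"{target_line}\n"
        f"seed: {seed}\n"
        f"{extra}"
    )


@pytest.fixture
def density_config():
    return load_config(config_text())


@pytest.fixture
def ph_config():
    return load_config(config_text(procedure="ph", target="7.0"))
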