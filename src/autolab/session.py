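"""The central workflow manager.

``run_session`` wires together the configured planner, instrument and
characterization stage and drives the closed loop:

    propose -> enqueue -> dequeue -> execute -> characterize -> record

A failed experiment (e.g. a degenerate recipe the liquid handler cannot
dispense) is logged and skipped without consuming budget; only successful
experiments count toward ``config.budget``. The loop is a pure function of
``(config, seed)``: planner and instrument noise draw from independent
streams spawned from the session seed.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np

from .characterization import make_objective, make_target
from .config import SessionConfig
from .errors import InstrumentError, PreconditionError
from .planners import PlannerState, make_planner
from .records import (History, Observation, ProposalRequest, Report,
                      record_observation, status_report)
from .store import SessionStore
from .virtual_lab import Instrument, build_instrument

logger = logging.getLogger("autolab.session")

#: hard cap on attempts, as a multiple of the budget, to guarantee termination
MAX_ATTEMPT_FACTOR = 10


def run_session(config: SessionConfig,
                store: Optional[SessionStore] = None,
                instrument: Optional[Instrument] = None,
                planner_state: Optional[PlannerState] = None) -> History:
    """Run one closed-loop session and return its history.

    Parameters
    ----------
    config :
        Validated session configuration.
    store :
        Optional persistent store; an in-memory store is used by default.
    instrument :
        Override the instrument binding (used for benchmarking on
        surrogate surfaces).
    planner_state :
        Override the default planner knobs.
    """
    own_store = store is None
    store = store or SessionStore()
    instrument = instrument or build_instrument(config)
    space = instrument.space
    target = make_target(config.procedure, config.target)
    objective_fn = make_objective(config.procedure, target)
    planner = make_planner(config.planner, config.budget, planner_state)

    seeds = np.random.SeedSequence(config.seed).spawn(2)
    planner_rng = np.random.default_rng(seeds[0])
    instrument_rng = np.random.default_rng(seeds[1])

    history = History(space, target=target, session_id=config.session_id)
    clock = 0
    attempts = 0
    consecutive_failures = 0
    max_attempts = MAX_ATTEMPT_FACTOR * config.budget

    try:
        while len(history) < config.budget:
            if attempts >= max_attempts:
                raise PreconditionError(
                    f"session {config.session_id}: exceeded "
                    f"{max_attempts} attempts for budget {config.budget}"
                )
            iteration = len(history)
            if consecutive_failures >= 3:
                # repeated instrument failures (e.g. proposals pinned at a
                # degenerate corner): recover with an uninformed draw
                params, mode = planner_rng.uniform(size=space.n_dims), "none"
            else:
                params, mode = planner.propose(space, history, iteration,
                                               planner_rng)
            params = space.validate(np.asarray(params, dtype=float))
            request = ProposalRequest(
                request_id=f"{config.session_id}-r{attempts:04d}",
                session_id=config.session_id,
                params=tuple(params),
                mode=mode,
                created_at=clock,
            )
            clock += 1
            attempts += 1
            store.queue_put(request)
            pending = store.queue_next(config.session_id)
            logger.info("session=%s request=%s mode=%s proposed",
                        config.session_id, request.request_id, mode)
            try:
                raw = instrument.measure(pending.params, instrument_rng)
            except InstrumentError as exc:
                consecutive_failures += 1
                logger.warning(
                    "session=%s request=%s failed: %s",
                    config.session_id, pending.request_id, exc)
                continue
            consecutive_failures = 0
            objective = objective_fn(raw)
            obs = Observation(
                request_id=pending.request_id,
                objective=objective,
                raw=raw,
                measured_at=clock,
            )
            clock += 1
            store.put_observation(config.session_id, obs)
            record_observation(history, pending, obs)
            logger.info(
                "session=%s request=%s objective=%.6g best=%.6g",
                config.session_id, pending.request_id, objective,
                history.best()[1].objective)
    finally:
        if own_store:
            store.close()
    return history


def session_report(config: SessionConfig, store: SessionStore) -> Report:
    """Status report for a stored session."""
    instrument = build_instrument(config)
    history = store.load_history(config.session_id, instrument.space)
    return status_report(history)
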