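"""SQLite-backed FIFO stores for requests and observations.

Requests and observations live in two distinct tables so that, as in a
multi-process deployment, readers and writers never contend on the same
table. Both tables are append-only with unique request ids; processing
order is strictly first-in-first-out.

A CSV mirror of both tables can be exported at any time for ad-hoc
analysis outside the database.
"""

from __future__ import annotations

import json
import sqlite3
from pathlib import Path
from typing import Iterable, List, Optional

from .errors import IntegrityError, ValidationError
from .records import History, Observation, ProposalRequest
from .space import ParameterSpace

_SCHEMA = """
CREATE TABLE IF NOT EXISTS requests (
    request_id  TEXT PRIMARY KEY,
    session_id  TEXT NOT NULL,
    params      TEXT NOT NULL,
    mode        TEXT NOT NULL,
    created_at  INTEGER NOT NULL,
    processed   INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE IF NOT EXISTS observations (
    request_id  TEXT PRIMARY KEY,
    session_id  TEXT NOT NULL,
    objective   REAL NOT NULL,
    raw         TEXT NOT NULL,
    measured_at INTEGER NOT NULL
);
"""

REQUEST_COLUMNS = ("request_id", "session_id", "params", "mode",
                   "created_at", "processed")
OBSERVATION_COLUMNS = ("request_id", "session_id", "objective", "raw",
                       "measured_at")


class SessionStore:
    """Request queue and observation log sharing one SQLite database.

    Parameters
    ----------
    path :
        Database file path, or ``":memory:"`` (the default) for an
        ephemeral store.
    """

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "SessionStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- request queue (FIFO) ------------------------------------------------

    def queue_put(self, item: ProposalRequest) -> str:
        """Persist a request; returns its id as acknowledgment."""
        try:
            self._conn.execute(
                "INSERT INTO requests (request_id, session_id, params, mode,"
                " created_at) VALUES (?, ?, ?, ?, ?)",
                (item.request_id, item.session_id,
                 json.dumps(list(item.params)), item.mode, item.created_at),
            )
        except sqlite3.IntegrityError:
            raise IntegrityError(
                f"duplicate request_id {item.request_id!r}"
            ) from None
        self._conn.commit()
        return item.request_id

    def queue_next(self, session_id: Optional[str] = None
                   ) -> Optional[ProposalRequest]:
        """Pop the oldest unprocessed request, or ``None`` if none pending."""
        query = ("SELECT request_id, session_id, params, mode, created_at"
                 " FROM requests WHERE processed = 0")
        args: tuple = ()
        if session_id is not None:
            query += " AND session_id = ?"
            args = (session_id,)
        query += " ORDER BY created_at ASC, rowid ASC LIMIT 1"
        row = self._conn.execute(query, args).fetchone()
        if row is None:
            return None
        self._conn.execute(
            "UPDATE requests SET processed = 1 WHERE request_id = ?",
            (row[0],),
        )
        self._conn.commit()
        return ProposalRequest(
            request_id=row[0], session_id=row[1],
            params=tuple(json.loads(row[2])), mode=row[3], created_at=row[4],
        )

    def queue_length(self, pending_only: bool = False) -> int:
        query = "SELECT COUNT(*) FROM requests"
        if pending_only:
            query += " WHERE processed = 0"
        return self._conn.execute(query).fetchone()[0]

    # -- observation log -----------------------------------------------------

    def put_observation(self, session_id: str, obs: Observation) -> None:
        row = self._conn.execute(
            "SELECT 1 FROM requests WHERE request_id = ?", (obs.request_id,)
        ).fetchone()
        if row is None:
            raise IntegrityError(
                f"observation references unknown request {obs.request_id!r}"
            )
        try:
            self._conn.execute(
                "INSERT INTO observations (request_id, session_id, objective,"
                " raw, measured_at) VALUES (?, ?, ?, ?, ?)",
                (obs.request_id, session_id, obs.objective,
                 json.dumps(obs.raw), obs.measured_at),
            )
        except sqlite3.IntegrityError:
            raise IntegrityError(
                f"duplicate observation for request {obs.request_id!r}"
            ) from None
        self._conn.commit()

    # -- history persistence -------------------------------------------------

    def save_history(self, history: History) -> None:
        """Write every pair of a history; requests are marked processed."""
        for request, obs in history:
            self.queue_put(request)
            self._conn.execute(
                "UPDATE requests SET processed = 1 WHERE request_id = ?",
                (request.request_id,),
            )
            self.put_observation(history.session_id, obs)
        self._conn.commit()

    def load_history(self, session_id: str, space: ParameterSpace,
                     target=None) -> History:
        """Rebuild a history for one session, in creation order."""
        history = History(space, target=target, session_id=session_id)
        rows = self._conn.execute(
            "SELECT r.request_id, r.params, r.mode, r.created_at,"
            " o.objective, o.raw, o.measured_at"
            " FROM requests r JOIN observations o"
            " ON r.request_id = o.request_id"
            " WHERE r.session_id = ? ORDER BY r.created_at ASC, r.rowid ASC",
            (session_id,),
        ).fetchall()
        for rid, params, mode, created, objective, raw, measured in rows:
            request = ProposalRequest(
                request_id=rid, session_id=session_id,
                params=tuple(json.loads(params)), mode=mode,
                created_at=created,
            )
            obs = Observation(
                request_id=rid, objective=objective,
                raw=json.loads(raw), measured_at=measured,
            )
            history.record(request, obs)
        return history

    def session_ids(self) -> List[str]:
        rows = self._conn.execute(
            "SELECT DISTINCT session_id FROM requests ORDER BY session_id"
        ).fetchall()
        return [r[0] for r in rows]

    # -- CSV mirror ----------------------------------------------------------

    def export_csv(self, directory: str | Path) -> List[Path]:
        """Mirror both tables to ``requests.csv`` / ``observations.csv``."""
        import csv

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for table, columns in (("requests", REQUEST_COLUMNS),
                               ("observations", OBSERVATION_COLUMNS)):
            out = directory / f"{table}.csv"
            rows = self._conn.execute(
                f"SELECT {', '.join(columns)} FROM {table}"
                " ORDER BY rowid ASC"
            ).fetchall()
            with out.open("w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(columns)
                writer.writerows(rows)
            written.append(out)
        return written


def queue_put(store: SessionStore, item: ProposalRequest) -> str:
    return store.queue_put(item)


def queue_next(store: SessionStore,
               session_id: Optional[str] = None) -> Optional[ProposalRequest]:
    return store.queue_next(session_id)
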