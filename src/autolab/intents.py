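"""Deterministic intent parsing and reply rendering.

A small keyword grammar stands in for the original chatbot: messages are
classified as a new experiment request, a status query, star-rating
feedback, or unknown. Parsing is total — any text yields an Intent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Dict, Optional

from .errors import ValidationError
from .records import Report

INTENT_KINDS = ("new_request", "status", "feedback", "unknown")

_STARS_RE = re.compile(r"\b([1-5])\s*(?:stars?|\*)", re.IGNORECASE)
_STATUS_RE = re.compile(r"\bstatus\b(?:.*?\bsession\s+(\S+))?", re.IGNORECASE)
_REQUEST_RE = re.compile(
    r"\b(?:new|request|run|start)\b.*?\b"
    r"(color|ph|density|drink|hplc)\b(?:.*?\btarget\s+([\d.,\s\[\]]+))?",
    re.IGNORECASE | re.DOTALL,
)
_REQUEST_ID_RE = re.compile(r"\b(?:for|request)\s+([\w-]+-r\d+)\b",
                            re.IGNORECASE)

HELP_TEXT = (
    "I did not understand that. Try one of:\n"
    "  status [session <id>]\n"
    "  run <color|ph|density|drink|hplc> [target <value>]\n"
    "  <1-5> stars [for <request id>]"
)


@dataclass(frozen=True)
class Intent:
    kind: str
    payload: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in INTENT_KINDS:
            raise ValidationError(f"unknown intent kind {self.kind!r}")
        if self.kind == "feedback":
            stars = self.payload.get("stars")
            if stars not in (1, 2, 3, 4, 5):
                raise ValidationError(
                    f"feedback stars must be in 1..5, got {stars!r}"
                )


def parse_message(text: str) -> Intent:
    """Classify free text; never raises on any input."""
    text = (text or "").strip()
    if not text:
        return Intent("unknown")

    match = _STARS_RE.search(text)
    if match:
        payload: Dict[str, Any] = {"stars": int(match.group(1))}
        rid = _REQUEST_ID_RE.search(text)
        if rid:
            payload["request_id"] = rid.group(1)
        return Intent("feedback", payload)

    match = _STATUS_RE.search(text)
    if match:
        payload = {}
        if match.group(1):
            payload["session_id"] = match.group(1)
        return Intent("status", payload)

    match = _REQUEST_RE.search(text)
    if match:
        payload = {"procedure": match.group(1).lower()}
        if match.group(2):
            numbers = re.findall(r"[\d.]+", match.group(2))
            values = [float(v) for v in numbers]
            payload["target"] = values[0] if len(values) == 1 else values
        return Intent("new_request", payload)

    return Intent("unknown")


def render_reply(intent: Intent, result: Optional[Any] = None) -> str:
    """Human-readable reply for an intent and its handler result."""
    if intent.kind == "status":
        if not isinstance(result, Report):
            raise ValidationError("status intent requires a Report result")
        if result.n_completed == 0:
            return (f"Session {result.session_id or '(unnamed)'}: "
                    "no completed experiments yet.")
        return (
            f"Session {result.session_id}: {result.n_completed} experiments "
            f"completed; best objective {result.best_objective:g} "
            f"(request {result.best_request.request_id})."
        )
    if intent.kind == "feedback":
        stars = intent.payload["stars"]
        rid = intent.payload.get("request_id")
        suffix = f" for request {rid}" if rid else ""
        return f"Thanks! Recorded {stars} star(s){suffix}."
    if intent.kind == "new_request":
        procedure = intent.payload["procedure"]
        target = intent.payload.get("target")
        suffix = f" with target {target}" if target is not None else ""
        return f"Queued a new {procedure} procedure{suffix}."
    return HELP_TEXT
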