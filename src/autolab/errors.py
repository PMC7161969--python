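"""Exception hierarchy for autolab.

Everything raised on purpose by the package derives from :class:`AutolabError`
so callers can catch a single base class at the CLI boundary.
"""


class AutolabError(Exception):
    """Base class for all autolab errors."""


class ConfigurationError(AutolabError):
    """Malformed or semantically invalid session configuration."""


class ValidationError(AutolabError):
    """An input value violates a documented contract."""


class IntegrityError(AutolabError):
    """A store operation would violate uniqueness or ordering guarantees."""


class PreconditionError(AutolabError):
    """An operation was called with an unsatisfied precondition."""


class StateError(AutolabError):
    """An object was used before it reached the required state."""


class InsufficientDataError(AutolabError):
    """Not enough data points to perform the requested fit."""


class GridSizeError(AutolabError):
    """A factorial grid would exceed the configured size cap."""

    def __init__(self, n_points: int, cap: int):
        self.n_points = n_points
        self.cap = cap
        super().__init__(
            f"factorial grid of {n_points} points exceeds the cap of {cap}"
        )


class InstrumentError(AutolabError):
    """A (virtual) instrument failed to execute a proposal."""


class DegenerateRecipeError(InstrumentError):
    """The proposal maps to an all-zero recipe; nothing can be dispensed."""


class MappingError(AutolabError):
    """The pump layout does not cover every non-zero stock fraction."""
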