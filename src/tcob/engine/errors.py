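"""Exception hierarchy for the temporal-constrained-objects engine."""

from __future__ import annotations


class CobError(Exception):
    """Base class for all engine errors."""


class CobDefinitionError(CobError):
    """A class definition is malformed (duplicate attribute, unknown symbol,
    future reference deeper than one tick, ...)."""


class CobParameterError(CobError, ValueError):
    """An operation received an invalid parameter value."""


class CobInconsistencyError(CobError):
    """The constraint system has no solution at some tick."""

    def __init__(self, message: str, tick: int | None = None,
                 constraints: tuple[str, ...] = ()) -> None:
        super().__init__(message)
        self.tick = tick
        self.constraints = constraints


class CobUnderdeterminedError(CobError):
    """Unknowns remain that no constraint can determine."""

    def __init__(self, message: str, tick: int | None = None,
                 unknowns: tuple[str, ...] = ()) -> None:
        super().__init__(message)
        self.tick = tick
        self.unknowns = unknowns


class CobConvergenceError(CobError):
    """The iterative solver failed to converge."""

    def __init__(self, message: str, iterations: int = 0) -> None:
        super().__init__(message)
        self.iterations = iterations


class CobDivergenceError(CobError):
    """A numeric simulation produced a non-finite value."""

    def __init__(self, message: str, tick: int | None = None) -> None:
        super().__init__(message)
        self.tick = tick


class CobIOError(CobError):
    """A reader or writer failed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None) -> None:
        super().__init__(message)
        self.line = line
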