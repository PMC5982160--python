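"""Exception hierarchy.

Every error raised by the library derives from :class:`BodyAnglesError` so
callers can catch the whole family with one clause.
"""

from __future__ import annotations


class BodyAnglesError(Exception):
    """Base class for all library errors."""


class SequenceParseError(BodyAnglesError):
    """Malformed sequence file; carries the offending line number when known."""

    def __init__(self, message: str, *, line: int | None = None, path: str | None = None):
        self.line = line
        self.path = path
        where = ""
        if path is not None:
            where += f" in {path}"
        if line is not None:
            where += f" at line {line}"
        super().__init__(message + where)


class UnknownJointError(SequenceParseError):
    """A joint name outside the 20-joint enumeration."""


class ValidationError(BodyAnglesError):
    """A frame or sequence violates a structural invariant."""


class DegenerateBoneError(BodyAnglesError):
    """Bone endpoints coincide; its direction is undefined."""


class ConfigurationError(BodyAnglesError):
    """Invalid configuration (e.g. empty relevant-bone set)."""


class SpeedMismatchError(BodyAnglesError):
    """Observation window duration outside the tolerance around the template's."""


class InsufficientDataError(BodyAnglesError):
    """Calibration requires non-empty positive and negative score samples."""


class UnreliableLimitError(BodyAnglesError):
    """Degenerate calibration interval: no limit can separate the samples.

    Carries the interval so a caller can inspect it and choose manually.
    """

    def __init__(self, message: str, interval=None):
        self.interval = interval
        super().__init__(message)


class NoSharedLimitError(BodyAnglesError):
    """Shared-limit calibration failed: the per-activity intervals are disjoint."""


class NoPredictionError(BodyAnglesError):
    """No template could be scored for the observation."""
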