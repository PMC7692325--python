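"""Exception hierarchy.

``InputError`` maps to CLI exit code 2, ``ValidationError`` (and subclasses)
to exit code 3; everything derives from ``NotchScoreError`` so callers can
catch package failures in one clause.
"""


class NotchScoreError(Exception):
    """Base class for all package errors."""


class InputError(NotchScoreError):
    """Unreadable, missing or structurally broken input (CLI exit 2)."""


class ParseError(InputError):
    """Malformed table or config file."""


class ValidationError(NotchScoreError):
    """A domain invariant is violated (CLI exit 3)."""


class PanelLookupError(ValidationError, KeyError):
    """Gene or probeset not present in the panel / mapping."""


class CalibrationError(ValidationError):
    """Calibration preconditions not met (e.g. an empty class)."""


class FrozenModelError(ValidationError):
    """Attempt to mutate or recalibrate a frozen model."""


class ScoringError(ValidationError):
    """A sample cannot be scored (e.g. all evidence missing)."""
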