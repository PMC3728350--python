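"""Exception types shared across the package."""


class CircabehaveError(Exception):
    """Base class for all package errors."""


class ValidationError(CircabehaveError):
    """Input data violate a documented invariant (negative counts, bad fractions...)."""


class ParseError(CircabehaveError):
    """A text file could not be parsed; the message names the offending line."""


class InsufficientDataError(CircabehaveError):
    """The record is too short, or too few onsets/days survive filtering."""


class GatingError(CircabehaveError):
    """A post-hoc test was requested without a significant omnibus test."""
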