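"""Exception hierarchy shared across the package.

Hard analytical failures (bad panel, broken internal standard, responses
outside the quantifiable region) are distinct classes so a pipeline can
surface the offending sample instead of silently dropping it.
"""


class ToxiquantError(Exception):
    """Base class for all package errors."""


class PanelError(ToxiquantError):
    """Invalid analyte panel configuration."""


class InsufficientCalibrationError(ToxiquantError):
    """Fewer than the minimum number of distinct calibration levels."""


class OutOfRangeError(ToxiquantError):
    """Response cannot be mapped to a concentration on the calibrated branch."""

    def __init__(self, message: str, response: float | None = None):
        super().__init__(message)
        self.response = response


class InternalStandardError(ToxiquantError):
    """Internal standard signal missing or zero; the sample must be rejected."""


class MalformedSampleError(ToxiquantError):
    """Sample record set is incomplete (e.g. no quantifier transition)."""


class InsufficientDataError(ToxiquantError):
    """Not enough usable observations for the requested estimate."""


class InvalidInputError(ToxiquantError):
    """A numeric input violates a precondition (e.g. non-positive noise)."""


class ParseError(ToxiquantError):
    """A data file failed validation; carries row context when available."""
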