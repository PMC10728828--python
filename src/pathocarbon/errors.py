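"""Exception hierarchy.

Every error raised by the library derives from :class:`PathocarbonError`
so callers (and the CLI) can distinguish library failures from bugs.
"""


class PathocarbonError(Exception):
    """Base class for all pathocarbon errors."""


class ConfigurationError(PathocarbonError):
    """A config value or distribution spec is invalid; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class CohortValidationError(PathocarbonError):
    """A cohort table violates a structural invariant."""


class EmptyCohortError(PathocarbonError):
    """An operation that needs slides received an empty cohort."""


class MalformedTraceError(PathocarbonError):
    """A power trace is unusable (non-monotone times, too few samples)."""


class CalibrationError(PathocarbonError):
    """A model calibration table cannot support the requested operation."""


class DegenerateDesignError(CalibrationError):
    """Regression design matrix has no variation (all parameter counts equal)."""


class ExtrapolationRefusedError(PathocarbonError):
    """A value outside the supported range of a calibrated curve was requested."""


class DriverSpecError(PathocarbonError):
    """A projection driver is under- or mis-specified."""


class GridMismatchError(PathocarbonError):
    """Projection drivers are not on a common year grid."""
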