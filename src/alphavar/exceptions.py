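"""Exception types shared across the package."""


class AlphavarError(Exception):
    """Base class for package-specific errors."""


class InvalidArgumentError(AlphavarError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(AlphavarError):
    """Fewer clean epochs (or subjects) are available than requested."""


class UndefinedCVError(AlphavarError):
    """Coefficient of variation is undefined (zero mean power) at some cell."""


class CalibrationError(AlphavarError):
    """A requested CV target lies outside the calibratable range."""


class ConvergenceError(AlphavarError):
    """A statistical model fit failed to converge or was singular."""


class IncompleteReportError(AlphavarError):
    """A run report is missing required results and cannot be written."""
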