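"""Exception hierarchy shared across the package."""


class LaurdanGPError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(LaurdanGPError, ValueError):
    """A configuration object violates one of its invariants."""


class InvalidParameterError(LaurdanGPError, ValueError):
    """An operation argument is outside its documented domain."""


class FormatError(LaurdanGPError, ValueError):
    """A file on disk does not satisfy the format contract."""


class ValidationError(LaurdanGPError, ValueError):
    """Parsed data violates a type invariant (e.g. negative intensity)."""


class BandCoverageError(LaurdanGPError, ValueError):
    """A spectrum has no samples inside a requested wavelength band."""


class UndefinedGPError(LaurdanGPError, ArithmeticError):
    """GP is undefined because both band intensities are zero."""


class EmptyDataError(LaurdanGPError, ValueError):
    """An operation received no usable data points."""


class EmptyRegionError(LaurdanGPError, ValueError):
    """A region mask overlaps no valid pixels."""


class FitFailureError(LaurdanGPError, RuntimeError):
    """All restarts of an iterative fit failed to converge."""


class RenderError(LaurdanGPError, ValueError):
    """A map cannot be rendered (e.g. no valid pixels for a data-driven LUT)."""
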