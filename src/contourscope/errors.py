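"""Exception types shared across the package."""


class ContourScopeError(Exception):
    """Base class for package-specific errors."""


class InvalidArgumentError(ContourScopeError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateDesignError(ContourScopeError):
    """A PSF design yielded no usable structure (for example, zero edge pixels)."""


class SamplingError(ContourScopeError):
    """A propagation distance / grid combination cannot be sampled faithfully."""


class DegenerateCalibrationError(ContourScopeError):
    """Calibration frames contain no signal after background subtraction."""


class DivisionGuardError(ContourScopeError):
    """An unregularized deconvolution hit a zero in the PSF spectrum."""


class UnboundedProfileError(ContourScopeError):
    """An intensity profile never falls below half of its maximum."""
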