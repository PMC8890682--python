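"""Exception hierarchy used across the package."""


class CircakitError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(CircakitError, ValueError):
    """A precondition on an argument was violated."""


class OutOfRangeError(CircakitError, ValueError):
    """A time point falls outside the span of a schedule or recording."""


class DegenerateInputError(CircakitError, ValueError):
    """Input carries no usable signal (e.g. zero-variance series)."""


class SingularFitError(CircakitError, ValueError):
    """The regression design matrix is rank deficient."""
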