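"""Exception hierarchy shared across the package."""


class HolofociError(Exception):
    """Base class for all holofoci errors."""


class InvalidParameterError(HolofociError, ValueError):
    """A parameter is outside its valid domain."""


class EmptyInputError(HolofociError, ValueError):
    """An operation received an empty collection where at least one item is required."""


class DegenerateFieldError(HolofociError, ValueError):
    """A complex field is identically zero and has no defined phase."""


class OutOfBoundsError(HolofociError, ValueError):
    """A position falls outside the bounds of a volume or grid."""


class NotMeasurableError(HolofociError, ValueError):
    """A profile does not admit the requested measurement (e.g. no half-maximum crossing)."""


class FitFailureError(HolofociError, ValueError):
    """A least-squares fit has a degenerate or non-identifiable input."""


class SchemaError(HolofociError, ValueError):
    """An input file does not match the expected schema."""
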