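"""Exception hierarchy shared across the pipeline."""


class PupilverseError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PupilverseError, ValueError):
    """An invalid configuration value (rates outside [0, 1], bad bounds, ...)."""


class SchemaError(PupilverseError, ValueError):
    """A table does not match the documented column schema."""


class IntegrityError(PupilverseError, ValueError):
    """A table violates a structural invariant (e.g. duplicate sample keys)."""


class StateError(PupilverseError, RuntimeError):
    """An operation was called before its inputs were complete."""


class BasisError(PupilverseError, ValueError):
    """A spline basis cannot be constructed (degenerate time range, too few knots)."""


class SpecificationError(PupilverseError, ValueError):
    """A model specification is incompatible with the data or the request."""


class FitError(PupilverseError, RuntimeError):
    """A model fit failed (singular design, degenerate dataset)."""
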