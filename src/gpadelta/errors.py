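"""Exception hierarchy shared across the package."""


class GpadeltaError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(GpadeltaError, ValueError):
    """A configuration violates one of its documented invariants."""


class ValidationError(GpadeltaError, ValueError):
    """Input data fail a documented precondition (e.g. not standardized)."""


class DegenerateScaleError(GpadeltaError, ValueError):
    """An operation requires nonzero dispersion but the input is constant."""


class EmptyInputError(GpadeltaError, ValueError):
    """No usable (non-missing) observations remain."""


class InsufficientDataError(GpadeltaError, ValueError):
    """Fewer observations than the operation's stated minimum."""


class CollinearityError(GpadeltaError, ValueError):
    """The design matrix is rank deficient."""


class ConvergenceError(GpadeltaError, RuntimeError):
    """An iterative fit failed to converge; carries diagnostics in args."""
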