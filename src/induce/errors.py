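"""Exception hierarchy shared across the package."""


class InduceError(Exception):
    """Base class for all package-specific errors."""


class InputError(InduceError, ValueError):
    """Invalid user-supplied argument (shape, sign, range)."""


class StabilityError(InduceError, ValueError):
    """Connectivity matrix is not Hurwitz-stable; no stationary state exists."""


class NumericalError(InduceError, ArithmeticError):
    """A numerical operation failed (singular matrix, non-convergence)."""


class FitError(InduceError, RuntimeError):
    """A model fit did not converge or is degenerate."""


class InsufficientDataError(InduceError, ValueError):
    """Too few cells or doses for the requested estimate."""


class ParseError(InduceError, ValueError):
    """Malformed dataset or configuration file."""
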