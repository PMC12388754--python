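"""Exception hierarchy."""


class FoulfitError(Exception):
    """Base class for all package errors."""


class ValidationError(FoulfitError, ValueError):
    """Invalid input data or parameters."""


class FittingError(FoulfitError, RuntimeError):
    """A linearized regression could not be performed (degenerate data)."""


class SolverError(FoulfitError, RuntimeError):
    """Numerical integration of a blocking-law ODE failed."""
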