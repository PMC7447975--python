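"""Exception hierarchy shared across the pipeline stages."""


class CycleSafeError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(CycleSafeError, ValueError):
    """A precondition on an argument was violated."""


class SchemaError(CycleSafeError, ValueError):
    """An input table is missing required columns or has misaligned keys."""


class NoPathError(CycleSafeError):
    """The road network has no path between the requested endpoints."""


class CoverageError(CycleSafeError):
    """A path leaves the zone cover; carries the orphan length in km."""

    def __init__(self, message: str, orphan_km: float = 0.0):
        super().__init__(message)
        self.orphan_km = orphan_km


class InsufficientDataError(CycleSafeError, ValueError):
    """Not enough observations to perform the requested computation."""


class ConvergenceError(CycleSafeError, RuntimeError):
    """An iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace or []
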