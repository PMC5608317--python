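"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
NumericalError (and subclasses) -> 4.
"""


class GrassVladError(Exception):
    """Base class for all package errors."""


class ConfigError(GrassVladError):
    """Invalid configuration (bad strategy name, k > n, infeasible split...)."""


class DataError(GrassVladError):
    """Bad input data: missing file, malformed manifest, image too small."""


class DimensionError(DataError):
    """Shape mismatch between arrays that must conform."""


class NumericalError(GrassVladError):
    """Numerical failure in an algorithm."""


class DegeneratePatchError(NumericalError):
    """Patch has (numerically) no variance; no identifiable dynamics."""


class RankDeficiencyError(NumericalError):
    """Observability matrix is rank deficient; system unobservable at this horizon."""


class CutLocusError(NumericalError):
    """Subspace pair at a principal angle of pi/2; log map undefined."""


class ConvergenceError(NumericalError):
    """Iterative algorithm failed to converge within max_iter."""

    def __init__(self, message, last_iterate=None, residual=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.residual = residual


class StabilizationError(ConvergenceError):
    """Transition-matrix stabilization failed; carries the last iterate."""
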