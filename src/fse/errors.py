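"""Exception and warning types shared across the package."""


class FseError(Exception):
    """Base class for all package-specific errors."""


class ShapeError(FseError):
    """Array dimensions are inconsistent with the operation."""


class ParseError(FseError):
    """A delimited-text matrix file could not be parsed."""


class SymmetryError(FseError):
    """A matrix required to be symmetric is not (beyond tolerance)."""


class NegativeEntryError(FseError):
    """A nonnegative matrix (structural connectome) contains negative entries."""


class ConstantRegionError(FseError):
    """A region's series has zero variance where variance is required."""


class NonFiniteError(FseError):
    """A numerical quantity overflowed or became NaN despite safeguards."""


class DivergenceError(FseError):
    """Gradient ascent produced a non-finite objective that backtracking
    could not repair."""


class NoInhibitionError(FseError):
    """E/I ratio undefined: the negative-edge denominator is zero."""


class FlatCurveError(FseError):
    """Susceptibility curve is constant; no critical point exists."""


class TooLargeError(FseError):
    """Exact enumeration requested for a system too large to enumerate."""


class DegenerateError(FseError):
    """A correlation-based metric is undefined (constant input vector)."""


class NonConvergenceWarning(RuntimeWarning):
    """Gradient ascent hit the iteration cap before meeting the tolerance.
    The result is still returned, flagged as non-converged."""
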