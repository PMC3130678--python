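"""Package-specific exception types."""


class PeakshiftError(Exception):
    """Base class for all package errors."""


class NewickParseError(PeakshiftError):
    """Malformed Newick input."""


class ShapeMismatchError(PeakshiftError):
    """Landmark configurations with incompatible point counts or roles."""


class DegenerateShapeError(PeakshiftError):
    """All landmarks coincide; size and shape are undefined."""


class CurveDefinitionError(PeakshiftError):
    """A semilandmark lacks the two curve neighbours needed to define a tangent."""


class MissingDataError(PeakshiftError):
    """Tip values absent for one or more species."""


class DegenerateBranchError(PeakshiftError):
    """Zero-length branches make an ancestral estimate undefined."""


class PaintingIncompleteError(PeakshiftError):
    """A branch has no assigned selective regime."""


class CollinearityError(PeakshiftError):
    """Singular design matrix in a GLS fit."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class AlignmentError(PeakshiftError):
    """Species sets of two inputs do not match."""


class UndefinedCurveError(PeakshiftError):
    """Zero total disparity: the relative-disparity curve is undefined."""


class ConvergenceWarning(UserWarning):
    """Optimizer stopped before meeting its tolerance."""
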