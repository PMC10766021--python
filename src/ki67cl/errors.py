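"""Named exceptions raised across the package.

Every failure mode that a caller may want to handle programmatically gets
its own class; generic ValueError is reserved for plain argument misuse.
"""


class Ki67CLError(Exception):
    """Base class for all package errors."""


class CellFileNotFoundError(Ki67CLError, FileNotFoundError):
    """A cell/region/survival file path does not exist."""


class MissingColumnError(Ki67CLError, KeyError):
    """A column required by the dialect mapping is absent from the file."""


class CoordinateParseError(Ki67CLError, ValueError):
    """A coordinate field could not be parsed as a finite non-negative number."""


class UnknownClassLabelError(Ki67CLError, ValueError):
    """A cell class label outside the four-label vocabulary was encountered."""


class EmptyRegionSetError(Ki67CLError, ValueError):
    """Region filtering was requested but no usable region polygons exist."""


class UnscorableSlideError(Ki67CLError, ValueError):
    """A slide has no tumor cells (or no clusters) and cannot be scored."""


class DotOutOfBoundsError(Ki67CLError, ValueError):
    """A dot annotation lies outside the patch/grid it belongs to."""


class NoFeasibleCutoffError(Ki67CLError, ValueError):
    """No cutoff candidate satisfies the minimum group-size constraint."""


class EmptyFoldError(Ki67CLError, ValueError):
    """A cross-validation fold contains no events; use stratified folding."""


class CoxConvergenceError(Ki67CLError, RuntimeError):
    """The Cox partial-likelihood fit failed to converge (e.g. separation)."""
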