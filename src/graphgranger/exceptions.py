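"""Exception hierarchy.

All package errors derive from :class:`GraphGrangerError` so callers (and the
command-line interface) can distinguish validation problems from genuine bugs.
"""


class GraphGrangerError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(GraphGrangerError, ValueError):
    """A parameter is outside its valid range or otherwise unusable."""


class ValidationError(GraphGrangerError, ValueError):
    """An input object violates a structural invariant."""


class ConstructionError(GraphGrangerError):
    """A random-graph construction is infeasible for the requested parameters."""


class InsufficientDataError(GraphGrangerError, ValueError):
    """Too few time points for the requested model order."""


class SingularDesignError(GraphGrangerError):
    """The regression design matrix is (numerically) rank deficient."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        #: indices of offending design columns, when identifiable
        self.columns = list(columns) if columns is not None else []


class FormatError(GraphGrangerError, ValueError):
    """An on-disk file does not conform to the expected format."""
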