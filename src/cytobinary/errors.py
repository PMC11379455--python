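"""Exception hierarchy.

Every error raised by this package derives from :class:`CytoError` so callers
can catch the whole family with one clause; subclasses distinguish bad files,
bad parameters, bad data and bad workflow state.
"""


class CytoError(Exception):
    """Base class for all errors raised by cytobinary."""


class FcsFormatError(CytoError):
    """The file is not a readable FCS 3.0/3.1 file (missing/corrupt header,
    truncated data segment, unsupported mode)."""


class EmptyFcsError(CytoError):
    """An FCS file that declares zero events ($TOT = 0)."""


class ParameterError(CytoError, ValueError):
    """A function argument is outside its documented domain."""


class StateError(CytoError):
    """An operation was called in the wrong workflow state
    (e.g. arcsinh-transforming an already transformed experiment)."""


class DataError(CytoError):
    """Input arrays violate a data contract (NaN/Inf values, length
    mismatches between paired vectors)."""


class MatrixParseError(CytoError):
    """A classification-matrix cell holds a symbol outside {+, -, A}."""


class ValidationError(CytoError):
    """A structurally parsed object fails semantic validation
    (duplicate cell types, all-'A' rows, unmatched metadata)."""


class ConfigurationError(CytoError):
    """The requested analysis cannot run against the given experiment
    (missing markers, missing replicate anchors, missing state markers)."""


class PopulationLookupError(CytoError, KeyError):
    """A requested cell-type label does not exist in the annotation."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)
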