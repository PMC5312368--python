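"""Exception hierarchy shared across the pipeline stages."""


class NmrPathError(Exception):
    """Base class for all package errors."""


class FormatError(NmrPathError):
    """A delimited-text input violates the documented dialect."""


class DesignError(NmrPathError):
    """A simulation design or configuration is internally inconsistent."""


class InsufficientDataError(NmrPathError):
    """Too few samples (or variables) for the requested computation."""


class NormalizationError(NmrPathError):
    """A spectrum cannot be normalized (e.g. an all-zero row)."""


class AssignmentError(NmrPathError):
    """A metabolite assignment window does not intersect the spectral axis."""


class ArgumentError(NmrPathError):
    """An argument is outside its valid range."""


class RankError(NmrPathError):
    """Matrix rank exhausted before the requested number of components."""


class ParseError(NmrPathError):
    """A pathway XML file could not be parsed."""


class MergeError(NmrPathError):
    """Conflicting node definitions while merging pathway fragments."""


class GraphLookupError(NmrPathError):
    """A node id is absent from the graph (distinct from unreachable)."""
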