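"""Exception hierarchy.

Every error raised by this package derives from :class:`PhyloconcordError`
so callers can catch the package's failures with a single except clause.
"""


class PhyloconcordError(Exception):
    """Base class for all package errors."""


class FormatError(PhyloconcordError):
    """A file or string could not be parsed (carries position info if known)."""


class ValidationError(PhyloconcordError):
    """An input violates a structural invariant (duplicate tips, unknown cell, ...)."""


class ConfigurationError(PhyloconcordError):
    """A parameter combination is unusable (e.g. empty normal-cell set)."""


class EmptyResultError(PhyloconcordError):
    """A filter removed everything."""


class UnsupportedTopologyError(PhyloconcordError):
    """The tree topology is outside the supported class (polytomies)."""


class InsufficientDataError(PhyloconcordError):
    """Too little data to estimate the requested quantity."""


class ConstraintInfeasibleError(PhyloconcordError):
    """No clade configuration satisfies the annotation constraints."""


class DegenerateTableError(PhyloconcordError):
    """A contingency table has fewer than two labels on an axis or a zero margin."""


class AlignmentError(PhyloconcordError):
    """An annotation shares no cells with the reference and cannot be aligned."""
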