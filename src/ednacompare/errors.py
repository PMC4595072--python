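"""Exception hierarchy for community-matrix and analysis contracts."""


class EdnaCompareError(Exception):
    """Base class for all package errors."""


class CommunityFormatError(EdnaCompareError):
    """Malformed community matrix: non-numeric/negative cells, duplicates."""


class HierarchyError(EdnaCompareError):
    """Sample labels that cannot be resolved to a plot (and subplot)."""


class EmptySampleError(EdnaCompareError):
    """An operation produced (or was given) a sample with zero total count."""


class LabelMismatchError(EdnaCompareError):
    """Two matrices/configurations do not share the required labels."""


class DegenerateInputError(EdnaCompareError):
    """Input is too small or too uniform for the requested statistic."""
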