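"""Exception hierarchy shared across the package."""


class StemevolError(Exception):
    """Base class for all package errors."""


class FormatError(StemevolError):
    """A file does not conform to its declared dialect (ragged rows, bad records)."""


class StructureError(StemevolError):
    """A consensus structure string is unbalanced or otherwise invalid.

    Carries a 1-based ``column`` attribute when the offending position is known.
    """

    def __init__(self, message: str, column: int | None = None):
        super().__init__(message)
        self.column = column


class ValidationError(StemevolError):
    """A domain invariant is violated (duplicate ids, mismatched label sets)."""


class MappingError(StemevolError):
    """Species in one input cannot be matched to the other (tree vs alignment)."""


class MissingDataError(StemevolError):
    """A leaf required by a reconstruction has no observed value."""


class NoCallError(StemevolError):
    """An event cannot be classified (e.g. every descendant is unsequenced)."""


class DegenerateTableError(StemevolError):
    """A contingency table has a zero expected cell."""


class EmptyMatrixError(StemevolError):
    """A count matrix with zero total events cannot be log-odds transformed."""


class ParameterError(StemevolError):
    """An analysis parameter is out of range for the data (e.g. k > n species)."""


class GenerationError(StemevolError):
    """The synthetic-data generator was given infeasible geometry or rates."""


class PipelineError(StemevolError):
    """A fatal cross-stage condition (e.g. no species shared by tree and alignment)."""
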