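"""Exception hierarchy shared across the package."""


class PromopopError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(PromopopError):
    """Ragged or otherwise structurally invalid alignment."""


class ParseError(PromopopError):
    """Malformed input file (FASTA, TSV, motif library)."""


class MappingError(PromopopError):
    """Population map does not cover the alignment, or is inconsistent."""


class InvalidArgument(PromopopError, ValueError):
    """Precondition violation on an operation argument."""


class UndefinedStatistic(PromopopError):
    """A statistic is mathematically undefined for the given input
    (e.g. Tajima's D with no segregating sites, Hd with n < 2)."""


class InvalidHierarchy(PromopopError):
    """AMOVA hierarchy is degenerate (single population with grouping,
    group with no populations, ...)."""


class PlantingError(PromopopError):
    """Motif planting could not find enough gap-free, non-overlapping loci."""


class UnknownMotif(PromopopError):
    """Motif id requested that is absent from the loaded library."""
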