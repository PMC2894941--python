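"""Exception hierarchy shared across the package."""


class MirstarError(Exception):
    """Base class for all package-specific errors."""


class FastaFormatError(MirstarError):
    """Malformed FASTA input (e.g. a sequence-less header)."""


class NameParseError(MirstarError):
    """A miRNA identifier that cannot be parsed."""


class MappingError(MirstarError):
    """A mature/star sequence that does not occur on its hairpin."""


class StructureTooWeakError(MirstarError):
    """Hairpin pairing too sparse under the mature strand to place a duplex."""


class UnpairedEndpointError(StructureTooWeakError):
    """No paired base within reach of a duplex endpoint."""


class TransferFailedError(MirstarError):
    """Homology transfer of a star span produced no usable interval."""


class SpanInconsistencyError(MirstarError):
    """Strand spans that overlap or lie on the same arm."""


class UndefinedDistanceError(MirstarError):
    """No comparable columns left after gap deletion."""


class EmptyProfileError(MirstarError):
    """No strand positions survive the occupancy filter."""


class RegionError(MirstarError):
    """A region specification disjoint from the available positions."""
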