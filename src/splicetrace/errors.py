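"""Exception hierarchy shared across the package.

All errors raised deliberately by splicetrace derive from
:class:`SpliceTraceError`, so callers can catch one base class.
"""


class SpliceTraceError(Exception):
    """Base class for all splicetrace errors."""


class ParseError(SpliceTraceError):
    """Malformed input file; the message names the offending line/record."""


class UnknownReferenceError(SpliceTraceError):
    """A record points at a genome/sequence id that cannot be resolved."""


class DegenerateIntronError(SpliceTraceError):
    """An intron is too short to carry donor and acceptor dinucleotides."""


class PseudogeneError(SpliceTraceError):
    """A spliced CDS contains an internal stop codon."""


class FrameError(SpliceTraceError):
    """A spliced CDS length is not a multiple of three."""


class PartialModelError(SpliceTraceError):
    """Operation requires a complete gene model but got a partial one."""


class AlphabetError(SpliceTraceError):
    """A sequence contains symbols outside its declared alphabet."""


class AlignmentFormatError(SpliceTraceError):
    """Alignment rows are ragged, empty or otherwise malformed."""


class IdError(SpliceTraceError):
    """Duplicate or unknown sequence identifier."""


class ConsistencyError(SpliceTraceError):
    """Two inputs that must describe the same sequences disagree."""


class BoundsError(SpliceTraceError):
    """A region or window exceeds the coordinate range of its reference."""


class UndefinedFractionError(SpliceTraceError):
    """A ratio whose denominator is zero (e.g. no differences between a==b)."""


class AnnotationError(SpliceTraceError):
    """A supplied annotation (e.g. a claimed start codon) is not what it claims."""


class MappingError(SpliceTraceError):
    """Taxa missing from the taxon-to-clade map; message lists them."""


class ConfigError(SpliceTraceError):
    """Invalid simulation or pipeline configuration."""
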