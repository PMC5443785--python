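"""Exception types shared across the package."""


class SSRPopscanError(Exception):
    """Base class for all package-specific errors."""


class InvalidAlphabetError(SSRPopscanError, ValueError):
    """A sequence or repeat unit contains characters outside A/C/G/T(/N)."""


class InvalidPeriodError(SSRPopscanError, ValueError):
    """A repeat-unit length is outside the supported 2-6 bp range."""


class NonPrimitiveMotifError(SSRPopscanError, ValueError):
    """A repeat unit is a whole-number repetition of a shorter unit."""


class CoordinateError(SSRPopscanError, ValueError):
    """Interval coordinates are malformed or fall outside the sequence."""


class MalformedAnnotationError(SSRPopscanError, ValueError):
    """A gene annotation violates structural expectations (e.g. CDS outside exons)."""


class ConsistencyError(SSRPopscanError, ValueError):
    """Two inputs that must be keyed consistently disagree."""


class UndefinedDistanceError(SSRPopscanError, ValueError):
    """A pairwise distance is undefined (no shared called loci)."""


class InvalidAlleleError(SSRPopscanError, ValueError):
    """An allele length is impossible for the locus (shorter than one unit)."""


class ParseError(SSRPopscanError, ValueError):
    """A file could not be parsed; message names the file and line."""


class SimulationError(SSRPopscanError, RuntimeError):
    """The synthetic-data generator could not satisfy its plan."""
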