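"""Exception hierarchy shared by all hspreg modules."""


class HspregError(Exception):
    """Base class for all errors raised by hspreg."""


class FormatError(HspregError, ValueError):
    """A file could not be parsed as the expected format."""


class AlignmentLengthError(FormatError):
    """Sequences in an alignment do not all have the same length."""


class AlphabetError(FormatError):
    """A sequence contains a character outside the allowed alphabet."""


class SchemaError(FormatError):
    """A delimited table is missing a required column."""


class TableValueError(FormatError):
    """A table cell could not be converted to the required type."""


class GapError(HspregError, ValueError):
    """A gap character was found where an ungapped sequence is required."""


class DegenerateAlignmentError(HspregError, ValueError):
    """No alignment columns survive filtering, or the alignment is unusable."""


class UndefinedFstError(HspregError, ValueError):
    """Fst is undefined because between-population diversity is zero."""


class ParameterError(HspregError, ValueError):
    """An operation received an out-of-range parameter."""


class NoAmpliconError(HspregError, ValueError):
    """In-silico PCR found no primer-delimited product."""


class AmbiguousAmpliconError(HspregError, ValueError):
    """In-silico PCR found more than one minimal product."""

    def __init__(self, message, products):
        super().__init__(message)
        self.products = products


class PairingError(HspregError, ValueError):
    """A biological replicate lacks a target or reference measurement."""


class DesignError(HspregError, ValueError):
    """The experimental design cannot support the requested model."""


class DegenerateDataError(HspregError, ValueError):
    """The response has no residual variance; F statistics are undefined."""


class CapacityError(HspregError, ValueError):
    """A simulation config requests more planted features than fit."""


class MotifOverlapError(HspregError, ValueError):
    """Planted motifs overlap each other."""


class PipelineStageError(HspregError, RuntimeError):
    """A pipeline stage failed; the stage name is recorded."""

    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
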