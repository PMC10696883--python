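"""Exception hierarchy shared across the package."""


class CrnnTfbsError(Exception):
    """Base class for all package errors."""


class ParseError(CrnnTfbsError):
    """A standard-format file could not be parsed."""


class AlphabetError(CrnnTfbsError):
    """A sequence contains characters outside the permitted alphabet."""


class PatternError(CrnnTfbsError):
    """An IUPAC pattern contains an unknown code."""


class ValidationError(CrnnTfbsError):
    """A record or interval violates its invariants."""


class InputError(CrnnTfbsError):
    """An operation received structurally invalid input."""


class ConfigError(CrnnTfbsError):
    """A configuration value is out of range or inconsistent."""


class LookupFailure(CrnnTfbsError):
    """A requested contig or identifier is absent from a source."""


class AlignmentError(CrnnTfbsError):
    """Two result collections that must share identifiers do not."""


class DegenerateDataError(CrnnTfbsError):
    """A statistic is undefined on the given data (e.g. zero variance)."""


class DivergenceError(CrnnTfbsError):
    """Training produced a non-finite loss."""


class ModelIOError(CrnnTfbsError):
    """A persisted model could not be loaded (corrupt or incompatible)."""
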