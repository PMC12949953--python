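"""Exception hierarchy shared across the package."""


class EstroMRError(Exception):
    """Base class for all package errors."""


class FormatError(EstroMRError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(EstroMRError, ValueError):
    """A value or record violates a domain invariant."""


class DataError(EstroMRError):
    """Inputs are structurally valid but mutually inconsistent (e.g. an rsID
    missing from the LD matrix, or incompatible allele pairs)."""


class ConfigurationError(EstroMRError):
    """A configuration value is outside its admissible range."""


class RoutingError(EstroMRError):
    """An estimator was called with an instrument size it is not defined for;
    the caller should route to the appropriate method instead."""


class InsufficientDataError(EstroMRError):
    """Too few harmonised variants for the requested analysis."""


class EmptyInstrumentError(EstroMRError):
    """Harmonisation left no usable variant for an (instrument, outcome) cell."""
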