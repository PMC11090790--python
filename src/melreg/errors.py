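"""Exception hierarchy shared across the package."""


class MelregError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MelregError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(MelregError):
    """An object or table violates a structural invariant."""


class InvalidParameterError(MelregError, ValueError):
    """A parameter is outside its documented domain."""


class EmptyInputError(MelregError):
    """An operation that requires data received none."""


class NoOverlapError(MelregError):
    """A gene set / regulon shares no genes with the profiled namespace."""


class DegenerateInputError(MelregError):
    """Input is formally valid but makes the statistic undefined."""


class EmptyRegulonError(MelregError):
    """Regulon construction filtered away every candidate target."""
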