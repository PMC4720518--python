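"""Exception hierarchy shared across the toolkit."""


class CronoscanError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CronoscanError):
    """A file could not be parsed; the message names the offending line/row."""


class GeneModelError(CronoscanError):
    """A transcript model violates a structural invariant."""


class OutOfCdsError(CronoscanError):
    """A genomic position does not fall within the coding sequence."""


class UnmappedPositionError(CronoscanError):
    """An amino-acid position is not covered by the orthology map."""


class ConfigError(CronoscanError):
    """A simulation or analysis configuration is infeasible."""


class InputError(CronoscanError):
    """An input record is inconsistent with its reference context."""
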