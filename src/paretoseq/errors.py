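"""Exception hierarchy shared across the pipeline stages."""


class ParetoseqError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ParetoseqError):
    """A structured input file (GTF, SAM, TSV) could not be parsed."""


class FormatError(ParetoseqError):
    """An input file is readable but does not follow the expected schema."""


class ValidationError(ParetoseqError):
    """Input data violates a contract (negative counts, empty tables, ...)."""


class ConfigError(ParetoseqError):
    """A configuration value is invalid (odd promoter size, bad labels, ...)."""
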