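"""Exception hierarchy shared across the package."""


class MsiseqError(Exception):
    """Base class for all package errors."""


class InputError(MsiseqError):
    """Malformed user input (bad sequence characters, bad parameters)."""


class ParseError(MsiseqError):
    """A structured file (catalogue, transcript model, VCF) could not be parsed."""


class ValidationError(MsiseqError):
    """Input is well-formed but internally inconsistent (e.g. REF allele
    disagrees with the reference sequence)."""


class ConfigError(MsiseqError):
    """Invalid run configuration (missing paths, nonsensical thresholds)."""
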