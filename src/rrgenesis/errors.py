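"""Exception hierarchy shared across the pipeline."""


class RRGenesisError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RRGenesisError):
    """A parameter or configuration value is invalid; the message names the field."""


class InputError(RRGenesisError):
    """An input file or record is malformed or unresolvable."""


class PreconditionError(RRGenesisError):
    """An operation's stated precondition does not hold for the given data."""


class InsufficientDataError(RRGenesisError):
    """Too little usable data remains after preprocessing (e.g. <3 codons for Ka/Ks)."""
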