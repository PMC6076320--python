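"""Exception hierarchy shared across the pipeline."""


class NivimyxError(Exception):
    """Base class for all package errors."""


class ConfigError(NivimyxError, ValueError):
    """A simulation or policy configuration is invalid or unsatisfiable."""


class FormatError(NivimyxError, ValueError):
    """An input file violates its format contract (e.g. duplicate FASTA id)."""


class DataError(NivimyxError, ValueError):
    """Input data violate a semantic contract (alphabet, timestamps, ...)."""


class ContractError(NivimyxError, ValueError):
    """A documented precondition of an operation was not met by the caller."""
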