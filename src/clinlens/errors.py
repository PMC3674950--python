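"""Exception hierarchy.

Exit-code mapping used by the command-line layer:
``ConfigurationError``/``SchemaError`` -> 2, ``DegenerateDataError`` -> 3.
"""


class ClinlensError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ClinlensError):
    """An input configuration violates its invariants."""


class SchemaError(ClinlensError):
    """A tabular input file does not match the expected schema."""


class DegenerateDataError(ClinlensError):
    """Data carry no usable information for the requested statistic
    (constant outcome, zero-variance vector, zero marginal, ...)."""


class StratumShortageError(ConfigurationError):
    """A stratified sample requests more cases than a stratum holds."""


class UndefinedPhiError(DegenerateDataError):
    """The 2x2 table has a zero marginal, so phi is undefined."""
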