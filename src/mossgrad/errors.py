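"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, FormatError / IOError
-> 3, UndefinedStatisticError and other numerical problems -> 4.
"""


class MossgradError(Exception):
    """Base class for all package errors."""


class ConfigError(MossgradError):
    """Invalid configuration value or schema violation."""


class FormatError(MossgradError):
    """Malformed input file (missing columns, non-numeric fields, ...)."""


class UndefinedStatisticError(MossgradError):
    """A statistic is requested on degenerate input (zero variance,
    one-class labels, all-empty incidence matrix, ...)."""
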