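"""Exception hierarchy. Each branch maps to a distinct CLI exit code."""


class RankDecompError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(RankDecompError):
    """Invalid run configuration (bad roles, missing options)."""

    exit_code = 2


class DataError(RankDecompError):
    """Invalid dataset contents (missing columns, bad weights, NaNs)."""

    exit_code = 3


class IdentificationError(RankDecompError):
    """Order condition fails for a structural equation."""

    exit_code = 4


class EstimationError(RankDecompError):
    """Numerical estimation failure (rank deficiency, singular weight matrix)."""

    exit_code = 5
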