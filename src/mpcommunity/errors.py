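"""Exception hierarchy shared across the package.

The split mirrors the pipeline exit codes: configuration problems (bad
options, unknown modes), data problems (malformed tables, vocabulary
violations) and statistical precondition failures (degenerate inputs a
test cannot run on).
"""


class MpcError(Exception):
    """Base class for all package errors."""


class ConfigError(MpcError):
    """Invalid configuration: unknown mode, bad parameter, missing field."""


class DataError(MpcError):
    """Malformed or inconsistent input data."""


class VocabularyError(DataError):
    """A categorical value outside its closed vocabulary under strict policy."""


class StatisticalError(MpcError):
    """A statistical precondition is violated (e.g. singleton group)."""
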