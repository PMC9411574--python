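"""Exception hierarchy for the permdeg pipeline.

Validation failures raise :class:`ValidationError` subclasses so the CLI can
map them to exit code 2, while unexpected failures propagate as ordinary
exceptions (exit code 1).
"""


class PermdegError(Exception):
    """Base class for all permdeg errors."""


class ValidationError(PermdegError):
    """Invalid user input (file contents, design, configuration)."""


class CountsFormatError(ValidationError):
    """Malformed count matrix: non-integer/negative cells, bad header, ..."""


class DuplicateRecordError(ValidationError):
    """Duplicate gene or sample identifier on read."""


class DesignError(ValidationError):
    """Invalid two-group design (wrong label count, undersized groups)."""


class MismatchError(ValidationError):
    """Identifiers in one table do not match those in another."""


class NormalizationError(ValidationError):
    """Normalization cannot proceed (e.g. an all-zero sample)."""


class ConfigError(ValidationError):
    """Invalid configuration value."""
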