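"""Exception hierarchy for mirisk.

Every error raised on purpose by the package derives from :class:`MiriskError`
so callers can catch pipeline failures without masking programming errors.
"""


class MiriskError(Exception):
    """Base class for all mirisk errors."""


class ParameterError(MiriskError, ValueError):
    """An argument value violates an operation's preconditions."""


class ValidationError(MiriskError, ValueError):
    """Input data fails cross-validation (unknown ids, inconsistent tables...)."""


class ParseError(MiriskError, ValueError):
    """A file could not be parsed; message carries row/column context."""


class ConfigurationError(MiriskError, ValueError):
    """A configuration table or option is incomplete or inconsistent."""


class EmptyPanelError(MiriskError, ValueError):
    """A filtering step removed every probe."""


class DegenerateSampleError(MiriskError, ValueError):
    """A sample cannot be normalized (e.g. all-zero counts)."""


class MappingError(MiriskError, KeyError):
    """Features required by a fitted model are missing from new data."""


class StageError(MiriskError, RuntimeError):
    """A pipeline stage failed; message is tagged with the stage name."""
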