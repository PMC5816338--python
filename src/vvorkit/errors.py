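"""Exception hierarchy for vvorkit.

Every error raised by the package derives from :class:`VvorError`, so callers
(including the CLI) can catch one type and report a one-line diagnostic.
"""


class VvorError(Exception):
    """Base class for all vvorkit errors."""


class ConfigurationError(VvorError):
    """A dialect, column or parameter setting is invalid or missing."""


class ParameterError(VvorError):
    """A numeric analysis parameter violates its constraints."""


class EmptyRecordingError(VvorError):
    """No valid samples remain after parsing and cleaning."""


class MalformedRecordingError(VvorError):
    """The recording violates a structural requirement (e.g. time order)."""


class TooShortError(VvorError):
    """The trace is too short for the requested analysis."""


class DegenerateDirectionError(VvorError):
    """One head-movement direction has no usable data."""


class InsufficientDataError(VvorError):
    """Too few paired measurements for the agreement statistic."""


class UndefinedStatisticError(VvorError):
    """The statistic is undefined for this input (e.g. zero total variance)."""


class DependencyError(VvorError):
    """A required upstream result is missing."""


class IncompleteReportError(VvorError):
    """An analysis report is missing a required block."""
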