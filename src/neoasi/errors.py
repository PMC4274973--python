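"""Exception hierarchy for ASI analysis failures.

Every error a pipeline stage can raise derives from :class:`NeoasiError`,
so callers can distinguish analysis failures from programming errors.
"""


class NeoasiError(Exception):
    """Base class for all neoasi errors."""


class MontageError(NeoasiError):
    """A required electrode label is missing from the record."""


class EpochLengthError(NeoasiError):
    """An epoch or window is too short for the requested analysis."""


class DataQualityError(NeoasiError):
    """The signal contains NaNs or annotated artifact in the analysis window."""


class DegenerateSignalError(NeoasiError):
    """A constant (flat) envelope cannot be quantized or scored."""


class AnalysisError(NeoasiError):
    """No usable lags / windows survived; the analysis cannot proceed."""


class IncompleteSubjectError(NeoasiError):
    """A subject is missing one of the two epoch-level ASI estimates."""


class StatisticsError(NeoasiError):
    """Too few observations for the requested statistical test."""


class ConfigError(NeoasiError):
    """Invalid pipeline configuration."""
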