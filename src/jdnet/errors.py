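"""Structured exceptions raised by the pipeline stages.

Every stage failure derives from :class:`JDNetError` so that cohort runs can
skip a bad subject with a structured message while other subjects proceed.
"""


class JDNetError(Exception):
    """Base class for all jdnet pipeline errors."""


class InvalidTrimError(JDNetError):
    """Pre-stimulus trim length meets or exceeds the epoch length."""


class EmptyInputError(JDNetError):
    """An operation received no data (e.g. zero epochs)."""


class InvalidFilterError(JDNetError):
    """Filter cutoffs are inconsistent with the sampling rate."""


class DegenerateChannelError(JDNetError):
    """A channel is constant and cannot be rescaled to [0, 1]."""

    def __init__(self, channel: int | None = None, message: str | None = None):
        self.channel = channel
        if message is None:
            message = (
                f"channel {channel} is constant (max == min); cannot rescale"
                if channel is not None
                else "constant signal; cannot rescale"
            )
        super().__init__(message)


class TooShortSeriesError(JDNetError):
    """The series is too short for the requested delay embedding."""


class TooFewObservationsError(JDNetError):
    """Not enough joint-distance observations for Doane binning."""


class DomainError(JDNetError):
    """Matrix entries outside the domain expected by the operation."""


class NormalizationError(JDNetError):
    """Entropy normalization is undefined (fewer than two bins)."""


class UndefinedMetricError(JDNetError):
    """A graph metric is undefined for this graph (e.g. empty component)."""


class DegenerateSampleError(JDNetError):
    """A statistical sample has zero variance or too few values."""


class ConfigError(JDNetError):
    """Invalid configuration values (bands, weights, group sizes)."""
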