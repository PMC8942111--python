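"""Exception types shared across the package."""


class BreathSnrError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigurationError(BreathSnrError, ValueError):
    """A parameter combination is physically or numerically invalid
    (e.g. analysis band outside Nyquist, non-positive durations)."""


class InsufficientDataError(BreathSnrError, RuntimeError):
    """Not enough usable data to estimate a quantity, e.g. no non-rejected
    quiet interval from which to estimate the noise floor."""


class UndefinedResultError(BreathSnrError, RuntimeError):
    """A statistic is mathematically undefined for the given input
    (e.g. rank correlation against a constant column)."""


class BandMismatchError(BreathSnrError, ValueError):
    """Two results computed over different analysis bands were combined."""


class DeadChannelError(BreathSnrError, ValueError):
    """A channel has zero variance and cannot be aligned or weighted."""
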