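"""Exception hierarchy for the archepsy pipeline."""


class ArchepsyError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ArchepsyError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientSignalError(ArchepsyError):
    """A signal carries too little physiological content to analyse
    (e.g. a flat-line trace from which no heartbeats can be detected)."""


class InsufficientDataError(ArchepsyError):
    """Too few samples/intervals to compute the requested statistic."""


class InvalidDesignError(ArchepsyError):
    """A cross-validation design constraint is violated (e.g. a class
    with a single sample under leave-one-out, or an unbalanced group)."""


class DegenerateVarianceError(ArchepsyError):
    """A paired t-test was requested on differences with zero variance."""


class MissingChannelError(ArchepsyError, KeyError):
    """A required physiological channel is absent from an epoch."""


class ConfigError(ArchepsyError):
    """A run configuration failed schema validation; the message names
    the offending field."""
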