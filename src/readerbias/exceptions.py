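"""Exception hierarchy shared across the pipeline."""


class ReaderBiasError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ReaderBiasError, ValueError):
    """A spec/config object has an invalid field value."""


class ValidationError(ReaderBiasError, ValueError):
    """Data (a manifest, a label vector, a probability vector) violates its contract."""


class UnsupportedBackboneError(ReaderBiasError, NotImplementedError):
    """The requested model backbone is recognized but not available in this build."""


class TrainingDivergenceError(ReaderBiasError, RuntimeError):
    """Training produced a non-finite loss; reports the epoch where it occurred."""


class UndefinedMetricError(ReaderBiasError, ValueError):
    """A metric is undefined for the given inputs (e.g. single-class AUC)."""


class DegenerateDesignError(ReaderBiasError, ValueError):
    """A regression design matrix is singular or spans too few distinct values."""
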