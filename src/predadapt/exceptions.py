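"""Exception hierarchy.

Every error raised by this package derives from :class:`PredadaptError`, so
callers can catch the whole family with one clause while the CLI maps the
subclasses onto distinct exit codes (configuration -> 2, divergence -> 3).
"""


class PredadaptError(Exception):
    """Base class for all predadapt errors."""


class ConfigurationError(PredadaptError, ValueError):
    """Invalid parameters, shapes or flags (e.g. non-positive layer size)."""


class PhaseError(PredadaptError, ValueError):
    """An operation received a trajectory from the wrong settling phase."""


class FitError(PredadaptError, RuntimeError):
    """Predictor fitting failed (e.g. too few trajectories)."""


class NumericalError(PredadaptError, FloatingPointError):
    """Non-finite activity or diverging weights during simulation."""


class IdxFormatError(PredadaptError, ValueError):
    """Base class for malformed IDX image/label files."""


class IdxMagicError(IdxFormatError):
    """IDX file does not start with the expected magic number."""


class IdxTruncatedError(IdxFormatError):
    """IDX file ends before the payload announced in its header."""


class IdxCountMismatchError(IdxFormatError):
    """Image and label files disagree on the number of items."""
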