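"""Exception hierarchy for the extempore-be pipeline.

Every error raised by the library derives from :class:`ExtemporeError` so
callers (and the CLI) can catch one base class.  The subclasses mirror the
failure modes of the individual stages: configuration problems, invalid
inputs, profile-alignment mismatches, data-quality violations, and numerical
failures of the ODE solvers.
"""


class ExtemporeError(Exception):
    """Base class for all library errors."""


class ConfigurationError(ExtemporeError):
    """A drug definition, physiology, or simulation setting is unusable."""


class ValidationError(ExtemporeError):
    """An input value violates a documented precondition."""


class AlignmentError(ExtemporeError):
    """Two dissolution profiles do not share a common timepoint vector."""


class UndefinedValueError(ExtemporeError):
    """A quantity is mathematically undefined for the given input
    (e.g. %PE with a zero observed value, f1 with an all-zero reference)."""


class InsufficientDataError(ExtemporeError):
    """Too few observations to perform the requested computation."""


class DataQualityError(ExtemporeError):
    """Input data violates a physical constraint beyond tolerance
    (e.g. a cumulative dissolution curve that decreases by more than 2%)."""


class IntegrationError(ExtemporeError):
    """The ODE solver failed or produced a state outside tolerance."""


class LambdaZEstimationError(ExtemporeError):
    """Terminal slope estimation failed (non-negative regression slope)."""
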