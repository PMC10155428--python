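"""Exception hierarchy shared across the package."""


class SynergyKitError(Exception):
    """Base class for all package errors."""


class SchemaError(SynergyKitError):
    """A session container or chart violates the documented schema."""


class ParameterError(SynergyKitError):
    """An argument is outside its documented domain."""


class SegmentationError(SynergyKitError):
    """A trial event cannot be segmented from the available envelope."""


class NormalizationError(SynergyKitError):
    """An amplitude-normalization scope group carries no signal."""


class DegenerateSeriesError(SynergyKitError):
    """A time series is too flat or short for the requested estimator."""


class ChartError(SchemaError):
    """A myotomal chart fails validation."""


class StageError(SynergyKitError):
    """A pipeline stage failed; carries the stage name and session id."""

    def __init__(self, stage: str, session_id: str, cause: Exception):
        self.stage = stage
        self.session_id = session_id
        self.cause = cause
        super().__init__(f"stage '{stage}' failed for session '{session_id}': {cause}")
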