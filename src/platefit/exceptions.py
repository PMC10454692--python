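"""Exception hierarchy for platefit.

Every error raised by the package derives from :class:`PlateFitError` so
callers can catch pipeline failures with a single except clause while still
distinguishing parse, validation, fitting and inference problems.
"""


class PlateFitError(Exception):
    """Base class for all platefit errors."""


class FormatError(PlateFitError):
    """A delimited input file does not have the expected structure."""


class LayoutError(PlateFitError):
    """A plate layout violates its invariants (duplicate wells, missing blanks...)."""


class PlateValidationError(PlateFitError):
    """Data contradicts a hard contract (non-monotone times, missing wells)."""


class AlignmentError(PlateFitError):
    """Two series that must share a time grid do not."""


class MissingBlankError(PlateFitError):
    """No blank wells exist for a (medium, experiment) pair."""

    def __init__(self, condition: str, experiment_id: str):
        self.condition = condition
        self.experiment_id = experiment_id
        super().__init__(
            f"no blank wells for medium {condition!r} in experiment {experiment_id!r}"
        )


class FitError(PlateFitError):
    """Nonlinear fit failed to converge after restarts."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class DesignError(PlateFitError):
    """The ANOVA design matrix is singular or otherwise unusable."""


class InferenceError(PlateFitError):
    """Inference is impossible (e.g. no residual degrees of freedom)."""


class ReportError(PlateFitError):
    """A requested report cannot be assembled (missing condition label...)."""


class ConfigError(PlateFitError):
    """A run configuration is contradictory or incomplete."""


class PipelineError(PlateFitError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
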