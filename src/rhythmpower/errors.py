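"""Exception hierarchy shared across the package."""


class RhythmPowerError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RhythmPowerError, ValueError):
    """A configuration object violated an invariant.

    Parameters
    ----------
    field : str
        Name of the offending field.
    message : str
        Human-readable description of the violation.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class FitError(RhythmPowerError, ValueError):
    """A cosinor fit could not be performed (too few points, rank deficiency)."""


class DegenerateCovarianceError(RhythmPowerError, ValueError):
    """The between-subject coefficient covariance is singular."""


class ConstantSeriesError(RhythmPowerError, ValueError):
    """A series has zero variance and cannot be z-scored."""

    def __init__(self, participant_id: str, protein_id: str):
        self.participant_id = participant_id
        self.protein_id = protein_id
        super().__init__(
            f"constant series (sd = 0) for participant {participant_id!r}, "
            f"protein {protein_id!r}: cannot z-score"
        )


class PipelineError(RhythmPowerError, RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
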