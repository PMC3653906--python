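"""Exception hierarchy for the pipeline.

Validation problems (bad files, bad config) and stage failures (a sample
that cannot be calibrated or normalized) are kept distinct so the CLI can
map them to different exit codes.
"""


class CemspipeError(Exception):
    """Base class for all package errors."""


class ValidationError(CemspipeError):
    """Invalid user input: malformed file, bad configuration value."""


class SchemaError(ValidationError):
    """A tabular file does not conform to its documented header/content."""


class ConfigError(ValidationError):
    """A configuration value violates its invariant."""


class StageError(CemspipeError):
    """A pipeline stage failed on a specific sample."""

    def __init__(self, stage: str, sample_id: str | None, message: str):
        self.stage = stage
        self.sample_id = sample_id
        where = f" (sample {sample_id})" if sample_id else ""
        super().__init__(f"{stage}{where}: {message}")


class CalibrationError(StageError):
    """Migration-time calibration failed (too few reference anchors)."""

    def __init__(self, sample_id: str | None, message: str):
        super().__init__("calibrate", sample_id, message)


class NormalizationError(StageError):
    """Intensity normalization failed (too few housekeeping detections)."""

    def __init__(self, sample_id: str | None, message: str):
        super().__init__("normalize", sample_id, message)
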