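"""Exception hierarchy for the sarcomap pipeline.

Every error raised by the package derives from :class:`SarcomapError`, so
callers can catch one type at a pipeline boundary while tests can assert
the specific failure mode.
"""


class SarcomapError(Exception):
    """Base class for all sarcomap errors."""


class ManifestError(SarcomapError):
    """Cohort manifest is missing columns or otherwise violates the schema."""


class CoregistrationError(SarcomapError):
    """Sequence volumes and masks do not share a voxel grid."""


class MaskError(SarcomapError):
    """A mask is non-binary, empty, or overlaps where it must not."""


class CalibrationError(SarcomapError):
    """Cortex reference is unusable (zero/negative mean, empty cortex)."""


class DataError(SarcomapError):
    """Non-finite or otherwise corrupt voxel data."""


class StageError(SarcomapError):
    """An operation was applied to a feature table in the wrong stage."""


class LeakageError(SarcomapError):
    """Test-cohort data reached a fitting step that must not see it."""


class ConfigError(SarcomapError):
    """Invalid or geometrically infeasible configuration."""


class NumericError(SarcomapError):
    """Numerical failure (non-finite update) during training."""
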