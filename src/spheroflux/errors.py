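"""Exception hierarchy for the spheroflux pipeline.

Every error raised by the package derives from :class:`SpherofluxError`,
split into validation problems (bad inputs/config, caught before any
computation) and runtime problems (failures while processing valid inputs).
The CLI maps these onto exit codes 1 and 2 respectively.
"""


class SpherofluxError(Exception):
    """Base class for all spheroflux errors."""


class ValidationError(SpherofluxError):
    """Invalid input data or configuration."""


class FormatError(ValidationError):
    """A file does not match the expected tabular format."""


class LayoutError(ValidationError):
    """Rate table and plate layout disagree."""


class DuplicateRecordError(ValidationError):
    """The same (well, measurement) pair appears more than once."""


class ScheduleError(ValidationError):
    """Injection schedule does not cover the measurement indices."""


class ConfigurationError(ValidationError):
    """Missing or inconsistent run configuration."""


class StateError(SpherofluxError):
    """Operation applied in the wrong pipeline state (e.g. double correction)."""


class FitError(SpherofluxError):
    """Calibration regression cannot be fit."""


class NormalizationError(SpherofluxError):
    """Per-cell / per-area normalization with a non-positive denominator."""


class IncompleteWellError(SpherofluxError):
    """A well lacks measurements required for parameter extraction."""


class NoSpheroidError(SpherofluxError):
    """Segmentation found no foreground object."""


class PipelineError(SpherofluxError):
    """A pipeline stage failed; message carries stage and well context."""
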