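"""Named exceptions used across the pipeline.

Every failure mode that callers are expected to handle gets its own class so
tests (and downstream code) can catch the precise condition rather than
string-matching messages.
"""


class MotorsigError(Exception):
    """Base class for all package errors."""


# --- configuration / synthetic data ---------------------------------------

class UnknownGroupError(MotorsigError):
    """A group label is not one of the configured groups."""


class IncompleteConfigError(MotorsigError):
    """A group-effect preset is missing a latent parameter for some group."""


class UnknownPresetError(MotorsigError):
    """A named preset does not exist."""


class GoalUnreachableError(MotorsigError):
    """The simulated finger did not reach the goal zone within the step cap."""


class EmptyRosterError(MotorsigError):
    """A cohort was requested with no tasks."""


# --- trajectory processing -------------------------------------------------

class MalformedStreamError(MotorsigError):
    """Touch-phase bookkeeping is inconsistent (e.g. release without press).

    Carries ``sample_index`` pointing at the offending sample.
    """

    def __init__(self, message: str, sample_index: int | None = None):
        super().__init__(message)
        self.sample_index = sample_index


class TimestampOrderError(MotorsigError):
    """Timestamps are not strictly increasing."""


class NonFiniteCoordinateError(MotorsigError):
    """A coordinate is NaN or infinite."""


class TooFewPointsError(MotorsigError):
    """A trajectory has fewer than two points."""


# --- features --------------------------------------------------------------

class TaskSkippedError(MotorsigError):
    """A task produced no defined value for some required feature."""


class ConflictingLabelError(MotorsigError):
    """One subject appears with more than one group label."""


class ConstantColumnError(MotorsigError):
    """A feature column is constant and cannot be standardized."""


# --- classifier ------------------------------------------------------------

class LayerSizeError(MotorsigError):
    """A model layer size is not a positive integer."""


class DivergenceError(MotorsigError):
    """Training loss became non-finite. Carries ``epoch``."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class LabelError(MotorsigError):
    """Labels outside the expected {ASD, TD} / {0, 1} set."""


class SplitError(MotorsigError):
    """Invalid cross-validation request (k > n, unknown split mode...)."""


# --- ablation --------------------------------------------------------------

class MaskError(MotorsigError):
    """An ablation mask names a non-kinematic (or unknown) feature."""


# --- I/O / pipeline --------------------------------------------------------

class TouchLogFormatError(MotorsigError):
    """A touch-log CSV is malformed. Carries ``line`` (1-based, incl. header)."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class ConfigError(MotorsigError):
    """A run configuration contains unknown or invalid keys."""
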