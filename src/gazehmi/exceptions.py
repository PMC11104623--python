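"""Exception types raised across the package."""


class GazeHMIError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GazeHMIError):
    """Invalid scene, learner, or pipeline configuration."""


class StreamTooShortError(GazeHMIError):
    """A gaze stream has too few samples for the requested operation."""


class UnterminatedSaccadeError(GazeHMIError):
    """The offset criterion was never met before the stream ended."""


class DegenerateTrajectoryError(GazeHMIError):
    """A saccade trajectory with coincident start and end point."""


class UndefinedAngleError(GazeHMIError):
    """Angular position requested for a point at the fixation cross."""


class DegenerateTestError(GazeHMIError):
    """A test statistic is undefined (e.g. zero variance everywhere)."""


class SampleTooSmallError(GazeHMIError):
    """Too few observations for the requested statistic."""


class UnbalancedDesignError(GazeHMIError):
    """Mixed-ANOVA table is not balanced across participants and cells."""


class SchemaError(GazeHMIError):
    """A dataset on disk does not match the documented column schema."""
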