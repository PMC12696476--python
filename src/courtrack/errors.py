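"""Exception hierarchy for courtrack."""


class CourtrackError(Exception):
    """Base class for all courtrack errors."""


class FormatError(CourtrackError):
    """Malformed input table (missing columns, duplicate rows, ...)."""


class RoleError(CourtrackError):
    """Role map does not cover, or conflicts with, the individuals present."""


class ParameterError(CourtrackError):
    """Invalid parameter value (non-positive fps, negative radius, ...)."""


class AlignmentError(CourtrackError):
    """Per-frame series of unequal length were combined."""


class EmptyTrialError(CourtrackError):
    """A trial with zero frames was passed where frames are required."""


class InsufficientDataError(CourtrackError):
    """Too few defined samples to compute the requested statistic."""


class MissingDataError(CourtrackError):
    """A required optional field (e.g. bounding boxes) is entirely absent."""


class IntervalContractError(CourtrackError):
    """Event-interval stream violates the sorted/disjoint contract."""


class ScriptError(CourtrackError):
    """Episode script is inconsistent with the trial duration or roles."""


class ConfigError(CourtrackError):
    """Run configuration is malformed or contains unknown keys."""
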