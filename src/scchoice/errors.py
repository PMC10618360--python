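"""Exception hierarchy for session simulation and analysis.

Every error raised on a per-trial or per-cell basis carries enough context
(trial id, cell id, file name) to locate the offending record.
"""


class SCChoiceError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(SCChoiceError):
    """A configuration object is internally inconsistent."""


class InvalidTargetError(SCChoiceError):
    """Requested target location is not on the LED grid."""


class InfeasibleGeometryError(SCChoiceError):
    """Receptive-field location plus ocular deviation falls off the grid."""


class NoChoiceError(SCChoiceError):
    """Race received zero drive on both sides; the trial cannot resolve."""


class InvalidProfileError(SCChoiceError):
    """A rate profile is unbounded or otherwise unusable for sampling."""


class MalformedTrialError(SCChoiceError):
    """A trial is missing a required event or epoch."""


class SamplingError(SCChoiceError):
    """Eye trace is not uniformly sampled."""


class InvalidFixationError(SCChoiceError):
    """Neither eye held the central fixation window at baseline."""


class FailedTrialError(SCChoiceError):
    """Neither eye acquired the eccentric target."""


class AmbiguousTrialError(SCChoiceError):
    """Both eyes ended within the acquisition window; labels undecidable."""


class UnmatchableError(SCChoiceError):
    """Amplitude matching cannot reach p > alpha with >= 3 trials per group."""


class RankError(SCChoiceError):
    """Calibration is degenerate (fewer than two distinct targets per axis)."""


class InvalidParamsError(SCChoiceError):
    """Numerical parameters out of their admissible range."""


class DegenerateCellError(SCChoiceError):
    """All condition traces are zero; the cell cannot be normalized."""


class AlignmentError(SCChoiceError):
    """Traces to be aggregated do not share a common time grid."""


class WindowError(SCChoiceError):
    """An analysis window falls outside the available trace grid."""


class SchemaError(SCChoiceError):
    """A session file on disk violates the expected schema."""
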