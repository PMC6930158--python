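"""Exception hierarchy used across the package.

Every anticipated failure mode maps to one of these, so callers can
distinguish bad input (ParseError, ValidationError) from degenerate
analyses (InsufficientGroupError, NoCutoffError, SingularDesignError)
and pipeline-stage failures (StageError).
"""


class ImmunoscreenError(Exception):
    """Base class for all package errors."""


class ParseError(ImmunoscreenError):
    """Malformed input file; message names the offending line/column."""


class ValidationError(ImmunoscreenError):
    """Input violates a documented precondition or type invariant."""


class EmptyCohortError(ImmunoscreenError):
    """A join or filter left no samples."""


class InsufficientGroupError(ImmunoscreenError):
    """A comparison group has too few samples to analyze."""


class NoCutoffError(ImmunoscreenError):
    """No eligible cutoff exists between the expression quartiles."""


class SingularDesignError(ImmunoscreenError):
    """Covariate matrix is constant, collinear or otherwise rank-deficient."""


class StageError(ImmunoscreenError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
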