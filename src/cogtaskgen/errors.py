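"""Exception hierarchy.

All package errors derive from :class:`TaskGenError` so callers (notably the
CLI) can distinguish validation problems from genuine bugs.
"""


class TaskGenError(Exception):
    """Base class for all errors raised by cogtaskgen."""


class UnknownTaskError(TaskGenError):
    """A task identifier is not one of the 11 registered training tasks."""


class InvalidParameterError(TaskGenError):
    """A parameter name is not defined for the task, or is missing."""


class OutOfRangeError(TaskGenError):
    """A parameter value is outside the task's allowed levels."""


class SchemaError(TaskGenError):
    """A configuration document is malformed; carries a list of offences."""

    def __init__(self, offences):
        self.offences = list(offences)
        super().__init__("invalid configuration: " + "; ".join(self.offences))


class UndefinedAlphaError(TaskGenError):
    """Cronbach alpha is undefined (fewer than 2 items, or no variance)."""


class CollinearityError(TaskGenError):
    """The design matrix is rank deficient; names the aliased predictors."""

    def __init__(self, aliased):
        self.aliased = list(aliased)
        super().__init__(
            "rank-deficient design; aliased predictors: " + ", ".join(self.aliased)
        )


class IncomparableModelsError(TaskGenError):
    """Model fits were computed on different record sets."""


class EmptyDesignError(TaskGenError):
    """A rating simulation was requested over an empty design."""


class BankExhaustedError(TaskGenError):
    """A content bank does not hold enough items for the requested task."""


class GenerationFailureError(TaskGenError):
    """Procedural generation failed after bounded retries."""


class ValidationError(TaskGenError):
    """An input document (profile, MoCA record, session) failed validation."""
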