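"""Exception hierarchy for the validation pipeline.

Every stage raises a subclass of :class:`PromsAgreeError` so callers (and the
CLI) can distinguish configuration mistakes, malformed inputs and contract
violations from ordinary bugs.
"""


class PromsAgreeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PromsAgreeError, ValueError):
    """An invalid parameter value; the message names the offending field."""


class SchemaError(PromsAgreeError, ValueError):
    """A required column is missing or has the wrong shape."""


class CodeValidationError(PromsAgreeError, ValueError):
    """A string is not a valid ICD-10 code; carries the offending text."""

    def __init__(self, raw: str, message: str | None = None):
        self.raw = raw
        super().__init__(message or f"not a valid ICD-10 code: {raw!r}")


class UnknownConditionError(PromsAgreeError, LookupError):
    """A condition name is absent from the code map or table."""


class AlignmentError(PromsAgreeError, ValueError):
    """Patient sets of two tables do not match; carries the missing ids."""

    def __init__(self, missing_left, missing_right):
        self.missing_left = sorted(missing_left)
        self.missing_right = sorted(missing_right)
        super().__init__(
            "patient sets differ: "
            f"{len(self.missing_left)} only in responses, "
            f"{len(self.missing_right)} only in flags "
            f"(e.g. {self.missing_left[:3] + self.missing_right[:3]})"
        )


class EvaluationError(PromsAgreeError, ValueError):
    """A statistic cannot be computed for structural reasons (e.g. a
    backward-coding comparison with zero reporters)."""


class ContractViolationError(PromsAgreeError, RuntimeError):
    """An upstream guarantee was broken (e.g. a cohort patient with no index
    admission reached flag derivation)."""
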