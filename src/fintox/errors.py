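"""Exception hierarchy for the fintox pipeline.

Exit-code mapping in the CLI: ValidationError/SchemaError -> 1,
anything else -> 2.
"""


class FintoxError(Exception):
    """Base class for all fintox errors."""


class SchemaError(FintoxError):
    """An input file does not have the expected columns or dialect."""


class ValidationError(FintoxError):
    """A value violates a documented precondition or invariant."""


class UnresolvableItemError(FintoxError):
    """A service record cannot be matched to any fee-schedule item."""


class JoinError(FintoxError):
    """Patient identifiers do not match across input tables."""


class GenerationError(FintoxError):
    """The synthetic-cohort generator cannot satisfy the requested target."""


class AnalysisError(FintoxError):
    """A descriptive statistic is undefined for the given input
    (empty group, zero-median denominator, ...)."""
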