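"""Exception hierarchy for network construction and model fitting."""


class CnmaError(Exception):
    """Base class for all package errors."""


class InputFormatError(CnmaError):
    """Malformed input table: missing columns, unparseable fields."""


class ValidationError(CnmaError):
    """Well-formed input that violates a model invariant (se <= 0, duplicate
    comparisons, incomplete multi-arm expansion, ...)."""


class ConnectivityError(CnmaError):
    """A connected-network method was called on a disconnected network."""


class StructuralError(CnmaError):
    """Degrees of freedom or design structure make the request meaningless
    (negative df, degenerate design)."""


class IdentificationError(CnmaError):
    """The component design matrix has lower rank than the number of
    components, so some component effects are not identified."""

    def __init__(self, message: str, non_identified: list[str] | None = None):
        super().__init__(message)
        self.non_identified = non_identified or []


class EstimabilityError(CnmaError):
    """A requested contrast lies outside the row space of the design matrix."""


class UsageError(CnmaError):
    """API misuse: incompatible fits, mismatched weights, non-nested designs."""
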