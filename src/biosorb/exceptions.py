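"""Exception hierarchy shared across the package."""


class BiosorbError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BiosorbError, ValueError):
    """Invalid data or parameter values (wrong sign, wrong length, NaN...)."""


class DomainError(BiosorbError, ValueError):
    """Input outside the mathematical domain of a model or transform."""


class CovolumeSingularityError(DomainError):
    """Equilibrium concentration at or beyond the co-volume bound 1/b.

    The van der Waals correction diverges as Ce -> 1/b; concentrations must
    stay strictly below that bound.
    """


class SchemaError(BiosorbError, ValueError):
    """Tabular input whose header or cells do not match the expected schema."""


class ConvergenceError(BiosorbError, RuntimeError):
    """All optimizer starts failed to converge."""
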