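"""Exception hierarchy shared across the pipeline stages."""


class BurnMechError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecificationError(BurnMechError, ValueError):
    """A generator or model specification violates its invariants."""


class InvalidGeometryError(BurnMechError, ValueError):
    """Specimen geometry with non-positive gauge length or area."""


class DegenerateCurveError(BurnMechError, ValueError):
    """A stress-strain curve that carries no usable signal (e.g. all-zero stress)."""


class EnergyOverflowError(BurnMechError, OverflowError):
    """The exponential term of the strain energy would overflow."""


class FitFailureError(BurnMechError, RuntimeError):
    """No start of the multi-start nonlinear least squares converged."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class UntestableError(BurnMechError, ValueError):
    """Samples too small or too degenerate for the hypothesis-test tree."""


class UndefinedEffectSizeError(BurnMechError, ZeroDivisionError):
    """Cohen's d is undefined because the pooled variance is zero."""


class SearchLimitError(BurnMechError, RuntimeError):
    """Sample-size search exhausted its limit without reaching the target power."""


class InvalidTaskError(BurnMechError, ValueError):
    """A classification task that is not a two-class problem."""


class SchemaError(BurnMechError, ValueError):
    """Tables with mismatched columns cannot be combined."""


class ParseError(BurnMechError, ValueError):
    """A delimited-text input file is malformed."""
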