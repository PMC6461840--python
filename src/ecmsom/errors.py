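"""Exception types shared across the pipeline stages."""


class EcmsomError(Exception):
    """Base class for all pipeline errors."""


class InvalidDesignError(EcmsomError):
    """Simulation design violates its invariants (e.g. non-increasing times)."""


class InvalidTemplateError(EcmsomError):
    """A gene template is malformed (e.g. wrong pattern length or state)."""


class IncompletePhaseError(EcmsomError):
    """A chemistry trajectory never reaches one of the nutritional phases."""

    def __init__(self, missing_phase: str, message: str | None = None):
        self.missing_phase = missing_phase
        super().__init__(message or f"trajectory never reaches phase {missing_phase!r}")


class PhaseOrderError(EcmsomError):
    """Depletion events occur in an order incompatible with the phase model."""


class DegenerateInputError(EcmsomError):
    """Input carries no usable signal (all-zero matrix, zero-variance groups...)."""


class FitConvergenceError(EcmsomError):
    """A nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class UndefinedRatioError(EcmsomError):
    """A marker ratio is undefined (zero denominator area or zero TOC)."""


class AnnotationError(EcmsomError):
    """Gene annotation table is inconsistent (conflicting paths for a gene)."""
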