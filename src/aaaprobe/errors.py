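"""Exception hierarchy for the simulation pipeline."""


class AAAProbeError(Exception):
    """Base class for all package errors."""


class StretchRangeError(AAAProbeError):
    """Constitutive evaluation left the admissible stretch range (e.g. exp overflow)."""

    def __init__(self, message: str, stretch: float | None = None):
        super().__init__(message)
        self.stretch = stretch


class MaterialDefinitionError(AAAProbeError):
    """Material parameters violate an invariant (e.g. non-positive-definite reduction)."""


class ElementInversionError(AAAProbeError):
    """det(F) <= 0 in a tissue element during assembly."""

    def __init__(self, message: str, element: int | None = None):
        super().__init__(message)
        self.element = element


class ConvergenceError(AAAProbeError):
    """Newton iteration failed after all step halvings."""

    def __init__(self, message: str, residual: float | None = None,
                 step: float | None = None, stage: str | None = None):
        super().__init__(message)
        self.residual = residual
        self.step = step
        self.stage = stage


class GeometryError(AAAProbeError):
    """Infeasible geometry specification (overlapping or escaping contours)."""


class MeshQualityError(AAAProbeError):
    """Triangulation failed or produced unacceptable element quality."""


class ZeroPressureError(AAAProbeError):
    """Backward-displacement iteration diverged or is not contracting."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class MeasurementError(AAAProbeError):
    """In-silico measurement (diameter/circumference or index) is degenerate."""


class ConfigError(AAAProbeError):
    """Study configuration failed validation."""
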