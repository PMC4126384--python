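"""Exception hierarchy for axonrve."""


class AxonRVEError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(AxonRVEError):
    """A path or point set does not define a usable geometry."""


class CalibrationError(AxonRVEError):
    """The undulation calibration loop cannot reach the requested target.

    Carries ``max_attainable``, the largest tortuosity the waypoint layout
    can realize.
    """

    def __init__(self, message: str, max_attainable: float | None = None):
        super().__init__(message)
        self.max_attainable = max_attainable


class ConfigurationError(AxonRVEError):
    """A configuration value is inconsistent or out of range."""


class ElementInversionError(AxonRVEError):
    """det F <= 0 was detected at a Gauss point; carries the element ids."""

    def __init__(self, message: str, element_ids=None, applied_stretch=None):
        super().__init__(message)
        self.element_ids = element_ids
        self.applied_stretch = applied_stretch


class ConvergenceError(AxonRVEError):
    """The Newton loop did not reach tolerance."""

    def __init__(self, message: str, applied_stretch=None, iterations=None,
                 residual_norm=None):
        super().__init__(message)
        self.applied_stretch = applied_stretch
        self.iterations = iterations
        self.residual_norm = residual_norm


class ExtrapolationError(AxonRVEError):
    """A stress-stretch curve was queried outside its sampled range."""
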