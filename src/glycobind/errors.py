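"""Exception hierarchy shared across the package."""


class GlycobindError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GlycobindError, ValueError):
    """Invalid parameter, schedule or data values."""


class UnsupportedModelError(GlycobindError, ValueError):
    """Operation called with a model kind it does not support."""


class GridMismatchError(GlycobindError, ValueError):
    """Sensorgram time grids differ where they must be identical."""


class IntegrationError(GlycobindError, RuntimeError):
    """Adaptive ODE integration failed for a parameter set."""


class ConvergenceError(GlycobindError, RuntimeError):
    """Optimizer failed to converge from every start.

    Carries the best candidate found so far in ``best_result``.
    """

    def __init__(self, message, best_result=None):
        super().__init__(message)
        self.best_result = best_result


class ParseError(GlycobindError, ValueError):
    """Malformed input table or configuration file."""
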