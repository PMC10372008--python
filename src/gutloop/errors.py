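"""Exception types shared across the package."""


class GutloopError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(GutloopError, ValueError):
    """An argument violates a documented precondition."""


class ConfigError(ParameterError):
    """A configuration file or override is invalid; names the field."""


class WindowError(ParameterError):
    """A rolling-window computation was asked for fewer than two points."""


class DegenerateCommunityError(GutloopError, RuntimeError):
    """The whole community collapsed to zero with no inflow to rescue it."""


class InstabilityError(GutloopError, RuntimeError):
    """A Lotka-Volterra abundance exceeded the divergence ceiling."""


class StateError(GutloopError, RuntimeError):
    """A trajectory is missing the phase boundaries a metric needs."""


class UndefinedFoldError(GutloopError, ZeroDivisionError):
    """Fold change requested against a zero baseline mean."""
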