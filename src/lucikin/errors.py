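"""Exception hierarchy shared by all lucikin modules."""


class LucikinError(Exception):
    """Base class for all package-specific errors."""


class DomainError(LucikinError, ValueError):
    """Input outside the physically meaningful domain (negative concentration, ...)."""


class FormatError(LucikinError, ValueError):
    """Malformed input file or table (missing column, non-monotone time, ...)."""


class ConfigError(LucikinError, ValueError):
    """Invalid run configuration (unknown key, missing seed, duplicate variant, ...)."""


class ConvergenceError(LucikinError, RuntimeError):
    """Optimizer or integrator failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class TruncationError(LucikinError, RuntimeError):
    """A curve did not reach the required conversion for the requested operation."""

    def __init__(self, message: str, achieved_fraction: float | None = None):
        super().__init__(message)
        self.achieved_fraction = achieved_fraction


class InfeasibleRateError(LucikinError, ValueError):
    """Requested microscopic rates are inconsistent with the macroscopic constants."""

    def __init__(self, message: str, minimal_k1: float | None = None):
        super().__init__(message)
        self.minimal_k1 = minimal_k1
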