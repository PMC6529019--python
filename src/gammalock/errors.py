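"""Exception hierarchy.

Every failure mode raised by the analysis code derives from
:class:`GammalockError` so callers can catch the package's own errors
without swallowing programming mistakes.
"""


class GammalockError(Exception):
    """Base class for all gammalock errors."""


class InvalidParameterError(GammalockError, ValueError):
    """A physical or numerical parameter violates its constraints."""


class NumericalBlowupError(GammalockError):
    """The integrated state became non-finite.

    Carries the time (ms) at which the blow-up was detected.
    """

    def __init__(self, time_ms: float, what: str = "state"):
        self.time_ms = time_ms
        super().__init__(f"non-finite {what} during integration at t = {time_ms:g} ms")


class RootNotFoundError(GammalockError):
    """Fixed-point search failed from the guess and the multi-start fallback."""


class NoCycleError(GammalockError):
    """The trajectory converged to a fixed point; no limit cycle exists here."""


class AdjointDivergenceError(GammalockError):
    """Backward adjoint integration did not converge within the period cap."""


class InsufficientDataError(GammalockError):
    """A trace is too short (or not oscillatory enough) for the requested measure."""


class GridMismatchError(GammalockError):
    """Two sampled objects do not share the same phase grid / period."""


class UnsettledShiftError(GammalockError):
    """A directly measured phase shift failed to plateau across the final cycles."""


class PresetNotFoundError(GammalockError, KeyError):
    """Unknown figure preset name."""


class ConfigError(GammalockError, ValueError):
    """A configuration file violates the schema; message names the offending key."""
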