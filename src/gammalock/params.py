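"""Parameter containers for one (or two) E-I circuits.

Units: time is in milliseconds throughout the package, so with the
canonical membrane time constant tau = 10 ms the emergent rhythms land in
the gamma band when frequencies are read as f = 1000 / T Hz.  Voltages,
currents and synaptic strengths are dimensionless, rates are in
spikes / neuron / ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "PopulationParams",
    "SynapticCouplings",
    "DriveProtocol",
    "CrossCoupling",
    "Pulse",
    "pack_params",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


@dataclass(frozen=True)
class PopulationParams:
    """Physical constants of one QIF population.

    ``eta_bar`` and ``delta`` are the center and half-width of the
    Lorentzian distribution of the bias current eta; ``delta = 0`` is the
    homogeneous-network limit.  ``v_th``/``v_reset`` are the finite
    spike cutoff and reset used by the spiking simulator (the reduced
    model corresponds to the limit of both at infinity).
    """

    tau: float = 10.0
    eta_bar: float = -5.0
    delta: float = 1.0
    size: int = 5000
    v_th: float = 500.0
    v_reset: float = -500.0

    def __post_init__(self) -> None:
        _require(self.tau > 0, f"membrane time constant must be > 0, got tau={self.tau}")
        _require(self.delta >= 0, f"half-width must be >= 0, got delta={self.delta}")
        _require(int(self.size) >= 1, f"population size must be >= 1, got size={self.size}")
        _require(
            self.v_reset < self.v_th,
            f"reset must lie below the cutoff, got v_reset={self.v_reset}, v_th={self.v_th}",
        )
        _require(math.isfinite(self.eta_bar), "eta_bar must be finite")


@dataclass(frozen=True)
class SynapticCouplings:
    """Within-circuit synaptic strengths, beta-onto-alpha convention.

    ``j_ab`` is the strength of population ``b`` projecting onto
    population ``a`` (e.g. ``j_ei`` is inhibition felt by the E-cells).
    All four synapses share one first-order filter time ``tau_s``.
    """

    j_ee: float = 0.0
    j_ei: float = 15.0
    j_ie: float = 15.0
    j_ii: float = 0.0
    tau_s: float = 1.0

    def __post_init__(self) -> None:
        _require(self.tau_s > 0, f"synaptic time constant must be > 0, got tau_s={self.tau_s}")
        for name in ("j_ee", "j_ei", "j_ie", "j_ii"):
            _require(math.isfinite(getattr(self, name)), f"{name} must be finite")


@dataclass(frozen=True)
class DriveProtocol:
    """Piecewise-constant external current I_ext(t).

    ``segments`` is a time-ordered tuple of ``(start_time_ms, value)``
    pairs; each value holds from its start time until the next segment's
    start (the final one extends to the end of the simulation window).
    """

    segments: tuple[tuple[float, float], ...] = ((0.0, 0.0),)

    def __post_init__(self) -> None:
        segs = tuple((float(t), float(v)) for t, v in self.segments)
        _require(len(segs) >= 1, "drive protocol needs at least one segment")
        starts = [t for t, _ in segs]
        _require(starts[0] <= 0.0, "first drive segment must start at (or before) t = 0")
        _require(
            all(b > a for a, b in zip(starts, starts[1:])),
            "drive segment start times must be strictly increasing",
        )
        object.__setattr__(self, "segments", segs)

    @classmethod
    def constant(cls, value: float) -> "DriveProtocol":
        return cls(((0.0, float(value)),))

    def value_at(self, t: float) -> float:
        v = self.segments[0][1]
        for start, val in self.segments:
            if t >= start:
                v = val
            else:
                break
        return v

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        starts = np.array([t for t, _ in self.segments], dtype=float)
        values = np.array([v for _, v in self.segments], dtype=float)
        return starts, values


def merge_drives(
    drive_e: DriveProtocol, drive_i: DriveProtocol
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Union of the two protocols' breakpoints with aligned values."""
    starts = np.unique(
        np.concatenate([drive_e.as_arrays()[0], drive_i.as_arrays()[0]])
    )
    e_vals = np.array([drive_e.value_at(t) for t in starts])
    i_vals = np.array([drive_i.value_at(t) for t in starts])
    return starts, e_vals, i_vals


# raised above this cross-coupling strength the weakly-coupled-oscillator
# reduction is extrapolating; analysis proceeds but results carry the flag
WEAK_COUPLING_THRESHOLD = 0.5


@dataclass(frozen=True)
class CrossCoupling:
    """Cross-circuit coupling: pyramidal axons only, with conduction delay.

    ``g_ee`` (onto E-cells) and ``g_ie`` (onto I-cells) are the strengths
    of the long-range projections from the other circuit's E-cells;
    ``delay`` is the conduction delay d in ms.
    """

    g_ee: float = 0.0
    g_ie: float = 0.0
    delay: float = 0.0
    weak_threshold: float = WEAK_COUPLING_THRESHOLD

    def __post_init__(self) -> None:
        _require(self.g_ee >= 0 and self.g_ie >= 0, "cross-coupling strengths must be >= 0")
        _require(self.delay >= 0, f"delay must be >= 0, got d={self.delay}")

    @property
    def extrapolated(self) -> bool:
        """True when the coupling exceeds the weak-coupling trust region."""
        return max(self.g_ee, self.g_ie) > self.weak_threshold


@dataclass(frozen=True)
class Pulse:
    """Square current pulse used for direct phase-resetting measurements."""

    amplitude: float = 1.0
    duration: float = 0.1
    population: str = "e"

    def __post_init__(self) -> None:
        _require(self.duration > 0, f"pulse duration must be > 0, got {self.duration}")
        _require(self.population in ("e", "i"), "pulse population must be 'e' or 'i'")

    @property
    def charge(self) -> float:
        return self.amplitude * self.duration


def pack_params(
    e: PopulationParams, i: PopulationParams, c: SynapticCouplings
) -> np.ndarray:
    """Pack circuit constants into the flat vector the numba kernels take.

    Layout: [tau_e, delta_e, eta_e, tau_i, delta_i, eta_i, tau_s,
             j_ee, j_ei, j_ie, j_ii]
    """
    return np.array(
        [e.tau, e.delta, e.eta_bar, i.tau, i.delta, i.eta_bar,
         c.tau_s, c.j_ee, c.j_ei, c.j_ie, c.j_ii],
        dtype=np.float64,
    )
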