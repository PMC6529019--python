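"""Weakly-coupled-oscillator reduction of two interacting circuits.

Two identical gamma circuits exchanging weak, delayed excitatory
projections reduce to a single equation for their phase lag theta:

    d theta / dt = G(theta) = H(theta - d) - H(-theta - d)

where d is the conduction delay and the interaction function

    H(theta) = (G_ee / T) int_0^T Z_see(s) r_e(s - theta) ds
             + (G_ie / T) int_0^T Z_sie(s) r_e(s - theta) ds

averages the effect of the presynaptic E-rate on the other circuit's
phase over one cycle.  Zeros of G are the phase-locking modes; a zero is
stable iff G' < 0 there.  By construction G(0) = G(T/2) = 0 for every
delay, so in-phase and anti-phase locking always exist — the delay
decides their stability and can stabilize intermediate, symmetry-broken
lags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridMismatchError, InvalidParameterError
from .meanfield import LimitCycle
from .params import CrossCoupling
from .prc import AdjointPRC

__all__ = [
    "HFunction",
    "GFunction",
    "LockingMode",
    "interaction_basis",
    "interaction_function",
    "coupling_function",
    "locking_modes",
    "locking_bifurcation",
]

MARGINAL_SLOPE_TOL = 1e-8


def _circular_interp(samples: np.ndarray, period: float, theta) -> np.ndarray:
    """Periodic linear interpolation of uniform samples at arbitrary theta."""
    m = samples.shape[0]
    u = (np.asarray(theta, dtype=float) % period) / period * m
    j = np.floor(u).astype(int) % m
    x = u - np.floor(u)
    return (1.0 - x) * samples[j] + x * samples[(j + 1) % m]


@dataclass
class HFunction:
    """Sampled interaction function H(theta) on a uniform period grid."""

    period: float
    values: np.ndarray
    g_ee: float
    g_ie: float

    @property
    def thetas(self) -> np.ndarray:
        return np.arange(self.values.size) * self.period / self.values.size

    def __call__(self, theta):
        return _circular_interp(self.values, self.period, theta)


@dataclass
class GFunction:
    """G(theta) = H(theta + d) - H(-theta + d); zeros are locking modes.

    With H(theta) the cycle average of Z_s(s) r_e(s - theta), averaging
    the delay-coupled pair gives the phase-difference drift
    G(theta) = H(theta + d) - H(-theta + d): the conduction delay shifts
    the interaction function by +d in this argument convention.  (The
    opposite shift direction, sometimes quoted, disagrees with direct
    integration of the delayed pair; see docs/methods.md.)  G is odd in
    theta for every d, and G(0) = G(T/2) = 0 identically.
    """

    h: HFunction
    delay: float

    @property
    def period(self) -> float:
        return self.h.period

    def __call__(self, theta):
        return self.h(np.asarray(theta, dtype=float) + self.delay) \
            - self.h(-np.asarray(theta, dtype=float) + self.delay)

    def sample(self, n: int = 1024) -> tuple[np.ndarray, np.ndarray]:
        th = np.arange(n) * self.period / n
        return th, self(th)

    def slope(self, theta: float, h_frac: float = 1e-4) -> float:
        h = self.period * h_frac
        return float((self(theta + h) - self(theta - h)) / (2.0 * h))


def interaction_basis(
    adjoint: AdjointPRC, cycle: LimitCycle
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-coupling interaction integrals (H_ee, H_ie) on the cycle grid.

    H_ee[k] = (1/M) sum_j Z_see[j] r_e[j - k], the cross-correlation of
    the synaptic adjoint component with the E-rate; on the uniform
    periodic grid this rectangle sum coincides with the trapezoid rule.
    H is linear in (G_ee, G_ie), so these two basis curves suffice.
    """
    if adjoint.n_samples != cycle.n_samples:
        raise GridMismatchError(
            f"adjoint grid ({adjoint.n_samples}) != cycle grid ({cycle.n_samples})"
        )
    if abs(adjoint.period - cycle.period) > 1e-9 * cycle.period:
        raise GridMismatchError("adjoint and cycle periods differ")
    m = cycle.n_samples
    re = cycle.states[:, 0]
    j = np.arange(m)
    shift_mat = re[(j[:, None] - j[None, :]) % m]  # [j, k] -> r_e[j - k]
    h_ee = adjoint.z[:, 2] @ shift_mat / m
    h_ie = adjoint.z[:, 6] @ shift_mat / m
    return h_ee, h_ie


def interaction_function(
    adjoint: AdjointPRC,
    cycle: LimitCycle,
    cross: CrossCoupling,
    rescale_by_tau_s: bool = False,
    basis: tuple[np.ndarray, np.ndarray] | None = None,
) -> HFunction:
    """H(theta) for the given cross-coupling strengths.

    ``rescale_by_tau_s`` divides by tau_s, the factor a conventional
    averaging of the synaptic equations would add; at the canonical
    tau_s = 1 ms both conventions coincide, and the default follows the
    H-function exactly as stated above.
    """
    if basis is None:
        basis = interaction_basis(adjoint, cycle)
    h_ee, h_ie = basis
    vals = cross.g_ee * h_ee + cross.g_ie * h_ie
    if rescale_by_tau_s:
        vals = vals / cycle.couplings.tau_s
    return HFunction(period=cycle.period, values=vals,
                     g_ee=cross.g_ee, g_ie=cross.g_ie)


def coupling_function(h: HFunction, delay: float) -> GFunction:
    """Odd part of the delay-shifted interaction function."""
    if delay < 0:
        raise InvalidParameterError(f"delay must be >= 0, got {delay}")
    return GFunction(h=h, delay=float(delay))


@dataclass
class LockingMode:
    """One zero of G: a candidate steady-state phase lag."""

    theta: float          # in [0, T)
    slope: float          # G'(theta)
    stable: bool
    marginal: bool

    def as_fraction(self, period: float) -> float:
        return self.theta / period


def locking_modes(g: GFunction, n_grid: int = 2048) -> list[LockingMode]:
    """All zeros of G over one period with their stability.

    Sign changes on a dense grid are polished by bisection; theta = 0 and
    theta = T/2 (exact zeros for every delay) are always included.
    Zeros with |G'| below the marginal tolerance are flagged rather than
    classified.
    """
    if n_grid < 512:
        raise InvalidParameterError("G must be sampled on >= 512 points")
    T = g.period
    th, gv = g.sample(n_grid)
    zeros: list[float] = [0.0, 0.5 * T]
    for k in range(n_grid):
        a, b = th[k], th[(k + 1) % n_grid] if k + 1 < n_grid else T
        fa, fb = gv[k], gv[(k + 1) % n_grid]
        if fa == 0.0 or fa * fb >= 0.0:
            continue
        lo, hi, flo = a, b, fa
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            fm = float(g(mid))
            if abs(fm) < 1e-10:
                lo = hi = mid
                break
            if flo * fm < 0:
                hi = mid
            else:
                lo, flo = mid, fm
        zeros.append(0.5 * (lo + hi))
    # dedupe against the structural zeros and each other
    zeros_sorted: list[float] = []
    for z in sorted(z % T for z in zeros):
        if not zeros_sorted or min(abs(z - zeros_sorted[-1]),
                                   T - abs(z - zeros_sorted[-1])) > T / 1000.0:
            zeros_sorted.append(z)
    if len(zeros_sorted) > 1 and (T - zeros_sorted[-1]) + zeros_sorted[0] < T / 1000.0:
        zeros_sorted.pop()
    modes = []
    for z in zeros_sorted:
        sl = g.slope(z)
        modes.append(LockingMode(theta=float(z), slope=sl, stable=bool(sl < 0),
                                 marginal=bool(abs(sl) < MARGINAL_SLOPE_TOL)))
    return modes


@dataclass
class BifurcationRow:
    value: float
    modes: list[LockingMode]

    def stable_thetas(self) -> np.ndarray:
        return np.array([m.theta for m in self.modes if m.stable and not m.marginal])


def locking_bifurcation(
    adjoint: AdjointPRC,
    cycle: LimitCycle,
    base: CrossCoupling,
    scan_parameter: str,
    value_grid,
    n_grid: int = 2048,
) -> list[BifurcationRow]:
    """Locking modes while scanning the delay or one coupling strength.

    The two interaction basis curves are computed once; H is rebuilt only
    when a coupling strength changes, and only the shift changes with d.
    """
    if scan_parameter not in ("d", "delay", "g_ee", "g_ie"):
        raise InvalidParameterError(
            f"scan parameter must be one of d, g_ee, g_ie; got {scan_parameter!r}"
        )
    grid = np.asarray(value_grid, dtype=float)
    basis = interaction_basis(adjoint, cycle)
    rows: list[BifurcationRow] = []
    h = interaction_function(adjoint, cycle, base, basis=basis)
    for v in grid:
        if scan_parameter in ("d", "delay"):
            g = coupling_function(h, float(v))
        else:
            kw = {"g_ee": base.g_ee, "g_ie": base.g_ie, "delay": base.delay}
            kw[scan_parameter] = float(v)
            cc = CrossCoupling(**kw)
            g = coupling_function(
                interaction_function(adjoint, cycle, cc, basis=basis), base.delay
            )
        rows.append(BifurcationRow(value=float(v), modes=locking_modes(g, n_grid)))
    return rows
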