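"""Exact firing-rate reduction of one E-I QIF circuit.

In the thermodynamic limit, a QIF population with Lorentzian-distributed
bias current is described exactly by two ODEs for its firing rate r(t)
and mean voltage V(t).  With first-order synapses the full E-I circuit
becomes the 8-dimensional system integrated here:

    tau_e dr_e/dt = Delta_e / (pi tau_e) + 2 r_e V_e
    tau_e dV_e/dt = V_e^2 + eta_e + I_e - (pi tau_e r_e)^2
    tau_s ds_ab/dt = -s_ab + J_ab r_b          (a, b in {e, i})

with I_e = I_ext^e + tau_e (s_ee - s_ei) and the analogous inhibitory
half.  This module provides the vector field, a fixed-step RK4
integrator, fixed points with their linear stability, limit cycles with
a refined period, and one- and two-parameter bifurcation scans.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from . import _kernels
from .errors import (
    InvalidParameterError,
    NoCycleError,
    NumericalBlowupError,
    RootNotFoundError,
)
from .params import (
    DriveProtocol,
    PopulationParams,
    SynapticCouplings,
    merge_drives,
    pack_params,
)

__all__ = [
    "STATE_LABELS",
    "Trajectory",
    "FixedPoint",
    "LimitCycle",
    "BranchPoint",
    "mf_vector_field",
    "linearization_matrix",
    "integrate_mf",
    "find_fixed_point",
    "find_limit_cycle",
    "bifurcation_scan_1d",
    "stability_region",
    "count_hopf_transitions",
]

#: component order of the reduced state vector O(t)
STATE_LABELS = ("r_e", "V_e", "s_ee", "s_ei", "r_i", "V_i", "s_ie", "s_ii")

#: eigenvalue real parts below this magnitude are reported as marginal
MARGINAL_EIG_TOL = 1e-8


def _as_drive(drive) -> DriveProtocol:
    if isinstance(drive, DriveProtocol):
        return drive
    return DriveProtocol.constant(float(drive))


def mf_vector_field(
    state: np.ndarray,
    e_params: PopulationParams,
    i_params: PopulationParams,
    couplings: SynapticCouplings,
    drive_values: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Time derivative of the 8-dimensional reduced state."""
    p = pack_params(e_params, i_params, couplings)
    return _kernels.mf_rhs(
        np.asarray(state, dtype=float), p, float(drive_values[0]), float(drive_values[1])
    )


def linearization_matrix(
    state: np.ndarray,
    e_params: PopulationParams,
    i_params: PopulationParams,
    couplings: SynapticCouplings,
) -> np.ndarray:
    """Jacobian M of the reduced E-I field at ``state`` (8 x 8).

    The drive enters the field additively, so M does not depend on it.
    """
    re, ve, _, _, ri, vi, _, _ = np.asarray(state, dtype=float)
    te, ti, ts = e_params.tau, i_params.tau, couplings.tau_s
    m = np.zeros((8, 8))
    m[0, 0] = 2.0 * ve / te
    m[0, 1] = 2.0 * re / te
    m[1, 0] = -2.0 * te * np.pi**2 * re
    m[1, 1] = 2.0 * ve / te
    m[1, 2] = 1.0
    m[1, 3] = -1.0
    m[2, 0] = couplings.j_ee / ts
    m[2, 2] = -1.0 / ts
    m[3, 4] = couplings.j_ei / ts
    m[3, 3] = -1.0 / ts
    m[4, 4] = 2.0 * vi / ti
    m[4, 5] = 2.0 * ri / ti
    m[5, 4] = -2.0 * ti * np.pi**2 * ri
    m[5, 5] = 2.0 * vi / ti
    m[5, 6] = 1.0
    m[5, 7] = -1.0
    m[6, 0] = couplings.j_ie / ts
    m[6, 6] = -1.0 / ts
    m[7, 4] = couplings.j_ii / ts
    m[7, 7] = -1.0 / ts
    return m


@dataclass
class Trajectory:
    """Uniformly sampled reduced-model trajectory."""

    t: np.ndarray
    states: np.ndarray  # (n, 8)
    step: float

    @property
    def r_e(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def r_i(self) -> np.ndarray:
        return self.states[:, 4]


def integrate_mf(
    initial: np.ndarray,
    e_params: PopulationParams,
    i_params: PopulationParams,
    couplings: SynapticCouplings,
    drive_e=0.0,
    drive_i=0.0,
    duration: float = 300.0,
    step: float = 0.01,
    save_stride: int = 1,
) -> Trajectory:
    """Fixed-step RK4 integration under piecewise-constant drive.

    Drive-segment boundaries are snapped to the step grid, so each
    constant-drive stretch is integrated exactly as an autonomous system.
    """
    if step <= 0:
        raise InvalidParameterError(f"step must be > 0, got {step}")
    p = pack_params(e_params, i_params, couplings)
    starts, e_vals, i_vals = merge_drives(_as_drive(drive_e), _as_drive(drive_i))
    n_total = int(round(duration / step))
    bounds = [int(round(max(t, 0.0) / step)) for t in starts] + [n_total]
    bounds[0] = 0
    y = np.asarray(initial, dtype=float).copy()
    chunks = [y[None, :]]
    for k in range(len(starts)):
        n_seg = bounds[k + 1] - bounds[k]
        if n_seg <= 0:
            continue
        stride = save_stride if n_seg % save_stride == 0 else 1
        path, y, blow = _kernels.rk4_const(
            y, p, e_vals[k], i_vals[k], step, n_seg, stride
        )
        if blow >= 0:
            raise NumericalBlowupError((bounds[k] + blow) * step)
        chunks.append(path[1:])
    states = np.concatenate(chunks, axis=0)
    t = np.arange(states.shape[0]) * step * save_stride
    if save_stride > 1:
        # mixed strides can occur when a segment did not divide evenly
        t = np.linspace(0.0, (states.shape[0] - 1) * duration / max(states.shape[0] - 1, 1), states.shape[0])
    return Trajectory(t=t, states=states, step=step * save_stride)


@dataclass
class FixedPoint:
    state: np.ndarray
    eigenvalues: np.ndarray
    residual: float

    @property
    def stable(self) -> bool:
        return bool(np.all(self.eigenvalues.real < 0.0))

    @property
    def marginal(self) -> bool:
        return bool(np.any(np.abs(self.eigenvalues.real) < MARGINAL_EIG_TOL))

    @property
    def oscillatory_unstable(self) -> bool:
        """Unstable through a complex-conjugate pair (Hopf-type instability)."""
        lam = self.eigenvalues
        return bool(np.any((lam.real > 0.0) & (np.abs(lam.imag) > 1e-12)))


def _default_seed_state(couplings: SynapticCouplings) -> np.ndarray:
    r0 = 0.05
    return np.array(
        [r0, -1.0, couplings.j_ee * r0, couplings.j_ei * r0,
         r0, -1.0, couplings.j_ie * r0, couplings.j_ii * r0]
    )


def find_fixed_point(
    e_params: PopulationParams,
    i_params: PopulationParams,
    couplings: SynapticCouplings,
    drive_values: tuple[float, float] = (0.0, 0.0),
    guess: np.ndarray | None = None,
    residual_tol: float = 1e-10,
) -> FixedPoint:
    """Root of the reduced field with the eigenvalues of its linearization.

    Falls back to a multi-start strategy (trajectory endpoints after a
    200 ms transient plus the trajectory time-average, which sits inside
    any limit cycle) when the direct search from ``guess`` fails.
    """
    p = pack_params(e_params, i_params, couplings)
    ie, ii = float(drive_values[0]), float(drive_values[1])

    def fun(y):
        return _kernels.mf_rhs(y, p, ie, ii)

    candidates: list[np.ndarray] = []
    if guess is not None:
        candidates.append(np.asarray(guess, dtype=float))
    seed = _default_seed_state(couplings)
    candidates.append(seed)
    for y in list(candidates):
        sol = optimize.root(fun, y, method="hybr", tol=1e-13)
        res = float(np.max(np.abs(fun(sol.x))))
        if sol.success and res < residual_tol and sol.x[0] > -1e-12:
            return _finish_fixed_point(sol.x, res, e_params, i_params, couplings)
    # multi-start fallback: endpoints after a transient, plus cycle averages
    scales = [0.2, 0.5, 1.0, 2.0]
    extra: list[np.ndarray] = []
    for sc in scales:
        _, y_end, blow = _kernels.rk4_const(seed * sc, p, ie, ii, 0.01, 20000, 20000)
        if blow < 0 and np.all(np.isfinite(y_end)):
            extra.append(y_end)
            path, _, blow2 = _kernels.rk4_const(y_end, p, ie, ii, 0.01, 20000, 10)
            if blow2 < 0:
                extra.append(path.mean(axis=0))
    for y in extra:
        sol = optimize.root(fun, y, method="hybr", tol=1e-13)
        res = float(np.max(np.abs(fun(sol.x))))
        if sol.success and res < residual_tol and sol.x[0] > -1e-12:
            return _finish_fixed_point(sol.x, res, e_params, i_params, couplings)
    raise RootNotFoundError(
        f"no fixed point found at drive={drive_values} from the guess or multi-start grid"
    )


def _finish_fixed_point(x, res, e_params, i_params, couplings) -> FixedPoint:
    lam = np.linalg.eigvals(linearization_matrix(x, e_params, i_params, couplings))
    return FixedPoint(state=x, eigenvalues=lam, residual=res)


@dataclass
class LimitCycle:
    """Periodic orbit sampled on a uniform grid, phase 0 at the r_e maximum."""

    period: float
    states: np.ndarray  # (n_samples, 8)
    derivs: np.ndarray  # vector field at each sample
    residual: float     # relative closure error |O(T) - O(0)|
    e_params: PopulationParams
    i_params: PopulationParams
    couplings: SynapticCouplings
    drive_values: tuple[float, float]

    @property
    def n_samples(self) -> int:
        return self.states.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.period / self.n_samples

    @property
    def phases(self) -> np.ndarray:
        return np.arange(self.n_samples) * 2.0 * np.pi / self.n_samples

    @property
    def frequency_hz(self) -> float:
        """f = 1000 / T with the millisecond time convention."""
        return 1000.0 / self.period

    @property
    def r_e(self) -> np.ndarray:
        return self.states[:, 0]


def _rk4_partial(y, p, ie, ii, dt):
    path, y1, _ = _kernels.rk4_const(y, p, ie, ii, dt, 1, 1)
    return y1


def _newton_crossing(y_prev, p, ie, ii, level, dt_guess, step):
    """Time (from y_prev) at which r_e crosses ``level`` upward, via Newton.

    y_prev is the state at the grid point immediately before the crossing;
    dr_e/dt is available exactly from the vector field.
    """
    delta = dt_guess
    y_c = y_prev
    for _ in range(6):
        delta = min(max(delta, 0.0), 2.0 * step)
        y_c = _rk4_partial(y_prev, p, ie, ii, delta) if delta > 0 else y_prev.copy()
        f = y_c[0] - level
        fp = _kernels.mf_rhs(y_c, p, ie, ii)[0]
        if fp == 0.0:
            break
        dnew = delta - f / fp
        if abs(dnew - delta) < 1e-14:
            delta = dnew
            break
        delta = dnew
    delta = min(max(delta, 0.0), 2.0 * step)
    y_c = _rk4_partial(y_prev, p, ie, ii, delta) if delta > 0 else y_prev.copy()
    return delta, y_c


def find_limit_cycle(
    e_params: PopulationParams,
    i_params: PopulationParams,
    couplings: SynapticCouplings,
    drive_values: tuple[float, float] = (0.0, 0.0),
    n_samples: int = 1024,
    step: float = 0.01,
    transient: float = 2000.0,
    initial: np.ndarray | None = None,
    return_tol: float = 1e-6,
) -> LimitCycle:
    """Locate the stable limit cycle via a Poincare section on r_e.

    After a transient the section (upward crossing of r_e through its
    time mean) is refined by Newton iterations that use the exact
    dr_e/dt, the return time is iterated until successive returns agree
    to ``return_tol`` (relative), and the orbit is resampled on
    ``n_samples`` uniform points with phase 0 anchored at the r_e
    maximum.
    """
    p = pack_params(e_params, i_params, couplings)
    ie, ii = float(drive_values[0]), float(drive_values[1])
    y0 = np.asarray(initial, dtype=float) if initial is not None else _default_seed_state(couplings)
    n_tr = int(round(transient / step))
    _, y, blow = _kernels.rk4_const(y0, p, ie, ii, step, n_tr, n_tr)
    if blow >= 0:
        raise NumericalBlowupError(blow * step)
    n_obs = int(round(600.0 / step))
    path, y_end, blow = _kernels.rk4_const(y, p, ie, ii, step, n_obs, 1)
    if blow >= 0:
        raise NumericalBlowupError(transient + blow * step)
    re = path[:, 0]
    tail = re[n_obs // 3:]
    if np.ptp(tail) < 1e-8 * max(1e-12, abs(float(np.mean(tail)))) or np.ptp(tail) < 1e-12:
        raise NoCycleError("trajectory converged to a fixed point (no oscillation)")
    level = float(np.mean(tail))
    up = np.where((re[:-1] < level) & (re[1:] >= level))[0]
    if up.size < 4:
        raise NoCycleError("fewer than four section crossings; no sustained oscillation")
    # coarse period from the last crossings
    t_cross = up + (level - re[up]) / (re[up + 1] - re[up])
    t0_coarse = float(np.median(np.diff(t_cross[-4:]))) * step
    # refined anchor on the section
    idx = up[-1]
    frac = (level - re[idx]) / (re[idx + 1] - re[idx]) * step
    _, y_s = _newton_crossing(path[idx], p, ie, ii, level, frac, step)
    # refine the return time: integrate ~1 period, land on the section
    period = t0_coarse
    prev_period = np.inf
    for _ in range(12):
        n_whole = int((0.75 * period) / step)
        _, y_a, _ = _kernels.rk4_const(y_s, p, ie, ii, step, n_whole, n_whole)
        t_acc = n_whole * step
        # walk forward to the next upward crossing
        found = False
        y_prev = y_a
        for _ in range(int(0.75 * period / step) + 10):
            y_nxt = _rk4_partial(y_prev, p, ie, ii, step)
            if y_prev[0] < level <= y_nxt[0]:
                frac = (level - y_prev[0]) / (y_nxt[0] - y_prev[0]) * step
                dtt, y_new = _newton_crossing(y_prev, p, ie, ii, level, frac, step)
                period_new = t_acc + dtt
                found = True
                break
            y_prev = y_nxt
            t_acc += step
        if not found:
            raise NoCycleError("lost the Poincare section while refining the period")
        if abs(period_new - period) < return_tol * period and abs(period - prev_period) < return_tol * period:
            period = period_new
            y_s = y_new
            break
        prev_period = period
        period = period_new
        y_s = y_new
    # anchor the phase at the r_e maximum: coarse scan then Newton on dr_e/dt
    n_scan = 2048
    sub = max(1, int(np.ceil((period / n_scan) / step)))
    dt_scan = period / (n_scan * sub)
    scan, _, _ = _kernels.rk4_const(y_s, p, ie, ii, dt_scan, n_scan * sub, sub)
    j_max = int(np.argmax(scan[:-1, 0]))
    y_p = scan[j_max]
    for _ in range(4):
        f = _kernels.mf_rhs(y_p, p, ie, ii)
        # d2 r_e/dt2 = 2 (r_e' V_e + r_e V_e') / tau_e
        d2 = 2.0 * (f[0] * y_p[1] + y_p[0] * f[1]) / e_params.tau
        if d2 == 0.0:
            break
        dtt = -f[0] / d2
        dtt = float(np.clip(dtt, -5 * dt_scan, 5 * dt_scan))
        if dtt > 0:
            y_p = _rk4_partial(y_p, p, ie, ii, dtt)
        elif dtt < 0:
            # step forward by T + dtt instead of backwards
            n_b = int((period + dtt) / dt_scan)
            _, y_p, _ = _kernels.rk4_const(y_p, p, ie, ii, dt_scan, n_b, n_b)
            rem = (period + dtt) - n_b * dt_scan
            if rem > 0:
                y_p = _rk4_partial(y_p, p, ie, ii, rem)
        if abs(dtt) < 1e-12:
            break
    # resample one period on the uniform grid
    sub = max(1, int(np.ceil((period / n_samples) / step)))
    dt_s = period / (n_samples * sub)
    samples, y_T, _ = _kernels.rk4_const(y_p, p, ie, ii, dt_s, n_samples * sub, sub)
    states = samples[:-1].copy()
    amp = np.maximum(np.ptp(states, axis=0), 1e-12)
    residual = float(np.max(np.abs(y_T - y_p) / amp))
    derivs = np.empty_like(states)
    for k in range(states.shape[0]):
        derivs[k] = _kernels.mf_rhs(states[k], p, ie, ii)
    return LimitCycle(
        period=period, states=states, derivs=derivs, residual=residual,
        e_params=e_params, i_params=i_params, couplings=couplings,
        drive_values=(ie, ii),
    )


@dataclass
class BranchPoint:
    value: float
    state: np.ndarray | None
    eigenvalues: np.ndarray | None
    stable: bool | None
    re_range: tuple[float, float] | None = None
    ri_range: tuple[float, float] | None = None
    error: str | None = None

    @property
    def marginal(self) -> bool:
        if self.eigenvalues is None:
            return False
        return bool(np.any(np.abs(self.eigenvalues.real) < MARGINAL_EIG_TOL))


def _apply_scan(e_params, i_params, drive, name, value):
    """Return (e_params, i_params, drive_values) with one scan knob set."""
    ie, ii = drive
    if name == "i_ext_e":
        ie = value
    elif name == "i_ext_i":
        ii = value
    elif name == "i_ext_both":
        ie = ii = value
    elif name == "delta" or name == "delta_both":
        e_params = replace(e_params, delta=value)
        i_params = replace(i_params, delta=value)
    elif name == "delta_e":
        e_params = replace(e_params, delta=value)
    elif name == "delta_i":
        i_params = replace(i_params, delta=value)
    else:
        raise InvalidParameterError(f"unknown scan parameter {name!r}")
    return e_params, i_params, (ie, ii)


def bifurcation_scan_1d(
    e_params: PopulationParams,
    i_params: PopulationParams,
    couplings: SynapticCouplings,
    drive_values: tuple[float, float],
    scan_parameter: str,
    value_grid: Sequence[float],
    cycle_extrema: bool = True,
) -> list[BranchPoint]:
    """Fixed point, stability and (where unstable) oscillation extrema per value.

    Roots are continued along the grid (the previous root seeds the next
    search).  Oscillation extrema come from the tail of a direct
    integration, which is cheap and robust arbitrarily close to onset.
    """
    grid = np.asarray(value_grid, dtype=float)
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise InvalidParameterError("scan grid must be strictly increasing")
    points: list[BranchPoint] = []
    guess = None
    for v in grid:
        ep, ip, dv = _apply_scan(e_params, i_params, drive_values, scan_parameter, v)
        try:
            fp = find_fixed_point(ep, ip, couplings, dv, guess=guess)
        except RootNotFoundError as exc:
            points.append(BranchPoint(value=float(v), state=None, eigenvalues=None,
                                      stable=None, error=str(exc)))
            continue
        guess = fp.state
        bp = BranchPoint(value=float(v), state=fp.state, eigenvalues=fp.eigenvalues,
                         stable=fp.stable)
        if cycle_extrema and not fp.stable:
            p = pack_params(ep, ip, couplings)
            seed = _default_seed_state(couplings)
            _, y_end, blow = _kernels.rk4_const(seed, p, dv[0], dv[1], 0.01, 80000, 80000)
            if blow < 0:
                tail, _, blow2 = _kernels.rk4_const(y_end, p, dv[0], dv[1], 0.01, 40000, 10)
                if blow2 < 0:
                    bp.re_range = (float(tail[:, 0].min()), float(tail[:, 0].max()))
                    bp.ri_range = (float(tail[:, 4].min()), float(tail[:, 4].max()))
        points.append(bp)
    return points


def count_hopf_transitions(points: Sequence[BranchPoint]) -> int:
    """Number of stable <-> unstable changes along a branch scan."""
    flags = [p.stable for p in points if p.stable is not None]
    return int(sum(1 for a, b in zip(flags, flags[1:]) if a != b))


def stability_region(
    e_params: PopulationParams,
    i_params: PopulationParams,
    couplings: SynapticCouplings,
    drive_grid: Sequence[float],
    heterogeneity_grid: Sequence[float],
    drive_axis: str = "i_ext_e",
    heterogeneity_axis: str = "delta_both",
) -> np.ndarray:
    """Boolean oscillation map over (drive, heterogeneity).

    Entry [i, j] is True when the fixed point at drive_grid[j],
    heterogeneity_grid[i] is unstable through a complex pair.
    """
    dg = np.asarray(drive_grid, dtype=float)
    hg = np.asarray(heterogeneity_grid, dtype=float)
    if (dg.size > 1 and np.any(np.diff(dg) <= 0)) or (hg.size > 1 and np.any(np.diff(hg) <= 0)):
        raise InvalidParameterError("stability-region grids must be strictly increasing")
    out = np.zeros((hg.size, dg.size), dtype=bool)
    for i, h in enumerate(hg):
        ep, ip, dv = _apply_scan(e_params, i_params, (0.0, 0.0), heterogeneity_axis, h)
        guess = None
        for j, d in enumerate(dg):
            ep2, ip2, dv2 = _apply_scan(ep, ip, dv, drive_axis, d)
            try:
                fp = find_fixed_point(ep2, ip2, couplings, dv2, guess=guess)
            except RootNotFoundError:
                continue
            guess = fp.state
            out[i, j] = fp.oscillatory_unstable
    return out
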