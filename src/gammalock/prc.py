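"""Macroscopic phase-resetting curves of the reduced limit cycle.

The infinitesimal PRC Z(t) is the 8-component periodic solution of the
adjoint system -dZ/dt = M(t)^T Z along the limit cycle O(t), normalized
so that Z(t) . dO/dt = 2 pi / T at every point.  Its voltage components
predict the phase shift caused by brief current pulses onto the E- or
I-cells; the synaptic components enter the inter-circuit interaction
function.  The direct method — apply a square pulse at a given phase and
measure the asymptotic shift of the r_e peaks — validates the adjoint
result and extends it to finite perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import (
    AdjointDivergenceError,
    InvalidParameterError,
    UnsettledShiftError,
)
from .meanfield import LimitCycle, linearization_matrix  # noqa: F401  (re-export)
from .params import DriveProtocol, Pulse, pack_params
from .spiking import simulate_spiking_network

__all__ = [
    "AdjointPRC",
    "DirectPRC",
    "adjoint_iprc",
    "direct_prc",
    "classify_prc",
    "linearization_matrix",
]

Z_LABELS = ("Z_re", "Z_ve", "Z_see", "Z_sei", "Z_ri", "Z_vi", "Z_sie", "Z_sii")


@dataclass
class AdjointPRC:
    """Adjoint iPRC sampled on the limit cycle's uniform phase grid."""

    period: float
    z: np.ndarray                 # (n_samples, 8)
    normalization_residual: float  # max relative deviation of Z.dO from 2pi/T
    periodicity_residual: float    # relative |Z(0) - Z(T)|
    n_periods: int                 # backward periods to convergence

    @property
    def n_samples(self) -> int:
        return self.z.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.period / self.n_samples

    @property
    def phases(self) -> np.ndarray:
        return np.arange(self.n_samples) * 2.0 * np.pi / self.n_samples

    def component(self, label: str) -> np.ndarray:
        return self.z[:, Z_LABELS.index(label)]


def adjoint_iprc(
    cycle: LimitCycle,
    k_sub: int = 4,
    tol: float = 1e-8,
    max_periods: int = 200,
) -> AdjointPRC:
    """Backward adjoint integration with per-period renormalization.

    The adjoint flow is integrated backward over repeated periods (which
    is stable exactly when the cycle is attracting) until the solution
    direction changes by less than ``tol`` per period, then rescaled once
    so the cycle-average of Z . dO/dt equals 2 pi / T.
    """
    p = pack_params(cycle.e_params, cycle.i_params, cycle.couplings)
    z_grid, n_per, converged, phi_end = _kernels.adjoint_backward(
        cycle.states, p, cycle.period, k_sub, max_periods, tol
    )
    if not converged:
        raise AdjointDivergenceError(
            f"adjoint direction not converged after {max_periods} periods "
            "(cycle unstable or marginal?)"
        )
    omega = 2.0 * np.pi / cycle.period
    dots = np.einsum("ij,ij->i", z_grid, cycle.derivs)
    mean_dot = float(np.mean(dots))
    if mean_dot == 0.0:
        raise AdjointDivergenceError("Z . dO/dt vanished; cannot normalize")
    scale = omega / mean_dot
    z = z_grid * scale
    norm_res = float(np.max(np.abs(dots * scale - omega)) / omega)
    zmax = float(np.max(np.abs(z)))
    per_res = float(np.linalg.norm(phi_end * scale - z[0]) / max(zmax, 1e-300))
    return AdjointPRC(period=cycle.period, z=z,
                      normalization_residual=norm_res,
                      periodicity_residual=per_res, n_periods=n_per)


@dataclass
class DirectPRC:
    """Phase shifts from square-pulse perturbations at a grid of onsets."""

    period: float
    onset_phases: np.ndarray   # radians in [0, 2pi)
    shifts_rad: np.ndarray     # positive = phase advance
    pulse: Pulse
    backend: str

    @property
    def shifts_ms(self) -> np.ndarray:
        return self.shifts_rad * self.period / (2.0 * np.pi)

    def scaled_to_iprc(self, tau: float) -> np.ndarray:
        """Shifts divided by the pulse charge / tau, comparable to Z_v."""
        return self.shifts_rad * tau / self.pulse.charge


def _peak_time_near(t: np.ndarray, x: np.ndarray, center: float, half: float) -> float:
    """Parabolically refined local-max time within [center-half, center+half]."""
    lo = np.searchsorted(t, center - half)
    hi = np.searchsorted(t, center + half)
    if hi - lo < 3:
        raise UnsettledShiftError("window too narrow for peak detection")
    j = lo + int(np.argmax(x[lo:hi]))
    if j == 0 or j == x.size - 1:
        return float(t[j])
    y0, y1, y2 = x[j - 1], x[j], x[j + 1]
    denom = y0 - 2 * y1 + y2
    off = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    return float(t[j] + off * (t[1] - t[0]))


def _wrap_half(x: np.ndarray | float, period: float):
    """Map to (-T/2, T/2]."""
    return -((-x + 0.5 * period) % period - 0.5 * period)


def direct_prc(
    cycle: LimitCycle,
    pulse: Pulse,
    n_phases: int = 32,
    backend: str = "reduced",
    n_cycles: int = 25,
    step: float = 0.005,
    settle_tol_fraction: float = 0.01,
    seed: int = 0,
    n_neurons: int | None = None,
) -> DirectPRC:
    """Measure the PRC by pulsing at each onset phase and tracking r_e peaks.

    The asymptotic shift is the mean over the last cycles of the
    perturbed-minus-reference peak-time difference, mapped to
    (-T/2, T/2] and converted to radians; the shift must plateau to
    within ``settle_tol_fraction`` * T across the final five cycles.
    """
    if backend not in ("reduced", "spiking"):
        raise InvalidParameterError(f"unknown backend {backend!r}")
    T = cycle.period
    phases = np.arange(n_phases) * 2.0 * np.pi / n_phases
    if backend == "reduced":
        shifts = _direct_prc_reduced(cycle, pulse, phases, n_cycles, step,
                                     settle_tol_fraction)
    else:
        shifts = _direct_prc_spiking(cycle, pulse, phases, n_cycles, seed,
                                     n_neurons or 5000)
    return DirectPRC(period=T, onset_phases=phases, shifts_rad=shifts,
                     pulse=pulse, backend=backend)


def _run_pulsed_reduced(cycle, pulse_amp, pulse_dur, pulse_pop, t_on, t_end, step):
    """Integrate from the cycle's phase-0 state with an optional pulse; r_e trace."""
    from .meanfield import integrate_mf

    ie, ii = cycle.drive_values
    if pulse_amp != 0.0:
        base = ie if pulse_pop == "e" else ii
        target = ([(0.0, base)] if t_on > 0 else []) + \
            [(t_on, base + pulse_amp), (t_on + pulse_dur, base)]
        other = [(0.0, ii if pulse_pop == "e" else ie)]
        segs_e = target if pulse_pop == "e" else other
        segs_i = other if pulse_pop == "e" else target
        drive_e = DriveProtocol(tuple(segs_e))
        drive_i = DriveProtocol(tuple(segs_i))
    else:
        drive_e, drive_i = ie, ii
    traj = integrate_mf(cycle.states[0], cycle.e_params, cycle.i_params,
                        cycle.couplings, drive_e, drive_i, duration=t_end,
                        step=step)
    return traj.t, traj.r_e


def _direct_prc_reduced(cycle, pulse, phases, n_cycles, step, settle_tol):
    T = cycle.period
    t_end = (n_cycles + 1.5) * T
    t_ref, re_ref = _run_pulsed_reduced(cycle, 0.0, pulse.duration,
                                        pulse.population, 0.0, t_end, step)
    ks = np.arange(n_cycles - 5, n_cycles + 1)
    ref_peaks = np.array([_peak_time_near(t_ref, re_ref, k * T, 0.45 * T) for k in ks])
    shifts = np.empty(phases.size)
    for idx, ph in enumerate(phases):
        if pulse.amplitude == 0.0:
            shifts[idx] = 0.0
            continue
        t_on = ph / (2.0 * np.pi) * T
        # snap the pulse window onto the step grid so segments stay exact
        t_on = round(t_on / step) * step
        t, re = _run_pulsed_reduced(cycle, pulse.amplitude, pulse.duration,
                                    pulse.population, t_on, t_end, step)
        per_cycle = np.empty(ks.size)
        for i, k in enumerate(ks):
            pk = _peak_time_near(t, re, ref_peaks[i], 0.45 * T)
            per_cycle[i] = _wrap_half(ref_peaks[i] - pk, T)
        if np.ptp(per_cycle[-5:]) > settle_tol * T:
            raise UnsettledShiftError(
                f"shift not stationary at onset phase {ph:.3f} rad "
                f"(spread {np.ptp(per_cycle[-5:]):.4f} ms over last 5 cycles)"
            )
        shifts[idx] = 2.0 * np.pi / T * float(np.mean(per_cycle[-3:]))
    return shifts


def _direct_prc_spiking(cycle, pulse, phases, n_cycles, seed, n_neurons):
    """Direct PRC on the finite network (noisy; averaged peak shifts)."""
    from dataclasses import replace

    T = cycle.period
    e_par = replace(cycle.e_params, size=n_neurons)
    i_par = replace(cycle.i_params, size=n_neurons)
    ie, ii = cycle.drive_values
    warm = 300.0
    t_end = warm + (n_cycles + 1.5) * T
    _, ref_trace = simulate_spiking_network(
        e_par, i_par, cycle.couplings, ie, ii, duration=t_end, seed=seed,
        bin_width=0.1, smoothing_sigma=1.0,
    )
    # anchor on the last pre-pulse reference peak after warmup
    t0 = _peak_time_near(ref_trace.t, ref_trace.r_e, warm, 0.6 * T)
    ks = np.arange(n_cycles - 5, n_cycles + 1)
    ref_peaks = np.array([
        _peak_time_near(ref_trace.t, ref_trace.r_e, t0 + k * T, 0.45 * T) for k in ks
    ])
    shifts = np.empty(phases.size)
    for idx, ph in enumerate(phases):
        if pulse.amplitude == 0.0:
            shifts[idx] = 0.0
            continue
        t_on = t0 + ph / (2.0 * np.pi) * T
        base_e, base_i = ie, ii
        if pulse.population == "e":
            drive_e = DriveProtocol(((0.0, base_e), (t_on, base_e + pulse.amplitude),
                                     (t_on + pulse.duration, base_e)))
            drive_i = base_i
        else:
            drive_e = base_e
            drive_i = DriveProtocol(((0.0, base_i), (t_on, base_i + pulse.amplitude),
                                     (t_on + pulse.duration, base_i)))
        _, tr = simulate_spiking_network(
            e_par, i_par, cycle.couplings, drive_e, drive_i, duration=t_end,
            seed=seed, bin_width=0.1, smoothing_sigma=1.0,
        )
        per_cycle = np.empty(ks.size)
        for i, k in enumerate(ks):
            pk = _peak_time_near(tr.t, tr.r_e, ref_peaks[i], 0.45 * T)
            per_cycle[i] = _wrap_half(ref_peaks[i] - pk, T)
        shifts[idx] = 2.0 * np.pi / T * float(np.mean(per_cycle[-3:]))
    return shifts


#: default relative noise floor for PRC typing: lobes below this fraction
#: of the peak magnitude are not counted as a sign lobe.  Direct PRC
#: measurements on finite networks carry a few percent of peak-height
#: noise, so smaller lobes are not observable in practice.
PRC_NOISE_FLOOR_FRACTION = 0.05


def classify_prc(values: np.ndarray, noise_floor: float | None = None) -> str:
    """Label a sampled PRC as 'type I', 'type II' or 'null'.

    Null when nothing exceeds the noise floor; type II (biphasic) when
    both signs do; otherwise type I (monophasic).  When ``noise_floor``
    is omitted it defaults to ``PRC_NOISE_FLOOR_FRACTION`` times the
    peak magnitude (an absolute floor of 1e-12 guards the all-zero case).
    """
    v = np.asarray(values, dtype=float)
    if noise_floor is None:
        noise_floor = max(PRC_NOISE_FLOOR_FRACTION * float(np.max(np.abs(v))),
                          1e-12)
    if float(np.max(np.abs(v))) < noise_floor:
        return "null"
    pos = float(np.max(v)) > noise_floor
    neg = float(-np.min(v)) > noise_floor
    if pos and neg:
        return "type II"
    return "type I"
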