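"""Two delay-coupled E-I circuits: reduced 16-ODE system and twin spiking
networks, phase-lag extraction, leader/follower identification and the
global PRC.

The reduced pair couples two copies of the 8-dimensional circuit through
the delayed E-rate of the partner: G_ee r_e^(2)(t-d) and
G_ie r_e^(2)(t-d) feed circuit 1's s_ee and s_ie equations (and
symmetrically).  In a symmetry-broken locked state the circuit firing
after the longer inter-burst silence is the leader; the global PRC
measures how a pulse onto either circuit shifts the phase of the locked
rhythm as a whole, and its leader/follower asymmetry is the footprint of
directional signal transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    NumericalBlowupError,
)
from .meanfield import LimitCycle
from .params import CrossCoupling, PopulationParams, Pulse, SynapticCouplings, pack_params
from .prc import _peak_time_near, _wrap_half
from .spiking import RateTrace, SpikeRaster, _counts_to_rate, sample_lorentzian, simulate_spiking_network

__all__ = [
    "CoupledTrajectory",
    "LockedState",
    "GlobalPRCResult",
    "simulate_coupled_reduced",
    "simulate_coupled_spiking",
    "extract_phase_lag",
    "identify_leader_follower",
    "settle_locked_state",
    "global_prc",
]


def _delay_steps(delay: float, step_target: float) -> tuple[int, float]:
    """Delay as an exact multiple of the step (h = d / m, m = round(d / h*))."""
    if delay < 0:
        raise InvalidParameterError(f"delay must be >= 0, got {delay}")
    if delay == 0.0:
        return 0, step_target
    m = max(1, int(round(delay / step_target)))
    return m, delay / m


@dataclass
class CoupledTrajectory:
    """Sampled 16-dimensional trajectory of the coupled pair."""

    t: np.ndarray
    states: np.ndarray          # (n, 16)
    delay: float
    step: float
    re1_full: np.ndarray        # r_e histories at full step resolution
    re2_full: np.ndarray        # (index 0 is t = 0)
    final_state: np.ndarray
    final_hist1: np.ndarray     # r_e over the trailing [-d, 0] window
    final_hist2: np.ndarray

    @property
    def r_e1(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def r_e2(self) -> np.ndarray:
        return self.states[:, 8]

    def rate_traces(self) -> tuple[RateTrace, RateTrace]:
        dt = float(self.t[1] - self.t[0])
        tr1 = RateTrace(t=self.t, r_e=self.states[:, 0], r_i=self.states[:, 4],
                        bin_width=dt)
        tr2 = RateTrace(t=self.t, r_e=self.states[:, 8], r_i=self.states[:, 12],
                        bin_width=dt)
        return tr1, tr2


def _history_from_cycle(cycle: LimitCycle, phase_offset_t: float, m: int,
                        h: float) -> tuple[np.ndarray, np.ndarray]:
    """Initial r_e history on [-d, 0] read off the uncoupled cycle."""
    T = cycle.period
    re = cycle.states[:, 0]
    tt = (np.arange(-m, 1) * h)
    hist1 = _interp_cycle(re, T, tt)
    hist2 = _interp_cycle(re, T, tt + phase_offset_t)
    return hist1, hist2


def _interp_cycle(samples: np.ndarray, period: float, tt) -> np.ndarray:
    mm = samples.size
    u = (np.asarray(tt, dtype=float) % period) / period * mm
    j = np.floor(u).astype(int) % mm
    x = u - np.floor(u)
    return (1.0 - x) * samples[j] + x * samples[(j + 1) % mm]


def _cycle_state_at(cycle: LimitCycle, t_off: float) -> np.ndarray:
    out = np.empty(8)
    for c in range(8):
        out[c] = _interp_cycle(cycle.states[:, c], cycle.period,
                               np.array([t_off]))[0]
    return out


def simulate_coupled_reduced(
    cycle: LimitCycle,
    cross: CrossCoupling,
    initial_offset_fraction: float = 0.05,
    duration: float = 2000.0,
    step: float = 0.005,
    save_stride: int = 10,
    pulse: Pulse | None = None,
    pulse_onset: float = 0.0,
    pulse_circuit: int = 0,
    initial_state: np.ndarray | None = None,
    initial_history: tuple[np.ndarray, np.ndarray] | None = None,
) -> CoupledTrajectory:
    """Integrate the 16-ODE delayed pair (RK4, step an exact divisor of d).

    The default initial condition places both circuits on the uncoupled
    limit cycle with circuit 2 advanced by ``initial_offset_fraction`` of
    a period (lag 0 is an invariant manifold, so symmetry-breaking runs
    need a nonzero offset).  A square ``pulse`` can be injected into
    either circuit at ``pulse_onset`` ms.
    """
    m, h = _delay_steps(cross.delay, step)
    p = pack_params(cycle.e_params, cycle.i_params, cycle.couplings)
    ie, ii = cycle.drive_values
    if initial_state is None:
        offset_t = initial_offset_fraction * cycle.period
        y0 = np.concatenate([cycle.states[0], _cycle_state_at(cycle, offset_t)])
        hist1, hist2 = _history_from_cycle(cycle, offset_t, m, h)
    else:
        y0 = np.asarray(initial_state, dtype=float).copy()
        if m > 0:
            if initial_history is None:
                raise InvalidParameterError(
                    "initial_history is required with a custom initial_state and d > 0"
                )
            hist1 = np.asarray(initial_history[0], dtype=float)
            hist2 = np.asarray(initial_history[1], dtype=float)
            if hist1.size != m + 1 or hist2.size != m + 1:
                raise InvalidParameterError(
                    f"history must cover [-d, 0] with {m + 1} samples"
                )
        else:
            hist1 = hist2 = np.array([y0[0]])
    if m == 0:
        hist1 = np.array([y0[0]])
        hist2 = np.array([y0[8]])
    n_steps = int(round(duration / h))
    n_steps -= n_steps % save_stride
    if pulse is not None:
        on = int(round(pulse_onset / h))
        plen = max(1, int(round(pulse.duration / h)))
        amp = pulse.amplitude
        ppop = 0 if pulse.population == "e" else 1
    else:
        on, plen, amp, ppop = 0, 0, 0.0, 0
    out, buf1, buf2, y_fin, blow = _kernels.dde16(
        y0, p, cross.g_ee, cross.g_ie, m, h, n_steps, hist1, hist2,
        ie, ii, save_stride, on, plen, amp, pulse_circuit, ppop,
    )
    if blow >= 0:
        raise NumericalBlowupError(blow * h, what="coupled state")
    t = np.arange(out.shape[0]) * h * save_stride
    return CoupledTrajectory(
        t=t, states=out, delay=cross.delay, step=h * save_stride,
        re1_full=buf1, re2_full=buf2, final_state=y_fin,
        final_hist1=buf1[-(m + 1):], final_hist2=buf2[-(m + 1):],
    )


def simulate_coupled_spiking(
    e_params: PopulationParams,
    i_params: PopulationParams,
    couplings: SynapticCouplings,
    cross: CrossCoupling,
    drive_e: float = 0.0,
    drive_i: float = 0.0,
    duration: float = 1000.0,
    step: float = 0.01,
    seed: int | None = 0,
    initial_offset_fraction: float = 0.05,
    period_hint: float | None = None,
    warmup: float = 300.0,
    bin_width: float = 0.5,
    smoothing_sigma: float = 1.0,
    rate_cap: float = 0.5,
) -> tuple[tuple[SpikeRaster, SpikeRaster], tuple[RateTrace, RateTrace]]:
    """Twin spiking networks with delayed cross-projections.

    Cross spikes from each circuit's E-cells arrive after delay d and
    increment the partner's s_ee / s_ie by G_ab / (N_e tau_s).  The two
    circuits start from snapshots of one uncoupled warmup run taken
    ``initial_offset_fraction`` * T apart, realizing a phase offset.
    """
    m, h = _delay_steps(cross.delay, step)
    if period_hint is None:
        from .meanfield import find_limit_cycle
        period_hint = find_limit_cycle(e_params, i_params, couplings,
                                       (drive_e, drive_i), n_samples=256).period
    offset = initial_offset_fraction * period_hint
    # snapshot the uncoupled network at two times offset ms apart
    _, tr_a = simulate_spiking_network(
        e_params, i_params, couplings, drive_e, drive_i,
        duration=warmup, step=h, seed=seed, rate_cap=rate_cap,
    )
    v_e1, v_i1 = tr_a.extras["final_voltages"]
    s1 = tr_a.extras["final_synapses"]
    _, tr_b = simulate_spiking_network(
        e_params, i_params, couplings, drive_e, drive_i,
        duration=warmup + offset, step=h, seed=seed, rate_cap=rate_cap,
    )
    v_e2, v_i2 = tr_b.extras["final_voltages"]
    s2 = tr_b.extras["final_synapses"]
    eta_e = sample_lorentzian(e_params.eta_bar, e_params.delta, e_params.size,
                              "quantile", seed)
    eta_i = sample_lorentzian(i_params.eta_bar, i_params.delta, i_params.size,
                              "quantile", None if seed is None else seed + 1)
    n_steps = int(round(duration / h))
    cap = int((e_params.size + i_params.size) * duration * rate_cap) + 1000
    sp_t1 = np.empty(cap); sp_id1 = np.empty(cap, dtype=np.int64)
    sp_t2 = np.empty(cap); sp_id2 = np.empty(cap, dtype=np.int64)
    nsp1, nsp2, ce1, ci1, ce2, ci2 = _kernels.coupled_spiking(
        v_e1.copy(), v_i1.copy(), v_e2.copy(), v_i2.copy(), eta_e, eta_i,
        e_params.tau, i_params.tau, couplings.tau_s,
        couplings.j_ee, couplings.j_ei, couplings.j_ie, couplings.j_ii,
        cross.g_ee, cross.g_ie, m,
        e_params.v_th, e_params.v_reset, i_params.v_th, i_params.v_reset,
        drive_e, drive_i, h, n_steps, s1, s2, sp_t1, sp_id1, sp_t2, sp_id2,
    )
    if nsp1 > cap or nsp2 > cap:
        raise InvalidParameterError("spike buffer overflow; raise rate_cap")
    r1 = SpikeRaster(times=sp_t1[:nsp1].copy(), ids=sp_id1[:nsp1].copy(),
                     n_e=e_params.size, n_i=i_params.size, window=(0.0, duration))
    r2 = SpikeRaster(times=sp_t2[:nsp2].copy(), ids=sp_id2[:nsp2].copy(),
                     n_e=e_params.size, n_i=i_params.size, window=(0.0, duration))
    t1 = _counts_to_rate(ce1, ci1, e_params.size, i_params.size, h,
                         bin_width, smoothing_sigma)
    t2 = _counts_to_rate(ce2, ci2, e_params.size, i_params.size, h,
                         bin_width, smoothing_sigma)
    return (r1, r2), (t1, t2)


def _peak_times(t: np.ndarray, x: np.ndarray, period: float) -> np.ndarray:
    """All r_e burst peak times in a trace (refined local maxima)."""
    from scipy.signal import find_peaks

    dt = float(t[1] - t[0])
    dist = max(1, int(0.6 * period / dt))
    height = x.mean() + 0.25 * (x.max() - x.mean())
    idx, _ = find_peaks(x, height=height, distance=dist)
    out = []
    for j in idx:
        if 0 < j < x.size - 1:
            y0, y1, y2 = x[j - 1], x[j], x[j + 1]
            den = y0 - 2 * y1 + y2
            off = 0.0 if den == 0 else 0.5 * (y0 - y2) / den
            out.append(t[j] + off * dt)
        else:
            out.append(t[j])
    return np.asarray(out)


def extract_phase_lag(
    trace1: RateTrace,
    trace2: RateTrace,
    period: float,
    analysis_window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Circular-mean phase lag (t_peak1 - t_peak2) in (-T/2, T/2].

    Pairs each circuit-1 burst peak with the nearest circuit-2 peak over
    the analysis window and returns (lag_ms, circular_std_ms).  A
    positive lag means circuit 1 peaks after circuit 2.
    """
    if analysis_window is None:
        analysis_window = (float(trace1.t[0]), float(trace1.t[-1]))
    lo, hi = analysis_window
    sel1 = (trace1.t >= lo) & (trace1.t <= hi)
    sel2 = (trace2.t >= lo) & (trace2.t <= hi)
    p1 = _peak_times(trace1.t[sel1], trace1.r_e[sel1], period)
    p2 = _peak_times(trace2.t[sel2], trace2.r_e[sel2], period)
    if p1.size < 10 or p2.size < 10:
        raise InsufficientDataError(
            f"need >= 10 oscillation cycles in the window, found {min(p1.size, p2.size)}"
        )
    diffs = []
    for tp in p1:
        k = int(np.argmin(np.abs(p2 - tp)))
        diffs.append(tp - p2[k])
    ang = np.asarray(diffs) * 2.0 * np.pi / period
    z = np.mean(np.exp(1j * ang))
    lag = _wrap_half(float(np.angle(z)) * period / (2.0 * np.pi), period)
    r = min(max(abs(z), 1e-12), 1.0)
    circ_std = float(np.sqrt(-2.0 * np.log(r)) * period / (2.0 * np.pi))
    return float(lag), circ_std


def identify_leader_follower(
    trace1: RateTrace,
    trace2: RateTrace,
    period: float,
    guard_fraction: float = 0.05,
) -> dict:
    """Assign leader / follower labels from the locked firing pattern.

    The leader is the circuit whose burst follows the longer inter-burst
    silence (it opens each volley).  In-phase and anti-phase states
    (within ``guard_fraction`` * T of 0 or T/2) are 'degenerate'.
    """
    lag, q = extract_phase_lag(trace1, trace2, period)
    guard = guard_fraction * period
    if abs(lag) < guard or abs(abs(lag) - 0.5 * period) < guard:
        return {"leader": None, "follower": None, "degenerate": True,
                "lag": lag, "quality": q}
    # positive lag: circuit 1 fires after the short gap -> circuit 2 leads
    leader = 2 if lag > 0 else 1
    return {"leader": leader, "follower": 3 - leader, "degenerate": False,
            "lag": lag, "quality": q}


@dataclass
class LockedState:
    """A settled phase-locked state of the reduced coupled pair."""

    cycle: LimitCycle
    cross: CrossCoupling
    lag: float                  # t_peak1 - t_peak2, ms, in (-T/2, T/2]
    lag_quality: float
    leader: int | None          # 1 or 2; None when degenerate
    state: np.ndarray           # 16-dim state at the end of settling
    hist1: np.ndarray           # trailing r_e histories over [-d, 0]
    hist2: np.ndarray
    step: float

    @property
    def degenerate(self) -> bool:
        return self.leader is None

    def circuit_index(self, which) -> int:
        """Map 'leader' / 'follower' / 1 / 2 to a 0-based circuit index."""
        if which in (1, 2):
            return which - 1
        if self.degenerate:
            # symmetric state: 'leader' defaults to circuit 1
            return 0 if which == "leader" else 1
        return (self.leader if which == "leader" else 3 - self.leader) - 1


def settle_locked_state(
    cycle: LimitCycle,
    cross: CrossCoupling,
    initial_offset_fraction: float = 0.05,
    settle_cycles: float = 300.0,
    step: float = 0.005,
) -> LockedState:
    """Run the reduced pair until the lag is stationary and label the roles.

    Convergence under weak coupling is slow (the lag drifts at rate
    G(theta)), hence the generous default settling horizon.
    """
    T = cycle.period
    traj = simulate_coupled_reduced(
        cycle, cross, initial_offset_fraction=initial_offset_fraction,
        duration=settle_cycles * T, step=step, save_stride=max(1, int(0.1 / step)),
    )
    tr1, tr2 = traj.rate_traces()
    win = (traj.t[-1] - 20.0 * T, traj.t[-1])
    lag, q = extract_phase_lag(tr1, tr2, T, win)
    roles = identify_leader_follower(tr1, tr2, T)
    return LockedState(
        cycle=cycle, cross=cross, lag=lag, lag_quality=q,
        leader=roles["leader"], state=traj.final_state,
        hist1=traj.final_hist1, hist2=traj.final_hist2, step=step,
    )


@dataclass
class GlobalPRCResult:
    """Global phase shifts of the locked pair under pulses to one circuit."""

    period: float
    baseline_lag: float
    onset_phases: np.ndarray
    shifts_rad: np.ndarray         # NaN where the pulse switched the mode
    mode_switch: np.ndarray        # bool per onset phase
    target: str                    # 'leader' / 'follower' / '1' / '2'
    population: str                # 'e' or 'i'
    pulse: Pulse

    @property
    def valid(self) -> np.ndarray:
        return ~self.mode_switch


def global_prc(
    locked: LockedState,
    perturbed_circuit="leader",
    target_population: str = "e",
    pulse: Pulse | None = None,
    n_phases: int = 24,
    n_cycles: int = 30,
    relock_tol_fraction: float = 0.02,
) -> GlobalPRCResult:
    """Direct-perturbation global PRC of the locked two-circuit rhythm.

    For each onset phase (relative to circuit 1's burst peak) a square
    pulse is applied to the chosen circuit and population; the run
    continues ``n_cycles`` periods, the pair must re-lock to the same lag
    (within ``relock_tol_fraction`` * T, else that sample is flagged as a
    mode switch and excluded), and the asymptotic shift of circuit 1's
    burst peaks relative to an unperturbed reference is reported in
    radians (positive = advance).
    """
    if pulse is None:
        pulse = Pulse(amplitude=1.0, duration=0.1, population=target_population)
    else:
        pulse = replace(pulse, population=target_population)
    T = locked.cycle.period
    circuit = locked.circuit_index(perturbed_circuit)
    duration = (n_cycles + 4.0) * T
    common = dict(
        cycle=locked.cycle, cross=locked.cross, duration=duration,
        step=locked.step, save_stride=max(1, int(0.05 / locked.step)),
        initial_state=locked.state,
        initial_history=(locked.hist1, locked.hist2),
    )
    ref = simulate_coupled_reduced(**common)
    tr1_ref, tr2_ref = ref.rate_traces()
    ref_peaks = _peak_times(tr1_ref.t, tr1_ref.r_e, T)
    if ref_peaks.size < n_cycles:
        raise InsufficientDataError("reference run lost its oscillation")
    t_anchor = ref_peaks[1]
    ks = np.arange(n_cycles - 6, n_cycles - 1)
    phases = np.arange(n_phases) * 2.0 * np.pi / n_phases
    shifts = np.full(n_phases, np.nan)
    switched = np.zeros(n_phases, dtype=bool)
    for i, ph in enumerate(phases):
        t_on = t_anchor + ph / (2.0 * np.pi) * T
        traj = simulate_coupled_reduced(
            pulse=pulse, pulse_onset=t_on, pulse_circuit=circuit, **common
        )
        tr1, tr2 = traj.rate_traces()
        # re-lock check on the trailing window
        win = (traj.t[-1] - 10.0 * T, traj.t[-1])
        lag, _ = extract_phase_lag(tr1, tr2, T, win)
        lag_err = min(abs(lag - locked.lag), T - abs(lag - locked.lag))
        if lag_err > relock_tol_fraction * T:
            switched[i] = True
            continue
        per_cycle = np.empty(ks.size)
        ok = True
        for jdx, k in enumerate(ks):
            try:
                pk = _peak_time_near(tr1.t, tr1.r_e, ref_peaks[k], 0.45 * T)
            except Exception:
                ok = False
                break
            per_cycle[jdx] = _wrap_half(ref_peaks[k] - pk, T)
        if not ok:
            switched[i] = True
            continue
        shifts[i] = 2.0 * np.pi / T * float(np.mean(per_cycle))
    return GlobalPRCResult(
        period=T, baseline_lag=locked.lag, onset_phases=phases,
        shifts_rad=shifts, mode_switch=switched,
        target=str(perturbed_circuit), population=target_population, pulse=pulse,
    )
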