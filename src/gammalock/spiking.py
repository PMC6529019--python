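"""Finite-size QIF network simulation.

Each neuron obeys tau dv/dt = eta_j + v^2 + I(t) with instantaneous
reset from the cutoff v_th to v_reset; the bias currents eta_j are
quenched draws (deterministic quantiles by default) from a Lorentzian.
Synapses are population-level first-order filters that jump by
J / (N tau_s) per presynaptic spike and decay exactly between spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from . import _kernels
from .errors import InsufficientDataError, InvalidParameterError
from .params import (
    DriveProtocol,
    PopulationParams,
    SynapticCouplings,
    merge_drives,
)

__all__ = [
    "sample_lorentzian",
    "fraction_non_oscillatory",
    "SpikeRaster",
    "RateTrace",
    "simulate_spiking_network",
    "estimate_rate",
    "oscillation_frequency",
    "qif_rest_voltages",
]


def sample_lorentzian(
    center: float,
    half_width: float,
    count: int,
    mode: str = "quantile",
    seed: int | None = None,
) -> np.ndarray:
    """Quenched bias currents from a Lorentzian of given center / half-width.

    ``mode='quantile'`` returns the deterministic grid
    eta_j = center + half_width * tan(pi/2 * (2j - count - 1) / (count + 1)),
    j = 1..count, which tiles the distribution reproducibly;
    ``mode='random'`` draws i.i.d. Cauchy samples from ``seed``.
    """
    if half_width < 0:
        raise InvalidParameterError(f"half-width must be >= 0, got {half_width}")
    if count < 1:
        raise InvalidParameterError(f"count must be >= 1, got {count}")
    if mode in ("quantile", "deterministic", "deterministic-quantile"):
        j = np.arange(1, count + 1, dtype=float)
        return center + half_width * np.tan(0.5 * np.pi * (2 * j - count - 1) / (count + 1))
    if mode == "random":
        rng = np.random.default_rng(seed)
        return center + half_width * rng.standard_cauchy(count)
    raise InvalidParameterError(f"unknown sampling mode {mode!r}")


def fraction_non_oscillatory(center: float, half_width: float) -> float:
    """Lorentzian mass at eta < 0: neurons with no intrinsic firing.

    Closed form (1/pi) (pi/2 - arctan(center / half_width)); with a
    heavy-tailed excitability distribution this is never zero, so the
    network rhythm is emergent rather than a synchronization of
    intrinsic oscillators.
    """
    if half_width <= 0:
        raise InvalidParameterError(f"half-width must be > 0, got {half_width}")
    return (0.5 * np.pi - np.arctan(center / half_width)) / np.pi


@dataclass
class SpikeRaster:
    """Spike times and neuron ids of one simulation (E ids first)."""

    times: np.ndarray
    ids: np.ndarray
    n_e: int
    n_i: int
    window: tuple[float, float]

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def population_of(self, neuron_id: int) -> str:
        return "e" if neuron_id < self.n_e else "i"

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        """(E spike times, I spike times)."""
        mask = self.ids < self.n_e
        return self.times[mask], self.times[~mask]


@dataclass
class RateTrace:
    """Population rates on a uniform grid (spikes / neuron / ms)."""

    t: np.ndarray
    r_e: np.ndarray
    r_i: np.ndarray
    bin_width: float
    extras: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0] + self.bin_width) if self.t.size else 0.0


def qif_rest_voltages(etas: np.ndarray, current: float) -> np.ndarray:
    """Resting voltage per neuron: -sqrt(-(eta + I)) below threshold, else 0."""
    tot = etas + current
    v = np.zeros_like(etas)
    sub = tot < 0
    v[sub] = -np.sqrt(-tot[sub])
    return v


def simulate_spiking_network(
    e_params: PopulationParams,
    i_params: PopulationParams,
    couplings: SynapticCouplings,
    drive_e=0.0,
    drive_i=0.0,
    duration: float = 300.0,
    step: float = 0.01,
    seed: int | None = None,
    heterogeneity: str = "quantile",
    bin_width: float = 0.5,
    smoothing_sigma: float = 1.0,
    initial_voltages: tuple[np.ndarray, np.ndarray] | None = None,
    initial_synapses: np.ndarray | None = None,
    rate_cap: float = 0.5,
) -> tuple[SpikeRaster, RateTrace]:
    """Euler simulation of the finite network; returns raster and binned rates.

    By default neurons start at their single-cell resting voltage for the
    initial drive (supra-threshold cells at v = 0) with silent synapses.
    ``rate_cap`` (spikes/neuron/ms) sizes the spike buffer.
    """
    if step <= 0:
        raise InvalidParameterError(f"step must be > 0, got {step}")
    de = drive_e if isinstance(drive_e, DriveProtocol) else DriveProtocol.constant(float(drive_e))
    di = drive_i if isinstance(drive_i, DriveProtocol) else DriveProtocol.constant(float(drive_i))
    starts, e_vals, i_vals = merge_drives(de, di)
    eta_e = sample_lorentzian(e_params.eta_bar, e_params.delta, e_params.size,
                              heterogeneity, seed)
    eta_i = sample_lorentzian(i_params.eta_bar, i_params.delta, i_params.size,
                              heterogeneity, None if seed is None else seed + 1)
    if initial_voltages is not None:
        v_e = np.array(initial_voltages[0], dtype=float)
        v_i = np.array(initial_voltages[1], dtype=float)
    else:
        v_e = qif_rest_voltages(eta_e, de.value_at(0.0))
        v_i = qif_rest_voltages(eta_i, di.value_at(0.0))
    s0 = (np.zeros(4) if initial_synapses is None
          else np.asarray(initial_synapses, dtype=float))
    n_steps = int(round(duration / step))
    cap = int((e_params.size + i_params.size) * duration * rate_cap) + 1000
    sp_t = np.empty(cap)
    sp_id = np.empty(cap, dtype=np.int64)
    nsp, cnt_e, cnt_i, s_fin = _kernels.spiking_network(
        v_e, v_i, eta_e, eta_i,
        e_params.tau, i_params.tau, couplings.tau_s,
        couplings.j_ee, couplings.j_ei, couplings.j_ie, couplings.j_ii,
        e_params.v_th, e_params.v_reset, i_params.v_th, i_params.v_reset,
        starts, e_vals, i_vals, step, n_steps, s0, sp_t, sp_id,
    )
    if nsp > cap:
        raise InvalidParameterError(
            f"spike buffer overflow ({nsp} > {cap}); raise rate_cap"
        )
    raster = SpikeRaster(times=sp_t[:nsp].copy(), ids=sp_id[:nsp].copy(),
                         n_e=e_params.size, n_i=i_params.size,
                         window=(0.0, duration))
    trace = _counts_to_rate(cnt_e, cnt_i, e_params.size, i_params.size, step,
                            bin_width, smoothing_sigma)
    trace.extras["final_voltages"] = (v_e, v_i)
    trace.extras["final_synapses"] = s_fin
    return raster, trace


def _counts_to_rate(cnt_e, cnt_i, n_e, n_i, step, bin_width, smoothing_sigma):
    per_bin = max(1, int(round(bin_width / step)))
    n_bins = cnt_e.size // per_bin
    ce = cnt_e[: n_bins * per_bin].reshape(n_bins, per_bin).sum(axis=1)
    ci = cnt_i[: n_bins * per_bin].reshape(n_bins, per_bin).sum(axis=1)
    bw = per_bin * step
    r_e = ce / (n_e * bw)
    r_i = ci / (n_i * bw)
    if smoothing_sigma and smoothing_sigma > 0:
        r_e = _conserving_smooth(r_e, smoothing_sigma / bw)
        r_i = _conserving_smooth(r_i, smoothing_sigma / bw)
    t = (np.arange(n_bins) + 0.5) * bw
    return RateTrace(t=t, r_e=r_e, r_i=r_i, bin_width=bw)


def _conserving_smooth(x: np.ndarray, sigma_bins: float) -> np.ndarray:
    """Gaussian smoothing that preserves the total mass exactly."""
    total = float(x.sum())
    y = gaussian_filter1d(x, sigma_bins, mode="reflect")
    s = float(y.sum())
    if s > 0 and total > 0:
        y *= total / s
    return y


def estimate_rate(
    raster: SpikeRaster,
    bin_width: float = 0.5,
    smoothing_sigma: float = 0.0,
) -> RateTrace:
    """Binned population rates from a raster.

    The unsmoothed integral times N recovers the spike count exactly;
    the optional Gaussian smoothing is renormalized to keep it so.
    """
    if bin_width <= 0:
        raise InvalidParameterError(f"bin width must be > 0, got {bin_width}")
    t0, t1 = raster.window
    n_bins = max(1, int(round((t1 - t0) / bin_width)))
    edges = t0 + np.arange(n_bins + 1) * bin_width
    te, ti = raster.split()
    ce, _ = np.histogram(te, bins=edges)
    ci, _ = np.histogram(ti, bins=edges)
    r_e = ce / (raster.n_e * bin_width)
    r_i = ci / (raster.n_i * bin_width)
    if smoothing_sigma and smoothing_sigma > 0:
        r_e = _conserving_smooth(r_e, smoothing_sigma / bin_width)
        r_i = _conserving_smooth(r_i, smoothing_sigma / bin_width)
    t = 0.5 * (edges[:-1] + edges[1:])
    return RateTrace(t=t, r_e=r_e, r_i=r_i, bin_width=bin_width)


def oscillation_frequency(
    trace, which: str = "e", peak_factor: float = 5.0
) -> float | None:
    """Dominant spectral frequency of a rate trace, in Hz.

    Returns None when no spectral peak exceeds ``peak_factor`` times the
    median background; raises when the trace spans fewer than five
    periods of the detected rhythm.  Accepts a RateTrace or a (t, x)
    pair with t in ms.
    """
    if isinstance(trace, RateTrace):
        t = trace.t
        x = trace.r_e if which == "e" else trace.r_i
    else:
        t, x = trace
        t = np.asarray(t, dtype=float)
        x = np.asarray(x, dtype=float)
    if t.size < 16:
        raise InsufficientDataError("trace too short for a spectral estimate")
    dt = float(t[1] - t[0])
    fs_hz = 1000.0 / dt
    freqs, power = signal.periodogram(x - x.mean(), fs=fs_hz, detrend=False)
    freqs, power = freqs[1:], power[1:]
    if not np.any(power > 0):
        return None
    k = int(np.argmax(power))
    background = float(np.median(power))
    if background <= 0:
        background = float(np.mean(power)) * 1e-3 + 1e-300
    if power[k] < peak_factor * background:
        return None
    f = freqs[k]
    if 0 < k < freqs.size - 1:
        # parabolic refinement on log-power
        lp = np.log(np.maximum(power[k - 1: k + 2], 1e-300))
        denom = lp[0] - 2 * lp[1] + lp[2]
        if denom < 0:
            f = freqs[k] + 0.5 * (lp[0] - lp[2]) / denom * (freqs[1] - freqs[0])
    duration_ms = t[-1] - t[0]
    if duration_ms * f / 1000.0 < 5.0:
        raise InsufficientDataError(
            f"trace spans fewer than 5 periods of the detected {f:.1f} Hz rhythm"
        )
    return float(f)
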