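"""Delay-coupled pair: DDE dynamics, lag extraction, roles."""

from dataclasses import replace

import numpy as np
import pytest

import gammalock as gl
from gammalock.errors import InsufficientDataError
from gammalock.params import CrossCoupling


def _synthetic_traces(period, lag, duration=400.0, dt=0.1):
    """Circuit 1 peaks ``lag`` ms after circuit 2 (lag = t_peak1 - t_peak2)."""
    t = np.arange(0.0, duration, dt)
    r1 = 1 + np.cos(2 * np.pi * (t - lag) / period)
    r2 = 1 + np.cos(2 * np.pi * t / period)
    tr1 = gl.RateTrace(t=t, r_e=r1, r_i=r1, bin_width=dt)
    tr2 = gl.RateTrace(t=t, r_e=r2, r_i=r2, bin_width=dt)
    return tr1, tr2


class TestPhaseLagExtraction:
    def test_identical_traces_have_zero_lag(self):
        tr1, tr2 = _synthetic_traces(20.0, 0.0)
        lag, _ = gl.extract_phase_lag(tr1, tr2, 20.0)
        assert abs(lag) < 1e-6

    def test_half_period_shift_maps_to_half_period(self):
        tr1, tr2 = _synthetic_traces(20.0, 10.0)
        lag, _ = gl.extract_phase_lag(tr1, tr2, 20.0)
        assert abs(abs(lag) - 10.0) < 0.05

    @pytest.mark.parametrize("true_lag", [3.0, -7.5])
    def test_recovers_known_lag(self, true_lag):
        tr1, tr2 = _synthetic_traces(20.0, true_lag)
        lag, q = gl.extract_phase_lag(tr1, tr2, 20.0)
        assert lag == pytest.approx(true_lag, abs=0.05)
        assert q < 0.1

    def test_short_window_raises(self):
        tr1, tr2 = _synthetic_traces(20.0, 0.0, duration=100.0)
        with pytest.raises(InsufficientDataError):
            gl.extract_phase_lag(tr1, tr2, 20.0, (0.0, 60.0))


class TestLeaderFollower:
    def test_zero_lag_is_degenerate(self):
        tr1, tr2 = _synthetic_traces(20.0, 0.0)
        roles = gl.identify_leader_follower(tr1, tr2, 20.0)
        assert roles["degenerate"] and roles["leader"] is None

    def test_antiphase_is_degenerate(self):
        tr1, tr2 = _synthetic_traces(20.0, 10.0)
        assert gl.identify_leader_follower(tr1, tr2, 20.0)["degenerate"]

    def test_swapping_traces_swaps_roles(self):
        tr1, tr2 = _synthetic_traces(20.0, 4.0)
        a = gl.identify_leader_follower(tr1, tr2, 20.0)
        b = gl.identify_leader_follower(tr2, tr1, 20.0)
        assert not a["degenerate"]
        assert a["leader"] == b["follower"] and a["follower"] == b["leader"]
        assert a["lag"] == pytest.approx(-b["lag"], abs=1e-9)

    def test_leader_follows_longer_silence(self):
        # circuit 2 fires 4 ms before circuit 1 inside each volley:
        # circuit 2 opens the volley after the long gap -> leader
        tr1, tr2 = _synthetic_traces(20.0, 4.0)
        assert gl.identify_leader_follower(tr1, tr2, 20.0)["leader"] == 2


class TestCoupledReduced:
    def test_uncoupled_circuits_reproduce_single_trajectory(self, ping_cycle):
        cc = CrossCoupling(g_ee=0.0, g_ie=0.0, delay=0.0)
        traj = gl.simulate_coupled_reduced(ping_cycle, cc,
                                           initial_offset_fraction=0.0,
                                           duration=5 * ping_cycle.period,
                                           step=0.005, save_stride=1)
        single = gl.integrate_mf(ping_cycle.states[0], ping_cycle.e_params,
                                 ping_cycle.i_params, ping_cycle.couplings,
                                 *ping_cycle.drive_values,
                                 duration=float(traj.t[-1]), step=0.005)
        n = min(traj.states.shape[0], single.states.shape[0])
        err = np.abs(traj.states[:n, :8] - single.states[:n]).max()
        assert err < 1e-9

    def test_zero_offset_preserves_exchange_symmetry(self, ping_cycle):
        cc = CrossCoupling(g_ee=0.1, g_ie=0.5, delay=0.0)
        traj = gl.simulate_coupled_reduced(ping_cycle, cc,
                                           initial_offset_fraction=0.0,
                                           duration=40 * ping_cycle.period)
        assert np.abs(traj.states[:, :8] - traj.states[:, 8:]).max() < 1e-10

    def test_antiphase_attractor_at_long_delay(self, ping_cycle):
        T = ping_cycle.period
        cc = CrossCoupling(g_ee=0.1, g_ie=0.5, delay=10.0)
        traj = gl.simulate_coupled_reduced(ping_cycle, cc,
                                           initial_offset_fraction=0.05,
                                           duration=300 * T)
        tr1, tr2 = traj.rate_traces()
        lag, _ = gl.extract_phase_lag(tr1, tr2, T,
                                      (traj.t[-1] - 20 * T, traj.t[-1]))
        assert abs(abs(lag) - T / 2) < 0.02 * T

    def test_step_convergence_of_final_lag(self, ping_cycle):
        T = ping_cycle.period
        cc = CrossCoupling(g_ee=0.1, g_ie=0.5, delay=7.0)
        lags = []
        for step in (0.01, 0.005):
            traj = gl.simulate_coupled_reduced(ping_cycle, cc,
                                               initial_offset_fraction=0.05,
                                               duration=200 * T, step=step)
            tr1, tr2 = traj.rate_traces()
            lag, _ = gl.extract_phase_lag(tr1, tr2, T,
                                          (traj.t[-1] - 20 * T, traj.t[-1]))
            lags.append(lag)
        assert abs(lags[0] - lags[1]) < T / 1000


class TestCoupledSpiking:
    def test_uncoupled_pair_matches_independent_runs(self):
        b = gl.figure_preset("fig2_ping")
        e = replace(b.e_params, size=200)
        i = replace(b.i_params, size=200)
        cc = CrossCoupling(g_ee=0.0, g_ie=0.0, delay=0.0)
        (r1, r2), _ = gl.simulate_coupled_spiking(
            e, i, b.couplings, cc, 10.0, 0.0, duration=150.0, seed=3,
            period_hint=20.8, initial_offset_fraction=0.0, warmup=100.0)
        # both circuits share eta and initial snapshot: identical rasters
        assert np.array_equal(r1.times, r2.times)
        assert np.array_equal(r1.ids, r2.ids)
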