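"""Reduced E-I system: vector field, integration, fixed points, cycles."""

from dataclasses import replace

import numpy as np
import pytest

import gammalock as gl
from gammalock.errors import NoCycleError


@pytest.fixture(scope="module")
def ping():
    return gl.figure_preset("fig2_ping")


class TestVectorField:
    def test_rate_drift_at_zero_rate_is_positive(self, ping):
        y = np.zeros(8)
        f = gl.mf_vector_field(y, ping.e_params, ping.i_params, ping.couplings)
        # dr/dt at r=0 equals Delta / (pi tau^2) > 0: rates cannot go negative
        assert f[0] == pytest.approx(1.0 / (np.pi * 100.0))
        assert f[4] == pytest.approx(1.0 / (np.pi * 100.0))

    def test_fixed_point_voltage_identity(self, ping):
        fp = gl.find_fixed_point(ping.e_params, ping.i_params, ping.couplings,
                                 (3.0, 0.0))
        re, ve, ri, vi = fp.state[0], fp.state[1], fp.state[4], fp.state[5]
        assert ve == pytest.approx(-1.0 / (2 * np.pi * 10.0 * re), abs=1e-8)
        assert vi == pytest.approx(-1.0 / (2 * np.pi * 10.0 * ri), abs=1e-8)

    def test_trajectory_finite_difference_matches_field(self, ping):
        y0 = np.array([0.05, -1.0, 0.1, 0.2, 0.05, -1.0, 0.1, 0.0])
        traj = gl.integrate_mf(y0, ping.e_params, ping.i_params, ping.couplings,
                               10.0, 0.0, duration=2.0, step=1e-4)
        mid = len(traj.t) // 2
        fd = (traj.states[mid + 1] - traj.states[mid - 1]) / (2e-4)
        f = gl.mf_vector_field(traj.states[mid], ping.e_params, ping.i_params,
                               ping.couplings, (10.0, 0.0))
        assert np.max(np.abs(fd - f)) < 1e-6 * max(1.0, np.max(np.abs(f)))


class TestIntegration:
    def test_rk4_halved_step_agrees(self, ping):
        y0 = np.array([0.05, -1.0, 0.1, 0.2, 0.05, -1.0, 0.1, 0.0])
        a = gl.integrate_mf(y0, ping.e_params, ping.i_params, ping.couplings,
                            10.0, 0.0, duration=100.0, step=0.01)
        b = gl.integrate_mf(y0, ping.e_params, ping.i_params, ping.couplings,
                            10.0, 0.0, duration=100.0, step=0.005)
        scale = np.max(np.abs(a.states[-1])) or 1.0
        assert np.max(np.abs(a.states[-1] - b.states[-1])) / scale < 1e-6

    def test_quiescent_homogeneous_network_is_stationary(self):
        pop = gl.PopulationParams(tau=10.0, eta_bar=-5.0, delta=0.0)
        c = gl.SynapticCouplings(j_ee=0, j_ei=0, j_ie=0, j_ii=0)
        # resting state: r = 0, V = -sqrt(5)
        y0 = np.array([0.0, -np.sqrt(5.0), 0, 0, 0.0, -np.sqrt(5.0), 0, 0])
        traj = gl.integrate_mf(y0, pop, pop, c, 0.0, 0.0, duration=50.0)
        assert np.max(np.abs(traj.states - y0)) < 1e-12

    def test_rates_stay_positive_along_trajectories(self, ping):
        y0 = np.array([0.3, -3.0, 0.0, 2.0, 0.01, -0.1, 0.5, 0.0])
        traj = gl.integrate_mf(y0, ping.e_params, ping.i_params, ping.couplings,
                               10.0, 0.0, duration=300.0)
        assert np.all(traj.r_e > 0) and np.all(traj.r_i > 0)


class TestFixedPoints:
    def test_ping_operating_point_is_hopf_unstable(self, ping):
        fp = gl.find_fixed_point(ping.e_params, ping.i_params, ping.couplings,
                                 (10.0, 0.0))
        assert not fp.stable
        lam = fp.eigenvalues
        assert np.any((lam.real > 0) & (np.abs(lam.imag) > 1e-6))

    def test_heterogeneity_restores_stability(self, ping):
        e = replace(ping.e_params, delta=10.0)
        i = replace(ping.i_params, delta=10.0)
        fp = gl.find_fixed_point(e, i, ping.couplings, (10.0, 0.0))
        assert fp.stable

    def test_eigenvalues_consistent_with_linearization(self, ping):
        fp = gl.find_fixed_point(ping.e_params, ping.i_params, ping.couplings,
                                 (10.0, 0.0))
        m = gl.linearization_matrix(fp.state, ping.e_params, ping.i_params,
                                    ping.couplings)
        lam = np.sort_complex(np.linalg.eigvals(m))
        assert np.allclose(np.sort_complex(fp.eigenvalues), lam)


class TestLimitCycle:
    def test_ping_cycle_exists_and_closes(self, ping_cycle):
        assert ping_cycle.period > 0
        assert ping_cycle.residual < 1e-6
        assert np.all(ping_cycle.r_e > 0)
        # phase origin anchored at the r_e maximum
        assert int(np.argmax(ping_cycle.r_e)) == 0

    def test_ing_cycle_exists(self, ing_cycle):
        assert ing_cycle.residual < 1e-6
        # ING runs in the fast-gamma range, faster than PING
        assert ing_cycle.frequency_hz > 80.0

    def test_subthreshold_drive_has_no_cycle(self, ping):
        with pytest.raises(NoCycleError):
            gl.find_limit_cycle(ping.e_params, ping.i_params, ping.couplings,
                                (3.0, 0.0), transient=500.0)

    def test_spiking_network_frequency_matches_cycle(self, ping, ping_cycle):
        _, tr = gl.simulate_spiking_network(ping.e_params, ping.i_params,
                                            ping.couplings, 10.0, 0.0,
                                            duration=400.0, seed=0)
        f = gl.oscillation_frequency(tr)
        assert f == pytest.approx(ping_cycle.frequency_hz, rel=0.05)


class TestScans:
    def test_single_value_grid(self, ping):
        pts = gl.bifurcation_scan_1d(ping.e_params, ping.i_params, ping.couplings,
                                     (0.0, 0.0), "i_ext_e", [10.0])
        assert len(pts) == 1 and not pts[0].stable
        assert pts[0].re_range is not None and pts[0].re_range[1] > pts[0].re_range[0]

    def test_ping_drive_scan_has_single_hopf(self, ping):
        pts = gl.bifurcation_scan_1d(ping.e_params, ping.i_params, ping.couplings,
                                     (0.0, 0.0), "i_ext_e",
                                     np.linspace(0, 10, 21), cycle_extrema=False)
        assert gl.count_hopf_transitions(pts) == 1
        assert pts[0].stable and not pts[-1].stable

    def test_heterogeneity_scan_kills_rhythm(self, ping):
        pts = gl.bifurcation_scan_1d(ping.e_params, ping.i_params, ping.couplings,
                                     (10.0, 0.0), "delta",
                                     np.linspace(0.5, 8.0, 16), cycle_extrema=False)
        assert not pts[0].stable and pts[-1].stable
        assert gl.count_hopf_transitions(pts) == 1

    def test_stability_region_monotone_boundary(self, ping):
        drive = np.linspace(0.0, 14.0, 8)
        het = np.array([0.5, 1.0, 1.5, 2.0])
        region = gl.stability_region(ping.e_params, ping.i_params, ping.couplings,
                                     drive, het)
        # zero-drive column never oscillates
        assert not region[:, 0].any()
        # larger heterogeneity needs at least as much drive to oscillate
        onsets = [np.argmax(row) if row.any() else region.shape[1]
                  for row in region]
        assert all(a <= b for a, b in zip(onsets, onsets[1:]))

    def test_one_by_one_region(self, ping):
        region = gl.stability_region(ping.e_params, ping.i_params, ping.couplings,
                                     [10.0], [1.0])
        assert region.shape == (1, 1) and bool(region[0, 0])
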