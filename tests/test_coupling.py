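"""Interaction function H, coupling function G, locking modes."""

import numpy as np
import pytest

import gammalock as gl
from gammalock.errors import GridMismatchError, InvalidParameterError
from gammalock.params import CrossCoupling


class TestInteractionFunction:
    def test_zero_coupling_gives_zero_h(self, ping_adjoint, ping_cycle):
        h = gl.interaction_function(ping_adjoint, ping_cycle, CrossCoupling())
        assert np.all(h.values == 0)

    def test_linearity_in_couplings(self, ping_adjoint, ping_cycle):
        hee = gl.interaction_function(ping_adjoint, ping_cycle,
                                      CrossCoupling(g_ee=0.1))
        hie = gl.interaction_function(ping_adjoint, ping_cycle,
                                      CrossCoupling(g_ie=0.5))
        hboth = gl.interaction_function(ping_adjoint, ping_cycle,
                                        CrossCoupling(g_ee=0.1, g_ie=0.5))
        assert np.allclose(hboth.values, hee.values + hie.values, atol=1e-14)

    def test_quadrature_grid_refinement(self, ping_adjoint, ping_cycle):
        # quadrature on 512 vs 1024 points of the same orbit: < 1e-6 relative
        from dataclasses import replace as drep

        cc = CrossCoupling(g_ee=0.1, g_ie=0.5)
        h_full = gl.interaction_function(ping_adjoint, ping_cycle, cc)
        adj_half = drep(ping_adjoint, z=ping_adjoint.z[::2])
        cyc_half = drep(ping_cycle, states=ping_cycle.states[::2],
                        derivs=ping_cycle.derivs[::2])
        h_half = gl.interaction_function(adj_half, cyc_half, cc)
        scale = np.abs(h_full.values).max()
        diff = np.abs(h_half.values - h_full.values[::2]).max()
        assert diff < 1e-6 * scale

    def test_tau_s_rescale_flag(self, ping_adjoint, ping_cycle):
        cc = CrossCoupling(g_ee=0.1, g_ie=0.5)
        h0 = gl.interaction_function(ping_adjoint, ping_cycle, cc)
        h1 = gl.interaction_function(ping_adjoint, ping_cycle, cc,
                                     rescale_by_tau_s=True)
        # canonical tau_s = 1 ms: both conventions coincide
        assert np.allclose(h0.values, h1.values)

    def test_grid_mismatch_rejected(self, ping_adjoint):
        b = gl.figure_preset("fig2_ping")
        cyc = gl.find_limit_cycle(b.e_params, b.i_params, b.couplings,
                                  b.drive_values, n_samples=512)
        with pytest.raises(GridMismatchError):
            gl.interaction_function(ping_adjoint, cyc, CrossCoupling(g_ee=0.1))


class TestCouplingFunction:
    @pytest.mark.parametrize("d", [0.0, 2.0, 6.0, 7.0, 10.0])
    def test_structural_zeros(self, fig5_interaction, d):
        g = gl.coupling_function(fig5_interaction, d)
        T = g.period
        assert abs(g(0.0)) < 1e-10
        assert abs(g(T / 2)) < 1e-10

    def test_odd_at_zero_delay(self, fig5_interaction):
        g = gl.coupling_function(fig5_interaction, 0.0)
        th = np.linspace(0, g.period, 333)
        scale = np.abs(g(th)).max()
        assert np.abs(g(th) + g(-th)).max() < 1e-10 * max(scale, 1.0)

    def test_delay_periodicity(self, fig5_interaction):
        T = fig5_interaction.period
        g1 = gl.coupling_function(fig5_interaction, 3.0)
        g2 = gl.coupling_function(fig5_interaction, 3.0 + T)
        th = np.linspace(0, T, 100)
        assert np.allclose(g1(th), g2(th), atol=1e-9)

    def test_negative_delay_rejected(self, fig5_interaction):
        with pytest.raises(InvalidParameterError):
            gl.coupling_function(fig5_interaction, -1.0)


class TestLockingModes:
    def test_zero_delay_in_phase_stable(self, fig5_interaction):
        g = gl.coupling_function(fig5_interaction, 0.0)
        modes = {round(m.theta / g.period, 3): m.stable
                 for m in gl.locking_modes(g)}
        assert modes[0.0] is True
        assert modes[0.5] is False

    def test_long_delay_reverses_stability(self, fig5_interaction):
        g = gl.coupling_function(fig5_interaction, 10.0)
        modes = {round(m.theta / g.period, 3): m.stable
                 for m in gl.locking_modes(g)}
        assert modes[0.0] is False
        assert modes[0.5] is True

    @pytest.mark.parametrize("d", [0.0, 4.0, 6.5, 9.0])
    def test_stabilities_alternate_around_circle(self, fig5_interaction, d):
        g = gl.coupling_function(fig5_interaction, d)
        modes = sorted(gl.locking_modes(g), key=lambda m: m.theta)
        flags = [m.stable for m in modes if not m.marginal]
        if len(flags) > 1:
            for a, b in zip(flags, flags[1:] + flags[:1]):
                assert a != b

    def test_coarse_grid_rejected(self, fig5_interaction):
        g = gl.coupling_function(fig5_interaction, 0.0)
        with pytest.raises(InvalidParameterError):
            gl.locking_modes(g, n_grid=128)


class TestLockingBifurcation:
    def test_single_value_grid(self, ping_adjoint, ping_cycle):
        rows = gl.locking_bifurcation(ping_adjoint, ping_cycle,
                                      CrossCoupling(g_ee=0.1, g_ie=0.5),
                                      "d", [0.0])
        assert len(rows) == 1
        assert rows[0].stable_thetas() == pytest.approx([0.0])

    def test_delay_scan_shows_symmetry_breaking_window(self, ping_adjoint,
                                                       ping_cycle):
        T = ping_cycle.period
        rows = gl.locking_bifurcation(ping_adjoint, ping_cycle,
                                      CrossCoupling(g_ee=0.1, g_ie=0.5),
                                      "d", np.linspace(0, 12, 49))
        kinds = []
        for r in rows:
            st = r.stable_thetas() / T
            st = np.minimum(st, 1 - st)  # fold the +/- pair
            if st.size and st.max() > 0.05 and st.max() < 0.45:
                kinds.append("broken")
            elif st.size and np.all(st < 0.05):
                kinds.append("in")
            else:
                kinds.append("anti")
        assert "broken" in kinds
        # contiguous: in-phase block, then broken window, then anti-phase
        first_b, last_b = kinds.index("broken"), len(kinds) - 1 - kinds[::-1].index("broken")
        assert all(k == "broken" for k in kinds[first_b:last_b + 1])
        assert all(k == "in" for k in kinds[:first_b])
        assert all(k == "anti" for k in kinds[last_b + 1:])

    def test_ing_modes_insensitive_to_coupling_strength(self, ing_adjoint,
                                                        ing_cycle):
        # cross-projections originate from the pyramids; for ING their
        # strength scales G without moving its zeros
        base = CrossCoupling(g_ee=0.0, g_ie=0.3, delay=0.3)
        rows = gl.locking_bifurcation(ing_adjoint, ing_cycle, base, "g_ie",
                                      [0.1, 0.3, 0.6])
        ref = [(round(m.theta, 6), m.stable) for m in rows[0].modes]
        for r in rows[1:]:
            assert [(round(m.theta, 6), m.stable) for m in r.modes] == ref
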