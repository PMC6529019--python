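"""Symmetry breaking and directional signal transfer in a coupled pair.

Integrates the 16-ODE delay-coupled PING pair at a delay inside the
symmetry-broken window, identifies the leader (the circuit firing after
the longer silence), and computes the global PRC: the phase shift of the
locked two-circuit rhythm caused by a square pulse to either circuit.
In the broken state, pulsing the leader and pulsing the follower give
different — largely opposite — responses: the signature of a preferred
direction of signal flow despite perfectly symmetric wiring.
"""

import numpy as np

import gammalock as gl

b = gl.figure_preset("fig9_global")
cycle = gl.find_limit_cycle(b.e_params, b.i_params, b.couplings, b.drive_values)
T = cycle.period
cross = gl.CrossCoupling(g_ee=0.1, g_ie=0.5, delay=7.0)
locked = gl.settle_locked_state(cycle, cross, settle_cycles=500)
print(f"delay d = {cross.delay} ms: locked lag = {locked.lag:.2f} ms "
      f"({locked.lag / T:.3f} T), leader = circuit {locked.leader}")

pulse = gl.Pulse(amplitude=1.0, duration=0.1)
gL = gl.global_prc(locked, "leader", "i", pulse, n_phases=16, n_cycles=40)
gF = gl.global_prc(locked, "follower", "i", pulse, n_phases=16, n_cycles=40)
v = gL.valid & gF.valid
sl, sf = gL.shifts_rad[v], gF.shifts_rad[v]
frac = np.mean(np.sign(sl) * np.sign(sf) < 0)
print(f"global PRC (I-cell pulses): sign disagreement over {frac:.0%} of "
      f"onset phases; peak |shift| leader/follower = "
      f"{np.abs(sl).max():.4f} / {np.abs(sf).max():.4f} rad")
print("opposite-signed, unequal responses mean a signal arriving at the "
      "leader is transmitted differently than one arriving at the follower")
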