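"""Macroscopic phase-resetting curves: adjoint method vs direct pulses.

Computes the 8-component adjoint iPRC of the PING limit cycle, then
validates its voltage components by directly pulsing the reduced model
(square pulse, amplitude 1, duration 0.1 ms) at a grid of onset phases
and measuring the asymptotic shift of the rate peaks.  Also prints the
PRC type of each pulse target: an excitatory pulse to the E-cells can
only advance the PING rhythm (type I), while a pulse to the I-cells
advances or delays it depending on timing (type II).
"""

import numpy as np

import gammalock as gl

b = gl.figure_preset("fig2_ping")
cycle = gl.find_limit_cycle(b.e_params, b.i_params, b.couplings, b.drive_values)
adjoint = gl.adjoint_iprc(cycle)
print(f"PING cycle: T = {cycle.period:.3f} ms; adjoint converged in "
      f"{adjoint.n_periods} backward periods "
      f"(normalization residual {adjoint.normalization_residual:.1e})")

for pop, col in [("E", 1), ("I", 5)]:
    pulse = gl.Pulse(amplitude=1.0, duration=0.1, population=pop.lower())
    direct = gl.direct_prc(cycle, pulse, n_phases=16)
    scaled = direct.scaled_to_iprc(b.e_params.tau)
    z = np.interp(direct.onset_phases, adjoint.phases, adjoint.z[:, col],
                  period=2 * np.pi)
    corr = np.corrcoef(scaled, z)[0, 1]
    print(f"{pop}-cell pulses: type = {gl.classify_prc(z)!r}; "
          f"adjoint-vs-direct correlation = {corr:.4f}")
print("correlations near 1 confirm the adjoint iPRC predicts the "
      "network's measured phase shifts in the weak-pulse limit")
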