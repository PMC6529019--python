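"""Exact mean-field reduction: finite QIF network vs the 8-ODE system.

Simulates 5000 excitatory + 5000 inhibitory QIF neurons under a staircase
stimulus and compares the binned population rates with the reduced
firing-rate system started from the matching fixed point.  The relative
L2 errors quantify how faithfully the low-dimensional model tracks the
spiking network through quiescent and rhythmic episodes.
"""

import numpy as np
from scipy.ndimage import gaussian_filter1d

import gammalock as gl

bundle = gl.figure_preset("fig1")
print(f"couplings: J_ei={bundle.couplings.j_ei}, J_ie={bundle.couplings.j_ie}, "
      f"J_ii={bundle.couplings.j_ii}; drive steps "
      f"{[v for _, v in bundle.drive_e.segments]}")

raster, trace = gl.simulate_spiking_network(
    bundle.e_params, bundle.i_params, bundle.couplings,
    bundle.drive_e, bundle.drive_i, duration=bundle.duration, seed=0)
print(f"spiking network: {raster.n_spikes} spikes in {bundle.duration:.0f} ms")

fp = gl.find_fixed_point(bundle.e_params, bundle.i_params, bundle.couplings,
                         bundle.drive_values)
traj = gl.integrate_mf(fp.state, bundle.e_params, bundle.i_params,
                       bundle.couplings, bundle.drive_e, bundle.drive_i,
                       duration=bundle.duration)

idx = np.clip((trace.t / traj.step).astype(int), 0, len(traj.t) - 1)
for label, net, col in [("r_e", trace.r_e, 0), ("r_i", trace.r_i, 4)]:
    mf = gaussian_filter1d(traj.states[idx, col], 1.0 / trace.bin_width,
                           mode="reflect")
    err = np.linalg.norm(net - mf) / np.linalg.norm(mf)
    print(f"{label}: relative L2 error network-vs-reduced = {err:.3f}")
print("errors of a few percent mean the 8 ODEs capture the population "
      "dynamics of 10,000 spiking neurons")
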