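# Methods

## Model

Each circuit is an all-to-all network of `N_e` excitatory and `N_i`
inhibitory quadratic integrate-and-fire neurons,

    tau dv_j/dt = eta_j + v_j^2 + I(t),

with instantaneous reset from the cutoff `v_th` to `v_reset` and a
quenched bias current `eta_j` drawn from a Lorentzian of center
`eta_bar` and half-width `Delta`.  The total current combines an
external drive and first-order synaptic filters,

    I_e = I_ext^e + tau_e (s_ee - s_ei),      tau_s ds_ab/dt = -s_ab + J_ab r_b,

where `J_ab` couples population `b` onto population `a` and `r_b(t)` is
the population rate.  In the thermodynamic limit the Lorentzian
heterogeneity makes the population density exactly Lorentzian in `v`,
which closes the dynamics on the firing rate `r(t)` and the mean
voltage `V(t)`:

    tau dr/dt = Delta / (pi tau) + 2 r V,
    tau dV/dt = V^2 + eta_bar + I - (pi tau r)^2.

The E-I circuit is then the 8-dimensional system
`O = (r_e, V_e, s_ee, s_ei, r_i, V_i, s_ie, s_ii)` implemented in
`meanfield.mf_vector_field`.  Because the rate drift at `r = 0` equals
`Delta / (pi tau^2) > 0`, rates stay positive along every trajectory.

**Units.**  The equations are scale-free; the package fixes time in
milliseconds with `tau = 10 ms` so that frequencies read `f = 1000 / T`
Hz and both canonical rhythms land in the gamma band (the PING
operating point gives `T = 20.81 ms`, 48 Hz; the ING point `T = 8.52 ms`,
117 Hz).  Voltages, currents, and coupling strengths are dimensionless;
rates are spikes/neuron/ms.

## Canonical operating points

Two mechanisms are bundled as presets (`presets.figure_preset`):

* **PING** (`fig2_ping`): `J_ei = J_ie = 15`, `J_ee = J_ii = 0`,
  `eta_bar = -5`, `Delta = 1`, `I_ext^e = 10`.  The rhythm lives in the
  E->I->E loop.
* **ING** (`fig3_ing`): `J_ei = 10`, `J_ii = 15`, `J_ie = J_ee = 0`,
  `I_ext = 25` on both populations.  The rhythm lives in the I->I loop
  and the E-cells are followers.

With `eta_bar = -5`, `Delta = 1` about 94% of neurons are not intrinsic
oscillators (`spiking.fraction_non_oscillatory`); the gamma rhythm is an
emergent network property, not synchronization of cellular oscillators.

The `fig1` preset (mean-field validation circuit, `J_ii = 10`) carries a
staircase drive `I_ext^e = 1.5 / 6 / 10 / 3` switching every 75 ms.
The original stimulus trace for this comparison is qualitative, so these
levels are the package's own fixed choice; they traverse the quiescent,
near-onset and strongly rhythmic regimes once, which is what the
fidelity comparison needs to be meaningful.

## Numerics

* **Spiking networks** — forward Euler with `step = 0.01 ms`; a spike
  is registered at the first step with `v >= v_th` and the voltage reset
  within the same step.  The residual travel time from `v_th` to
  infinity and back to `v_reset` (about `tau/v_th + tau/|v_reset|
  = 0.04 ms` at the default cutoffs of +-500) is neglected — a known
  O(step) timing bias, small against the 20 ms period.  Synapses decay
  exactly (`exp(-dt/tau_s)` per step) and jump by `J_ab / (N_b tau_s)`
  per presynaptic spike, so the filter accrues no step-size error.
  Heterogeneity defaults to deterministic Lorentzian quantiles
  (`eta_j = center + width * tan(pi/2 (2j - N - 1)/(N + 1))`), making
  runs reproducible without a seed; i.i.d. Cauchy draws are available
  behind `mode="random"`.
* **Reduced model** — classical RK4 at `step = 0.01 ms` (halving the
  step moves trajectory endpoints by < 1e-6 relative).  Piecewise-
  constant drives are integrated segment by segment with boundaries
  snapped to the step grid, so pulses introduce no quadrature error.
* **Limit cycles** — after a 2000 ms transient the Poincare section
  (upward crossing of `r_e` through its mean) is located by Newton
  iterations that use the exact `dr_e/dt` from the vector field;
  successive return times are iterated to < 1e-6 relative agreement.
  The orbit is resampled on `M = 1024` uniform points (a balance of
  quadrature accuracy for the interaction integrals against memory and
  time), with phase 0 anchored at the `r_e` maximum — the model is
  autonomous, so the phase origin is a pure convention and this one
  makes burst-peak bookkeeping trivial.  Closure residuals are ~1e-10.
* **Fixed points and scans** — `scipy.optimize.root` (Powell hybrid) on
  the 8-D field, continued along scan grids; a multi-start fallback
  (trajectory endpoints after a 200 ms transient plus trajectory time
  averages, which lie inside any cycle) covers roots without a good
  guess.  Stability comes from the eigenvalues of the analytic Jacobian;
  real parts within 1e-8 of zero are flagged marginal.  Oscillation
  extrema along unstable branches are read from the tail of a direct
  integration, which stays robust arbitrarily close to the Hopf point.
* **Adjoint iPRC** — the adjoint system `-dZ/dt = M(t)^T Z` is
  integrated backward (stable exactly when the cycle attracts) with RK4
  at `T/4096`, interpolating the stored orbit with a periodic
  Catmull-Rom spline; the solution direction is renormalized each period
  and convergence is declared at < 1e-8 change per period (cap 200
  periods, then an error — a non-converging adjoint signals a marginal
  cycle).  One final rescale enforces the normalization
  `Z . dO/dt = 2 pi / T`; the pointwise residual of that identity
  (~1e-6, bound 1e-3) doubles as an integration-quality check because
  the product is conserved exactly by the continuous flow.
* **Direct PRC** — square pulse onto E- or I-cells at a grid of onset
  phases; the asymptotic shift of the `r_e` burst peaks (parabolically
  refined) versus an unperturbed reference is taken as the mean over
  cycles 22-25 after checking it plateaus to within `T/100` over the
  last five cycles.  Shifts are reported in radians (positive =
  advance); dividing by `pulse charge / tau` makes them directly
  comparable to the adjoint voltage components.
* **Delay-coupled pair** — the 16-ODE system with delayed cross-terms
  `G_ee r_e^(2)(t - d)` and `G_ie r_e^(2)(t - d)` entering the partner's
  `s_ee`/`s_ie` equations is integrated with fixed-step RK4 where the
  step divides the delay exactly (`h = d / round(d / 0.005)`); the
  half-step stage interpolates the stored rate history with a 4-point
  cubic stencil.  Initial history: both circuits on the uncoupled limit
  cycle, circuit 2 offset by 0.05 T by default — zero lag is an
  invariant manifold, so symmetry-breaking runs need a nonzero seed
  offset.  The twin spiking networks queue per-step E-spike counts and
  deliver them to the partner's `s_ee`/`s_ie` after `d/h` steps with
  jumps `G_ab / (N_e tau_s)`.

## Phase reduction and the coupling function

For weak cross-coupling the pair reduces to a single equation for the
phase lag `theta` (circuit 1 minus circuit 2; only zeros and their
stability, which are orientation-invariant, are reported as results):

    d theta / dt = G(theta),
    H(theta) = (G_ee / T) int_0^T Z_see(s) r_e(s - theta) ds
             + (G_ie / T) int_0^T Z_sie(s) r_e(s - theta) ds.

On the uniform cycle grid the integral is a circular cross-correlation
(the rectangle sum equals the trapezoid rule there); H is linear in
`(G_ee, G_ie)`, so two unit-coupling basis curves are cached and reused
across scans.

**Delay-shift convention.**  With this definition of H, averaging the
delayed coupling term gives

    G(theta) = H(theta + d) - H(-theta + d).

The opposite shift (`theta - d` / `-theta - d`) also appears in the
literature paired with the same H; the two differ by `d -> -d` and make
opposite predictions for where the symmetry-breaking delay window sits.
The convention used here was fixed by cross-validating against direct
integration of the 16-ODE pair at weak coupling (`G_ee = 0.02`,
`G_ie = 0.1`): the predicted stable lags (+-0.067 T at `d = 6 ms`,
+-0.339 T at `d = 7 ms`, anti-phase beyond ~8 ms) match the simulated
lags to well under 0.05 T, while the opposite shift places the window at
2.7-4.5 ms where the simulations show plain in-phase locking.  Both
conventions satisfy the structural identities `G(0) = G(T/2) = 0`
(exact for every delay), oddness of G at `d = 0`, and T-periodicity of
the locking diagram in d.

An optional `rescale_by_tau_s` flag divides H by `tau_s` — the factor a
conventional averaging of the synaptic perturbation (`G r / tau_s`
entering `ds/dt`) would include; at the canonical `tau_s = 1 ms` the two
conventions coincide, and the default leaves H as defined above.

Zeros of G are located by sign change plus bisection to `|G| < 1e-10`;
`theta = 0` and `T/2` are always included (they are zeros by
construction).  Stability is the sign of the central-difference slope;
slopes within 1e-8 of zero are reported as marginal rather than
classified — bifurcation points live exactly there.

## PRC typing

A sampled PRC is `null` if nothing exceeds the noise floor, `type II`
(biphasic) if both signs do, else `type I` (monophasic).  The default
floor is 5% of the peak magnitude: direct PRC measurements on finite
networks carry a few percent of peak-height noise, so smaller
counter-lobes are not observable in practice.  (The ING I-pulse iPRC,
for instance, has a 4.5%-of-peak negative dip; it is classified
monophasic, matching what any direct measurement shows.)  The `null`
verdict for ING E-pulses is checked much more stringently: with
`J_ee = J_ie = 0` the four E-subsystem adjoint components vanish
identically (< 1e-6 of `max |Z_vi|`; numerically ~1e-13).

## Leader, follower, and the global PRC

In a symmetry-broken locked state the burst lag is neither 0 nor T/2;
the circuit firing after the longer inter-burst silence opens each
volley and is called the leader.  States within T/20 of in-phase or
anti-phase are labelled degenerate rather than forced into roles (the
guard band is an artifact choice, marked in outputs).

The global PRC perturbs one circuit of the settled pair (square pulse,
default amplitude 1, duration 0.1 ms) at a grid of onset phases and
measures the shift of circuit 1's burst peaks against an unperturbed
continuation, after verifying the pair re-locked to the same lag (within
T/50; samples that re-lock elsewhere are flagged as mode switches and
excluded — strong pulses can swap the roles).  The shift is read ~30
cycles after the pulse by default; near-degenerate states re-equilibrate
slowly, and the symmetric-control comparison only becomes exact at ~60
cycles, so the horizon is a parameter.

**Strong-coupling caveat.**  The phase reduction assumes weak
cross-coupling (a `CrossCoupling` with `max(G_ee, G_ie) > 0.5` raises an
`extrapolated` flag).  At the full canonical couplings
(`G_ee = 0.1`, `G_ie = 0.5`) the in/anti-phase transition survives but
its delay window shifts: the weak-coupling theory breaks symmetry at
`d ~ 5.5-8 ms`, while the strongly coupled pair settles in-phase at
`d = 6 ms` and breaks symmetry at `d ~ 6.5-7.5 ms`.  Demonstrations of
leader/follower directionality therefore use `d = 7 ms`, where the
full-coupling pair is unambiguously broken (lag 0.38 T).

## What the synthetic conditions do and do not show

All inputs are parameter bundles; there is no external data.  The
spiking simulations emulate finite-size effects (shot noise in the
rates, quenched heterogeneity) but not features of biological circuits
outside the model class: sparse or distance-dependent connectivity,
conductance-based synapses, within-circuit delays, or multiple
interneuron classes.  Agreement between the spiking networks and the
reduced model therefore validates the reduction and the phase theory on
their own terms; it does not by itself establish the behavior of
cortical tissue.  Numbers quoted above (48 Hz, 117 Hz, lag windows,
residuals) are all recomputed by the test suite and
`scripts/acceptance.py`, not stored.

## Known limitations

* The direct spiking-network PRC backend estimates shifts from noisy
  finite-size rates; it needs large N and pulse amplitudes well above
  the noise floor, and is validated only qualitatively.
* Dense scans stand in for proper numerical continuation; branches that
  fold or coexist (the system can be bistable near onset) are covered
  by the multi-start heuristic, not tracked.
* Only two coupled circuits, identical by construction; detuned or
  cross-frequency (PING-ING) interactions are out of scope.
* The delay enters only between circuits, not within them.
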