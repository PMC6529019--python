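"""Numba-compiled numerical kernels.

All integrators are fixed-step and fully deterministic: classical RK4 for
the reduced 8-dimensional circuit, RK4 with a stored history buffer for
the 16-dimensional delay-coupled pair (delay an exact multiple of the
step, cubic interpolation at the half-step stage), backward RK4 with
per-period renormalization for the adjoint pass, and forward Euler with
exact exponential synaptic decay for the spiking networks.

State layout of one circuit (8 components):
    [r_e, V_e, s_ee, s_ei, r_i, V_i, s_ie, s_ii]
Parameter vector layout (see params.pack_params):
    [tau_e, delta_e, eta_e, tau_i, delta_i, eta_i, tau_s,
     j_ee, j_ei, j_ie, j_ii]
"""

import numpy as np
from numba import njit

PI = np.pi


@njit(cache=True)
def mf_rhs(y, p, i_ext_e, i_ext_i):
    tau_e = p[0]; delta_e = p[1]; eta_e = p[2]
    tau_i = p[3]; delta_i = p[4]; eta_i = p[5]
    tau_s = p[6]; jee = p[7]; jei = p[8]; jie = p[9]; jii = p[10]
    re = y[0]; ve = y[1]; see = y[2]; sei = y[3]
    ri = y[4]; vi = y[5]; sie = y[6]; sii = y[7]
    out = np.empty(8)
    out[0] = (delta_e / (PI * tau_e) + 2.0 * re * ve) / tau_e
    out[1] = (ve * ve + eta_e + i_ext_e + tau_e * (see - sei)
              - (PI * tau_e * re) ** 2) / tau_e
    out[2] = (-see + jee * re) / tau_s
    out[3] = (-sei + jei * ri) / tau_s
    out[4] = (delta_i / (PI * tau_i) + 2.0 * ri * vi) / tau_i
    out[5] = (vi * vi + eta_i + i_ext_i + tau_i * (sie - sii)
              - (PI * tau_i * ri) ** 2) / tau_i
    out[6] = (-sie + jie * re) / tau_s
    out[7] = (-sii + jii * ri) / tau_s
    return out


@njit(cache=True)
def rk4_const(y0, p, i_ext_e, i_ext_i, dt, n_steps, stride):
    """RK4 under constant drive; returns (saved_path, final_state, blowup_step).

    ``saved_path`` holds the state at steps 0, stride, 2*stride, ...
    (n_steps // stride + 1 rows; the caller arranges stride | n_steps).
    ``blowup_step`` is -1 when the run stayed finite.
    """
    n_saved = n_steps // stride + 1
    out = np.empty((n_saved, 8))
    y = y0.copy()
    out[0] = y
    k = 1
    for n in range(n_steps):
        k1 = mf_rhs(y, p, i_ext_e, i_ext_i)
        k2 = mf_rhs(y + 0.5 * dt * k1, p, i_ext_e, i_ext_i)
        k3 = mf_rhs(y + 0.5 * dt * k2, p, i_ext_e, i_ext_i)
        k4 = mf_rhs(y + dt * k3, p, i_ext_e, i_ext_i)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if (n + 1) % stride == 0:
            out[k] = y
            k += 1
            if not np.isfinite(y[0]) or not np.isfinite(y[1]):
                return out, y, n + 1
    return out, y, -1


@njit(cache=True)
def adjoint_mtz(z, y, p):
    """M(y)^T . z for the linearization M of the reduced E-I field."""
    tau_e = p[0]; tau_i = p[3]; tau_s = p[6]
    jee = p[7]; jei = p[8]; jie = p[9]; jii = p[10]
    re = y[0]; ve = y[1]; ri = y[4]; vi = y[5]
    out = np.empty(8)
    out[0] = (2.0 * ve / tau_e) * z[0] - 2.0 * tau_e * PI * PI * re * z[1] \
        + (jee / tau_s) * z[2] + (jie / tau_s) * z[6]
    out[1] = (2.0 * re / tau_e) * z[0] + (2.0 * ve / tau_e) * z[1]
    out[2] = z[1] - z[2] / tau_s
    out[3] = -z[1] - z[3] / tau_s
    out[4] = (jei / tau_s) * z[3] + (2.0 * vi / tau_i) * z[4] \
        - 2.0 * tau_i * PI * PI * ri * z[5] + (jii / tau_s) * z[7]
    out[5] = (2.0 * ri / tau_i) * z[4] + (2.0 * vi / tau_i) * z[5]
    out[6] = z[5] - z[6] / tau_s
    out[7] = -z[5] - z[7] / tau_s
    return out


@njit(cache=True)
def _cycle_state(cycle, tt, period):
    """Catmull-Rom interpolation of the stored cycle at time tt (periodic)."""
    m = cycle.shape[0]
    u = (tt % period) / period * m
    j = int(np.floor(u))
    x = u - j
    j = j % m
    p0 = cycle[(j - 1) % m]
    p1 = cycle[j]
    p2 = cycle[(j + 1) % m]
    p3 = cycle[(j + 2) % m]
    a = 2.0 * p1
    b = p2 - p0
    c = 2.0 * p0 - 5.0 * p1 + 4.0 * p2 - p3
    d = -p0 + 3.0 * p1 - 3.0 * p2 + p3
    return 0.5 * (a + b * x + c * x * x + d * x * x * x)


@njit(cache=True)
def adjoint_backward(cycle, p, period, k_sub, max_periods, tol):
    """Backward adjoint integration over repeated periods.

    Integrates phi(s) = Z(T - s), dphi/ds = M(T - s)^T phi with RK4 until
    the direction of phi stabilizes (relative change < tol per period).
    Returns (Z_on_grid (m,8), n_periods, converged_flag).  The caller
    applies the 2*pi/T normalization.
    """
    m = cycle.shape[0]
    h = period / (m * k_sub)
    phi = np.ones(8)
    phi /= np.sqrt(np.sum(phi * phi))
    prev = phi.copy()
    n_per = 0
    converged = False
    for it in range(max_periods):
        s = 0.0
        for n in range(m * k_sub):
            y1 = _cycle_state(cycle, period - s, period)
            y2 = _cycle_state(cycle, period - (s + 0.5 * h), period)
            y3 = _cycle_state(cycle, period - (s + h), period)
            k1 = adjoint_mtz(phi, y1, p)
            k2 = adjoint_mtz(phi + 0.5 * h * k1, y2, p)
            k3 = adjoint_mtz(phi + 0.5 * h * k2, y2, p)
            k4 = adjoint_mtz(phi + h * k3, y3, p)
            phi = phi + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            s += h
        nrm = np.sqrt(np.sum(phi * phi))
        phi /= nrm
        n_per = it + 1
        diff = np.sqrt(np.sum((phi - prev) ** 2))
        prev = phi.copy()
        if diff < tol:
            converged = True
            break
    # one more period, storing Z at the cycle sample times
    z_grid = np.empty((m, 8))
    s = 0.0
    for n in range(m * k_sub):
        if n % k_sub == 0:
            idx = (m - n // k_sub) % m
            z_grid[idx] = phi
        y1 = _cycle_state(cycle, period - s, period)
        y2 = _cycle_state(cycle, period - (s + 0.5 * h), period)
        y3 = _cycle_state(cycle, period - (s + h), period)
        k1 = adjoint_mtz(phi, y1, p)
        k2 = adjoint_mtz(phi + 0.5 * h * k1, y2, p)
        k3 = adjoint_mtz(phi + 0.5 * h * k2, y2, p)
        k4 = adjoint_mtz(phi + h * k3, y3, p)
        phi = phi + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        s += h
    return z_grid, n_per, converged, phi


@njit(cache=True)
def dde_rhs(y, rd1, rd2, p, gee, gie, ie1, ii1, ie2, ii2):
    """Right-hand side of the 16-D delay-coupled pair.

    ``rd1`` is r_e of circuit 2 evaluated at t - d (entering circuit 1's
    s_ee / s_ie equations), ``rd2`` the symmetric term.
    """
    tau_e = p[0]; delta_e = p[1]; eta_e = p[2]
    tau_i = p[3]; delta_i = p[4]; eta_i = p[5]
    tau_s = p[6]; jee = p[7]; jei = p[8]; jie = p[9]; jii = p[10]
    out = np.empty(16)
    for c in range(2):
        o = 8 * c
        rd = rd1 if c == 0 else rd2
        ie = ie1 if c == 0 else ie2
        ii = ii1 if c == 0 else ii2
        re = y[o]; ve = y[o + 1]; see = y[o + 2]; sei = y[o + 3]
        ri = y[o + 4]; vi = y[o + 5]; sie = y[o + 6]; sii = y[o + 7]
        out[o] = (delta_e / (PI * tau_e) + 2.0 * re * ve) / tau_e
        out[o + 1] = (ve * ve + eta_e + ie + tau_e * (see - sei)
                      - (PI * tau_e * re) ** 2) / tau_e
        out[o + 2] = (-see + jee * re + gee * rd) / tau_s
        out[o + 3] = (-sei + jei * ri) / tau_s
        out[o + 4] = (delta_i / (PI * tau_i) + 2.0 * ri * vi) / tau_i
        out[o + 5] = (vi * vi + eta_i + ii + tau_i * (sie - sii)
                      - (PI * tau_i * ri) ** 2) / tau_i
        out[o + 6] = (-sie + jie * re + gie * rd) / tau_s
        out[o + 7] = (-sii + jii * ri) / tau_s
    return out


@njit(cache=True)
def _hist_mid(buf, n, m):
    """History value at grid index n + 1/2, cubic when the stencil fits.

    At step n the buffers are filled through index m + n, so the cubic
    stencil (n-1 .. n+2) is only available for m >= 2 and n >= 1.
    """
    if n >= 1 and m >= 2:
        p0 = buf[n - 1]; p1 = buf[n]; p2 = buf[n + 1]; p3 = buf[n + 2]
        return (-p0 + 9.0 * p1 + 9.0 * p2 - p3) / 16.0
    return 0.5 * (buf[n] + buf[n + 1])


@njit(cache=True)
def dde16(y0, p, gee, gie, m_delay, h, n_steps, hist1, hist2,
          ie_e, ii_i, stride,
          pulse_on, pulse_len, pulse_amp, pulse_circuit, pulse_pop):
    """Fixed-step RK4 for the delay-coupled pair.

    ``hist1``/``hist2`` hold r_e of circuits 1 and 2 at the grid times
    -m_delay*h .. 0 (length m_delay + 1, last entry equals y0's r_e).
    The optional square pulse adds ``pulse_amp`` to the external drive of
    population ``pulse_pop`` (0 = E, 1 = I) of ``pulse_circuit`` (0 or 1)
    during steps [pulse_on, pulse_on + pulse_len).  Returns
    (saved_path, re1_full, re2_full, final_state, blowup_step).
    """
    m = m_delay
    buf1 = np.empty(n_steps + m + 1)
    buf2 = np.empty(n_steps + m + 1)
    buf1[: m + 1] = hist1
    buf2[: m + 1] = hist2
    n_saved = n_steps // stride + 1
    out = np.empty((n_saved, 16))
    y = y0.copy()
    out[0] = y
    ks = 1
    blow = -1
    for n in range(n_steps):
        ie1 = ie_e; ii1 = ii_i; ie2 = ie_e; ii2 = ii_i
        if pulse_len > 0 and pulse_on <= n < pulse_on + pulse_len:
            if pulse_circuit == 0:
                if pulse_pop == 0:
                    ie1 += pulse_amp
                else:
                    ii1 += pulse_amp
            else:
                if pulse_pop == 0:
                    ie2 += pulse_amp
                else:
                    ii2 += pulse_amp
        if m > 0:
            # index of t - d in the buffers is n (buffers offset by m)
            rd1_a = buf2[n]; rd2_a = buf1[n]
            rd1_b = _hist_mid(buf2, n, m); rd2_b = _hist_mid(buf1, n, m)
            rd1_c = buf2[n + 1]; rd2_c = buf1[n + 1]
        else:
            rd1_a = y[8]; rd2_a = y[0]
            rd1_b = rd1_a; rd2_b = rd2_a
            rd1_c = rd1_a; rd2_c = rd2_a
        k1 = dde_rhs(y, rd1_a, rd2_a, p, gee, gie, ie1, ii1, ie2, ii2)
        if m == 0:
            ymid = y + 0.5 * h * k1
            rd1_b = ymid[8]; rd2_b = ymid[0]
        k2 = dde_rhs(y + 0.5 * h * k1, rd1_b, rd2_b, p, gee, gie, ie1, ii1, ie2, ii2)
        if m == 0:
            ymid = y + 0.5 * h * k2
            rd1_b = ymid[8]; rd2_b = ymid[0]
        k3 = dde_rhs(y + 0.5 * h * k2, rd1_b, rd2_b, p, gee, gie, ie1, ii1, ie2, ii2)
        if m == 0:
            yend = y + h * k3
            rd1_c = yend[8]; rd2_c = yend[0]
        k4 = dde_rhs(y + h * k3, rd1_c, rd2_c, p, gee, gie, ie1, ii1, ie2, ii2)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        buf1[m + n + 1] = y[0]
        buf2[m + n + 1] = y[8]
        if (n + 1) % stride == 0:
            out[ks] = y
            ks += 1
        if n % 1000 == 0 and not np.isfinite(y[0] + y[8]):
            blow = n
            break
    return out, buf1[m:], buf2[m:], y, blow


@njit(cache=True)
def spiking_network(v_e, v_i, eta_e, eta_i,
                    tau_e, tau_i, tau_s, jee, jei, jie, jii,
                    vth_e, vr_e, vth_i, vr_i,
                    seg_starts, seg_ie, seg_ii,
                    dt, n_steps, s0, sp_t, sp_id):
    """Euler integration of one finite QIF network.

    Synapses decay exactly (factor exp(-dt/tau_s) per step) and jump by
    J / (N tau_s) per presynaptic spike.  ``sp_t``/``sp_id`` are
    preallocated spike buffers; recording stops silently past capacity
    (the returned count tells the caller whether it overflowed).
    Returns (n_spikes, cnt_e, cnt_i, s_final).
    """
    n_e = v_e.size
    n_i = v_i.size
    see = s0[0]; sei = s0[1]; sie = s0[2]; sii = s0[3]
    dec = np.exp(-dt / tau_s)
    a_ee = jee / (n_e * tau_s)
    a_ei = jei / (n_i * tau_s)
    a_ie = jie / (n_e * tau_s)
    a_ii = jii / (n_i * tau_s)
    cap = sp_t.size
    nsp = 0
    cnt_e = np.zeros(n_steps)
    cnt_i = np.zeros(n_steps)
    seg = 0
    for n in range(n_steps):
        t = n * dt
        while seg + 1 < seg_starts.size and t >= seg_starts[seg + 1] - 1e-12:
            seg += 1
        ie = seg_ie[seg] + tau_e * (see - sei)
        ii = seg_ii[seg] + tau_i * (sie - sii)
        ne_sp = 0
        for j in range(n_e):
            v = v_e[j]
            v = v + dt * (eta_e[j] + v * v + ie) / tau_e
            if v >= vth_e:
                if nsp < cap:
                    sp_t[nsp] = t + dt
                    sp_id[nsp] = j
                nsp += 1
                ne_sp += 1
                v = vr_e
            v_e[j] = v
        ni_sp = 0
        for j in range(n_i):
            v = v_i[j]
            v = v + dt * (eta_i[j] + v * v + ii) / tau_i
            if v >= vth_i:
                if nsp < cap:
                    sp_t[nsp] = t + dt
                    sp_id[nsp] = n_e + j
                nsp += 1
                ni_sp += 1
                v = vr_i
            v_i[j] = v
        see = see * dec + a_ee * ne_sp
        sei = sei * dec + a_ei * ni_sp
        sie = sie * dec + a_ie * ne_sp
        sii = sii * dec + a_ii * ni_sp
        cnt_e[n] = ne_sp
        cnt_i[n] = ni_sp
    s_final = np.array([see, sei, sie, sii])
    return nsp, cnt_e, cnt_i, s_final


@njit(cache=True)
def coupled_spiking(v_e1, v_i1, v_e2, v_i2, eta_e, eta_i,
                    tau_e, tau_i, tau_s, jee, jei, jie, jii,
                    gee, gie, m_delay,
                    vth_e, vr_e, vth_i, vr_i,
                    ie_ext, ii_ext, dt, n_steps, s01, s02,
                    sp_t1, sp_id1, sp_t2, sp_id2):
    """Twin QIF networks with delayed cross-projections from the E-cells.

    A spike fired by circuit 2's E-cells at step n increments circuit 1's
    s_ee / s_ie by G_ab / (N_e tau_s) at step n + m_delay (and
    symmetrically).  Returns per-circuit spike counts and rate-count
    traces: (nsp1, nsp2, cnt_e1, cnt_i1, cnt_e2, cnt_i2).
    """
    n_e = v_e1.size
    n_i = v_i1.size
    see1 = s01[0]; sei1 = s01[1]; sie1 = s01[2]; sii1 = s01[3]
    see2 = s02[0]; sei2 = s02[1]; sie2 = s02[2]; sii2 = s02[3]
    dec = np.exp(-dt / tau_s)
    a_ee = jee / (n_e * tau_s)
    a_ei = jei / (n_i * tau_s)
    a_ie = jie / (n_e * tau_s)
    a_ii = jii / (n_i * tau_s)
    g_ee = gee / (n_e * tau_s)
    g_ie = gie / (n_e * tau_s)
    cap1 = sp_t1.size
    cap2 = sp_t2.size
    nsp1 = 0
    nsp2 = 0
    cnt_e1 = np.zeros(n_steps)
    cnt_i1 = np.zeros(n_steps)
    cnt_e2 = np.zeros(n_steps)
    cnt_i2 = np.zeros(n_steps)
    for n in range(n_steps):
        t = n * dt
        ie1 = ie_ext + tau_e * (see1 - sei1)
        ii1 = ii_ext + tau_i * (sie1 - sii1)
        ie2 = ie_ext + tau_e * (see2 - sei2)
        ii2 = ii_ext + tau_i * (sie2 - sii2)
        ne1 = 0
        for j in range(n_e):
            v = v_e1[j]
            v = v + dt * (eta_e[j] + v * v + ie1) / tau_e
            if v >= vth_e:
                if nsp1 < cap1:
                    sp_t1[nsp1] = t + dt
                    sp_id1[nsp1] = j
                nsp1 += 1
                ne1 += 1
                v = vr_e
            v_e1[j] = v
        ni1 = 0
        for j in range(n_i):
            v = v_i1[j]
            v = v + dt * (eta_i[j] + v * v + ii1) / tau_i
            if v >= vth_i:
                if nsp1 < cap1:
                    sp_t1[nsp1] = t + dt
                    sp_id1[nsp1] = n_e + j
                nsp1 += 1
                ni1 += 1
                v = vr_i
            v_i1[j] = v
        ne2 = 0
        for j in range(n_e):
            v = v_e2[j]
            v = v + dt * (eta_e[j] + v * v + ie2) / tau_e
            if v >= vth_e:
                if nsp2 < cap2:
                    sp_t2[nsp2] = t + dt
                    sp_id2[nsp2] = j
                nsp2 += 1
                ne2 += 1
                v = vr_e
            v_e2[j] = v
        ni2 = 0
        for j in range(n_i):
            v = v_i2[j]
            v = v + dt * (eta_i[j] + v * v + ii2) / tau_i
            if v >= vth_i:
                if nsp2 < cap2:
                    sp_t2[nsp2] = t + dt
                    sp_id2[nsp2] = n_e + j
                nsp2 += 1
                ni2 += 1
                v = vr_i
            v_i2[j] = v
        cnt_e1[n] = ne1
        cnt_i1[n] = ni1
        cnt_e2[n] = ne2
        cnt_i2[n] = ni2
        # delayed cross counts; no in-flight spikes before t = 0
        nd = n - m_delay
        cx1 = cnt_e2[nd] if nd >= 0 else 0.0
        cx2 = cnt_e1[nd] if nd >= 0 else 0.0
        see1 = see1 * dec + a_ee * ne1 + g_ee * cx1
        sei1 = sei1 * dec + a_ei * ni1
        sie1 = sie1 * dec + a_ie * ne1 + g_ie * cx1
        sii1 = sii1 * dec + a_ii * ni1
        see2 = see2 * dec + a_ee * ne2 + g_ee * cx2
        sei2 = sei2 * dec + a_ei * ni2
        sie2 = sie2 * dec + a_ie * ne2 + g_ie * cx2
        sii2 = sii2 * dec + a_ii * ni2
    return nsp1, nsp2, cnt_e1, cnt_i1, cnt_e2, cnt_i2
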