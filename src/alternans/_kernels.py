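"""Numba kernels: ionic right-hand sides and tight integration loops.

Everything here works on bare float64 arrays so the loops compile to machine
code.  The public modules wrap these kernels in typed containers; nothing in
this module validates its inputs.

Conventions (package-wide): time in ms, potential in mV, space in mm,
diffusion in mm^2/ms, current density in the cell model's native units per
unit capacitance, so ``dV/dt = -(I_ion + I_stim)`` with Cm folded in.
A *negative* stimulus amplitude depolarises.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Luo-Rudy 1991 guinea-pig ventricular cell (8 state variables)
#
# State layout: [V, m, h, j, d, f, X, Cai]
# Parameter vector layout:
#   p[0] s_gna   dimensionless scaling on g_Na
#   p[1] g_na    maximal Na conductance (mS/uF)
#   p[2] e_na    Na reversal potential (mV)
#   p[3] delta_tau_h  added h-gate time constant (ms) below the threshold
#   p[4] v_mod_threshold (mV)
#   p[5] g_si_scale    scaling on the slow inward (Ca) current
#   p[6] g_k_scale     scaling on I_K
#   p[7] ca_speed      scaling on the d/f gate rates (restitution steepness)
# ---------------------------------------------------------------------------

LR91_NSTATE = 7 + 1  # V + 6 gates + Cai

# Nernst potentials from the model's fixed ionic concentrations
# ([K]o = 5.4, [K]i = 145, [Na]o = 140, [Na]i = 18 mM, RT/F at 37 C).
_RTF = 26.712338
LR91_EK = _RTF * np.log((5.4 + 0.01833 * 140.0) / (145.0 + 0.01833 * 18.0))
LR91_EK1 = _RTF * np.log(5.4 / 145.0)


@njit(cache=True, fastmath=True)
def lr91_rhs(Y, i_stim, dY, p):
    """In-place dY for an array of LR91 cells. Y, dY: (n, 8); i_stim: (n,)."""
    s_gna = p[0]
    g_na = p[1]
    e_na = p[2]
    dtau_h = p[3]
    v_mod = p[4]
    g_si = 0.09 * p[5]
    g_k = 0.282 * p[6]
    ca_speed = p[7]
    for i in range(Y.shape[0]):
        V = Y[i, 0]
        m = Y[i, 1]
        h = Y[i, 2]
        j = Y[i, 3]
        d = Y[i, 4]
        f = Y[i, 5]
        X = Y[i, 6]
        cai = Y[i, 7]

        # --- I_Na gates -----------------------------------------------------
        dv = V + 47.13
        if abs(dv) < 1e-7:
            a_m = 3.2
        else:
            a_m = 0.32 * dv / (1.0 - np.exp(-0.1 * dv))
        b_m = 0.08 * np.exp(-V / 11.0)

        if V < -40.0:
            a_h = 0.135 * np.exp(-(80.0 + V) / 6.8)
            b_h = 3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V)
            a_j = (
                (-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
                * (V + 37.78)
                / (1.0 + np.exp(0.311 * (V + 79.23)))
            )
            b_j = 0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
        else:
            a_h = 0.0
            b_h = 1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
            a_j = 0.0
            b_j = 0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))

        # h gate: slowed recovery — time constant increased below v_mod
        tau_h = 1.0 / (a_h + b_h)
        h_inf = a_h * tau_h
        if V < v_mod:
            tau_h = tau_h + dtau_h

        # --- slow inward (L-type Ca-like) gates -----------------------------
        a_d = ca_speed * 0.095 * np.exp(-0.01 * (V - 5.0)) / (1.0 + np.exp(-0.072 * (V - 5.0)))
        b_d = ca_speed * 0.07 * np.exp(-0.017 * (V + 44.0)) / (1.0 + np.exp(0.05 * (V + 44.0)))
        a_f = ca_speed * 0.012 * np.exp(-0.008 * (V + 28.0)) / (1.0 + np.exp(0.15 * (V + 28.0)))
        b_f = ca_speed * 0.0065 * np.exp(-0.02 * (V + 30.0)) / (1.0 + np.exp(-0.2 * (V + 30.0)))

        # --- time-dependent K gate ------------------------------------------
        a_x = 0.0005 * np.exp(0.083 * (V + 50.0)) / (1.0 + np.exp(0.057 * (V + 50.0)))
        b_x = 0.0013 * np.exp(-0.06 * (V + 20.0)) / (1.0 + np.exp(-0.04 * (V + 20.0)))

        # --- currents -------------------------------------------------------
        i_na = s_gna * g_na * m * m * m * h * j * (V - e_na)

        e_si = 7.7 - 13.0287 * np.log(cai)
        i_si = g_si * d * f * (V - e_si)

        xv = V + 77.0
        if abs(xv) < 1e-7:
            xi = 2.837 * 0.04 / np.exp(0.04 * (V + 35.0))
        elif V > -100.0:
            xi = 2.837 * (np.exp(0.04 * xv) - 1.0) / (xv * np.exp(0.04 * (V + 35.0)))
        else:
            xi = 1.0
        i_k = g_k * X * xi * (V - LR91_EK)

        a_k1 = 1.02 / (1.0 + np.exp(0.2385 * (V - LR91_EK1 - 59.215)))
        b_k1 = (
            0.49124 * np.exp(0.08032 * (V - LR91_EK1 + 5.476))
            + np.exp(0.06175 * (V - LR91_EK1 - 594.31))
        ) / (1.0 + np.exp(-0.5143 * (V - LR91_EK1 + 4.753)))
        i_k1 = 0.6047 * (a_k1 / (a_k1 + b_k1)) * (V - LR91_EK1)

        kp = 1.0 / (1.0 + np.exp((7.488 - V) / 5.98))
        i_kp = 0.0183 * kp * (V - LR91_EK1)

        i_b = 0.03921 * (V + 59.87)

        i_ion = i_na + i_si + i_k + i_k1 + i_kp + i_b

        dY[i, 0] = -(i_ion + i_stim[i])
        dY[i, 1] = a_m * (1.0 - m) - b_m * m
        dY[i, 2] = (h_inf - h) / tau_h
        dY[i, 3] = a_j * (1.0 - j) - b_j * j
        dY[i, 4] = a_d * (1.0 - d) - b_d * d
        dY[i, 5] = a_f * (1.0 - f) - b_f * f
        dY[i, 6] = a_x * (1.0 - X) - b_x * X
        dY[i, 7] = -1.0e-4 * i_si + 0.07 * (1.0e-4 - cai)


# ---------------------------------------------------------------------------
# Three-variable minimal excitable cell (Fenton-Karma form)
#
# State layout: [V, v, w]  (v = fast-inward recovery gate, w = slow gate)
# Parameter vector layout:
#   p[0]  tau_d    p[1] tau_r    p[2] tau_si   p[3] tau_0
#   p[4]  tau_vp   p[5] tau_v1m  p[6] tau_v2m  p[7] tau_wp  p[8] tau_wm
#   p[9]  u_c      p[10] u_v     p[11] u_csi   p[12] k_si
#   p[13] v_rest (mV)            p[14] v_amp (mV)
#   p[15] s_gna (scales fast inward current)
#   p[16] delta_tau_v (ms, added to v-gate recovery below threshold)
#   p[17] v_mod_threshold (mV)
# ---------------------------------------------------------------------------

FK_NSTATE = 3


@njit(cache=True, fastmath=True)
def fk_rhs(Y, i_stim, dY, p):
    """In-place dY for an array of minimal 3-variable cells. Y, dY: (n, 3)."""
    tau_d = p[0] / max(p[15], 1e-12)
    tau_r = p[1]
    tau_si = p[2]
    tau_0 = p[3]
    tau_vp = p[4]
    tau_v1m = p[5]
    tau_v2m = p[6]
    tau_wp = p[7]
    tau_wm = p[8]
    u_c = p[9]
    u_v = p[10]
    u_csi = p[11]
    k_si = p[12]
    v_rest = p[13]
    v_amp = p[14]
    dtau = p[16]
    v_mod = p[17]
    for i in range(Y.shape[0]):
        u = (Y[i, 0] - v_rest) / v_amp
        v = Y[i, 1]
        w = Y[i, 2]
        if u >= u_c:
            j_fi = -v * (1.0 - u) * (u - u_c) / tau_d
            j_so = 1.0 / tau_r
            dv = -v / tau_vp
            dw = -w / tau_wp
        else:
            j_fi = 0.0
            j_so = u / tau_0
            tau_vm = tau_v1m if u >= u_v else tau_v2m
            if Y[i, 0] < v_mod:
                tau_vm = tau_vm + dtau
            dv = (1.0 - v) / tau_vm
            dw = (1.0 - w) / tau_wm
        j_si = -w * (1.0 + np.tanh(k_si * (u - u_csi))) / (2.0 * tau_si)
        i_ion = v_amp * (j_fi + j_so + j_si)
        dY[i, 0] = -(i_ion + i_stim[i])
        dY[i, 1] = dv
        dY[i, 2] = dw


# ---------------------------------------------------------------------------
# Integration drivers
# ---------------------------------------------------------------------------


@njit
def _stim_amp_at(t, onsets, dur, amp):
    """Stimulus amplitude active at time t for a train of pulses."""
    for k in range(onsets.shape[0]):
        if onsets[k] <= t < onsets[k] + dur:
            return amp
        if onsets[k] > t:
            break
    return 0.0


@njit
def run_cell(rhs, y0, p, dt, n_steps, stim_onsets, stim_dur, stim_amp, trace_every, t0):
    """Forward-Euler integration of a single cell.

    Returns (Ytrace, yfinal): full state sampled every `trace_every` steps
    (including step 0) and the final state.
    """
    n_state = y0.shape[0]
    Y = np.empty((1, n_state))
    dY = np.empty((1, n_state))
    ist = np.zeros(1)
    Y[0, :] = y0
    n_saved = n_steps // trace_every + 1
    out = np.empty((n_saved, n_state))
    out[0, :] = y0
    ks = 1
    for step in range(n_steps):
        t = t0 + step * dt
        ist[0] = _stim_amp_at(t, stim_onsets, stim_dur, stim_amp)
        rhs(Y, ist, dY, p)
        for s in range(n_state):
            Y[0, s] += dt * dY[0, s]
        if (step + 1) % trace_every == 0 and ks < n_saved:
            out[ks, :] = Y[0, :]
            ks += 1
    return out, Y[0, :].copy()


@njit
def _thomas_prefactor(lo, di, up):
    """LU prefactor of a tridiagonal matrix; returns (denom, cprime)."""
    n = di.shape[0]
    denom = np.empty(n)
    cp = np.empty(n)
    denom[0] = di[0]
    cp[0] = up[0] / di[0]
    for i in range(1, n):
        denom[i] = di[i] - lo[i] * cp[i - 1]
        cp[i] = up[i] / denom[i]
    return denom, cp


@njit
def _thomas_solve(lo, denom, cp, d, x):
    n = denom.shape[0]
    x[0] = d[0] / denom[0]
    for i in range(1, n):
        x[i] = (d[i] - lo[i] * x[i - 1]) / denom[i]
    for i in range(n - 2, -1, -1):
        x[i] = x[i] - cp[i] * x[i + 1]


@njit
def run_fiber(
    rhs,
    Y0,
    p,
    dt,
    n_steps,
    imp_lo,
    imp_di,
    imp_up,
    exp_lo,
    exp_di,
    exp_up,
    dead,
    stim_extent,
    stim_onsets,
    stim_dur,
    stim_amp,
    save_every,
    probe_idx,
    t0,
):
    """Operator-split (reaction forward-Euler, Crank-Nicolson diffusion) 1D cable.

    Returns (frames, probes, yfinal):
      frames: (n_frames, n_nodes) float32 V snapshots every `save_every` steps,
      probes: (n_steps + 1, n_probes) float64 V at full time resolution.
    """
    n_nodes, n_state = Y0.shape
    Y = Y0.copy()
    dY = np.empty_like(Y)
    ist = np.zeros(n_nodes)
    denom, cp = _thomas_prefactor(imp_lo, imp_di, imp_up)
    rhsd = np.empty(n_nodes)
    x = np.empty(n_nodes)

    n_frames = n_steps // save_every + 1
    frames = np.empty((n_frames, n_nodes), dtype=np.float32)
    probes = np.empty((n_steps + 1, probe_idx.shape[0]))
    for q in range(probe_idx.shape[0]):
        probes[0, q] = Y[probe_idx[q], 0]
    for i in range(n_nodes):
        frames[0, i] = Y[i, 0]
    kf = 1

    for step in range(n_steps):
        t = t0 + step * dt
        amp = _stim_amp_at(t, stim_onsets, stim_dur, stim_amp)
        if amp != 0.0:
            for i in range(stim_extent):
                ist[i] = amp
        # reaction
        rhs(Y, ist, dY, p)
        for i in range(n_nodes):
            if not dead[i]:
                for s in range(n_state):
                    Y[i, s] += dt * dY[i, s]
        if amp != 0.0:
            for i in range(stim_extent):
                ist[i] = 0.0
        # diffusion: solve (I - dt/2 L) V' = (I + dt/2 L) V
        for i in range(n_nodes):
            acc = exp_di[i] * Y[i, 0]
            if i > 0:
                acc += exp_lo[i] * Y[i - 1, 0]
            if i < n_nodes - 1:
                acc += exp_up[i] * Y[i + 1, 0]
            rhsd[i] = acc
        _thomas_solve(imp_lo, denom, cp, rhsd, x)
        for i in range(n_nodes):
            Y[i, 0] = x[i]
        # record
        for q in range(probe_idx.shape[0]):
            probes[step + 1, q] = Y[probe_idx[q], 0]
        if (step + 1) % save_every == 0 and kf < n_frames:
            for i in range(n_nodes):
                frames[kf, i] = Y[i, 0]
            kf += 1
    return frames, probes, Y


@njit
def reaction_step(rhs, Y, i_stim, dY, dt, dead, p):
    """One forward-Euler reaction substep over all live nodes (2D path)."""
    rhs(Y, i_stim, dY, p)
    n_nodes, n_state = Y.shape
    for i in range(n_nodes):
        if not dead[i]:
            for s in range(n_state):
                Y[i, s] += dt * dY[i, s]
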