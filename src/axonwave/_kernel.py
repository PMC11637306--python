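"""Numba time-stepping kernel for the branched cable equation.

One backward-Euler step per dt: gate variables advance by the exact
exponential (Rush-Larsen) update at the frozen start-of-step voltage, the
gated conductances then enter an implicit linear solve for the voltage.  The
tree-structured system is solved exactly each step by one child-to-root
elimination sweep and a root-to-leaf back-substitution over compartments in
Hines order (parent index < child index).  The GHK Ca current — orders of
magnitude smaller than the Na/K currents — is treated explicitly at the
start-of-step voltage.

Node-level units: nF, uS, MOhm, nA, mV, ms.
"""

import math

import numpy as np
from numba import njit

# output current species order
I_NA, I_K, I_KCOMP, I_CA, I_LEAK = 0, 1, 2, 3, 4
N_SPECIES = 5


@njit(cache=True, fastmath=False)
def _vtrap(x, y):
    if abs(x / y) < 1e-7:
        return y * (1.0 - x / y / 2.0)
    return x / math.expm1(x / y)


@njit(cache=True, fastmath=False)
def _hh_gate_update(v, x, gate, shift, scale, dt):
    """One Rush-Larsen update of squid gate 'gate' (0=m,1=h,2=n)."""
    u = v - shift
    if gate == 0:
        a = 0.1 * _vtrap(-(u + 40.0), 10.0)
        b = 4.0 * math.exp(-(u + 65.0) / 18.0)
    elif gate == 1:
        a = 0.07 * math.exp(-(u + 65.0) / 20.0)
        b = 1.0 / (1.0 + math.exp(-(u + 35.0) / 10.0))
    else:
        a = 0.01 * _vtrap(-(u + 55.0), 10.0)
        b = 0.125 * math.exp(-(u + 65.0) / 80.0)
    a *= scale
    b *= scale
    tot = a + b
    xinf = a / tot
    return xinf + (x - xinf) * math.exp(-dt * tot)


@njit(cache=True, fastmath=False)
def _boltz_gate_update(v, x, vhalf, slope, tau_min, tau_amp, rate_factor, dt):
    xinf = 1.0 / (1.0 + math.exp(-(v - vhalf) / slope))
    tau = (tau_min + tau_amp / math.cosh((v - vhalf) / (2.0 * slope))) / rate_factor
    return xinf + (x - xinf) * math.exp(-dt / tau)


@njit(cache=True, fastmath=False)
def _ghk_unit(v, u_coef, ci, co, zf3):
    """GHK current density per unit permeability (mA/cm^2 per cm/s)."""
    u = u_coef * v
    if abs(u) < 1e-12:
        ratio = 1.0
    else:
        ratio = u / (-math.expm1(-u))
    flux = ci - co * math.exp(-u)
    return zf3 * flux * ratio


@njit(cache=True, fastmath=False)
def integrate(parent, g_pair, cap, g_leak, e_leak,
              g_na, g_k, g_kc, ca_coef,
              v, m, h, nn, ks, kc, cg,
              e_na, e_k,
              shift_na, shift_h, shift_k, scale_na, scale_h, scale_k,
              use_slow_k, slow_tau, slow_tau_depol, slow_vhalf, slow_slope,
              slow_floor,
              kc_vhalf, kc_slope, kc_tau_min, kc_tau_amp,
              ca_vhalf, ca_slope, ca_tau_min, ca_tau_amp, ca_rate_factor,
              u_coef, ca_in, ca_out, zf3,
              stim_sites, stim_wave,
              clamp_site, g_clamp, clamp_v,
              rec_idx, record_currents, record_ca_all,
              dt, nsteps, store):
    """Advance the circuit ``nsteps`` steps; state arrays update in place.

    Returns (v_out, cur_out, ica_out, clamp_current, vmax_abs).  Trace
    arrays have ``nsteps + 1`` rows (initial state first) when ``store`` is
    True, else a single row.
    """
    n = parent.size
    nrec = rec_idx.size
    rows = nsteps + 1 if store else 1
    v_out = np.empty((rows, n))
    cur_out = np.empty((N_SPECIES, rows, nrec)) if record_currents \
        else np.empty((N_SPECIES, 1, 1))
    ica_out = np.empty((rows, n)) if record_ca_all else np.empty((1, 1))
    clamp_current = np.empty(rows) if clamp_site >= 0 else np.empty(1)

    d = np.empty(n)
    rhs = np.empty(n)
    ica_nA = np.empty(n)

    has_ca = ca_coef.shape[0] > 0
    n_sub = ca_coef.shape[0]

    if store:
        v_out[0, :] = v
        if record_ca_all:
            ica_out[0, :] = 0.0
        if record_currents:
            cur_out[:, 0, :] = 0.0
        if clamp_site >= 0:
            clamp_current[0] = 0.0

    vmax_abs = 0.0
    for t in range(nsteps):
        # --- gates (Rush-Larsen at frozen voltage) -----------------------
        for i in range(n):
            vi = v[i]
            if g_na[i] > 0.0:
                m[i] = _hh_gate_update(vi, m[i], 0, shift_na, scale_na, dt)
                h[i] = _hh_gate_update(vi, h[i], 1, shift_h, scale_h, dt)
            if g_k[i] > 0.0:
                nn[i] = _hh_gate_update(vi, nn[i], 2, shift_k, scale_k, dt)
                if use_slow_k:
                    sinf = slow_floor + (1.0 - slow_floor) / (
                        1.0 + math.exp((vi - slow_vhalf) / slow_slope))
                    # inactivation develops fast at depolarized potentials
                    # and recovers slowly at rest (cumulative over trains)
                    stau = slow_tau_depol if vi > slow_vhalf else slow_tau
                    ks[i] = sinf + (ks[i] - sinf) * math.exp(-dt / stau)
            if g_kc[i] > 0.0:
                kc[i] = _boltz_gate_update(vi, kc[i], kc_vhalf, kc_slope,
                                           kc_tau_min, kc_tau_amp, 1.0, dt)
            if has_ca:
                for s in range(n_sub):
                    cg[s, i] = _boltz_gate_update(
                        vi, cg[s, i], ca_vhalf[s], ca_slope[s],
                        ca_tau_min[s], ca_tau_amp[s], ca_rate_factor, dt)

        # --- assemble implicit system ------------------------------------
        for i in range(n):
            vi = v[i]
            gna = g_na[i] * m[i] ** 3 * h[i]
            gk = g_k[i] * nn[i] ** 4 * (ks[i] if use_slow_k else 1.0)
            gkc = g_kc[i] * kc[i]
            ica = 0.0
            if has_ca:
                unit = _ghk_unit(vi, u_coef, ca_in, ca_out, zf3)
                for s in range(n_sub):
                    ica += ca_coef[s, i] * cg[s, i] ** 2 * unit
            ica_nA[i] = ica
            di = cap[i] / dt + g_leak[i] + gna + gk + gkc
            ri = (cap[i] / dt * vi + g_leak[i] * e_leak[i]
                  + gna * e_na + (gk + gkc) * e_k - ica)
            if parent[i] >= 0:
                di += g_pair[i]
            d[i] = di
            rhs[i] = ri
        for i in range(1, n):
            d[parent[i]] += g_pair[i]
        for s in range(stim_sites.size):
            rhs[stim_sites[s]] += stim_wave[s, t]
        if clamp_site >= 0:
            d[clamp_site] += g_clamp
            rhs[clamp_site] += g_clamp * clamp_v[t]

        # --- Hines solve ---------------------------------------------------
        for i in range(n - 1, 0, -1):
            f = g_pair[i] / d[i]
            p = parent[i]
            d[p] -= f * g_pair[i]
            rhs[p] += f * rhs[i]
        v[0] = rhs[0] / d[0]
        if abs(v[0]) > vmax_abs:
            vmax_abs = abs(v[0])
        for i in range(1, n):
            v[i] = (rhs[i] + g_pair[i] * v[parent[i]]) / d[i]
            if abs(v[i]) > vmax_abs:
                vmax_abs = abs(v[i])

        # --- record --------------------------------------------------------
        if store:
            row = t + 1
            v_out[row, :] = v
            if record_ca_all:
                ica_out[row, :] = ica_nA
            if record_currents:
                for r in range(nrec):
                    i = rec_idx[r]
                    gna = g_na[i] * m[i] ** 3 * h[i]
                    gk = g_k[i] * nn[i] ** 4 * (ks[i] if use_slow_k else 1.0)
                    gkc = g_kc[i] * kc[i]
                    cur_out[I_NA, row, r] = gna * (v[i] - e_na)
                    cur_out[I_K, row, r] = gk * (v[i] - e_k)
                    cur_out[I_KCOMP, row, r] = gkc * (v[i] - e_k)
                    cur_out[I_CA, row, r] = ica_nA[i]
                    cur_out[I_LEAK, row, r] = g_leak[i] * (v[i] - e_leak[i])
            if clamp_site >= 0:
                clamp_current[row] = g_clamp * (clamp_v[t] - v[clamp_site])

    if not store:
        v_out[0, :] = v

    return v_out, cur_out, ica_out, clamp_current, vmax_abs
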