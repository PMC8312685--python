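"""Fixed-step forward-Euler integration kernel (numba-compiled).

The kernel advances the full coupled state - two neurons, the vesicle
resource pools and the ten compartment concentrations - with the same scalar
current laws the public modules expose (it calls the very same compiled
functions), detects presynaptic/postsynaptic spikes as upward threshold
crossings with a refractory guard, and applies spike-triggered transmitter
release at the end of the step in which the crossing is detected.

Everything here is in canonical units (V, s, A/m^2, mM).  The kernel is
deterministic: identical inputs produce bit-identical outputs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .astro import (_eaat_current, _species_currents, eaat_reversal,
                    gat_current, gat_reversal, kir_current, leak_current,
                    nernst, nka_current, ncx_current, nkcc_current)
from .neuron import (h_inf, mg_block, n_inf, receptor_kinetics_derivative,
                     tau_h_ms, tau_n_ms, voltage_gated_currents)
from .release import apply_spike, resource_derivatives

# --- state vector layout -----------------------------------------------------
S_V_PRE, S_H_PRE, S_N_PRE, S_RG_PRE = 0, 1, 2, 3
S_V_POST, S_H_POST, S_N_POST, S_RN_POST, S_RA_POST, S_RG_POST = 4, 5, 6, 7, 8, 9
S_X, S_Y, S_Z = 10, 11, 12
S_NA_SYN, S_K_SYN, S_GLU_SYN, S_CA_SYN, S_GABA_SYN = 13, 14, 15, 16, 17
S_NA_AST, S_K_AST, S_GLU_AST, S_CA_AST, S_GABA_AST = 18, 19, 20, 21, 22
S_LED_GLU, S_LED_K = 23, 24
NSTATE = 25

CONC_SLOTS = np.array([S_NA_SYN, S_K_SYN, S_GLU_SYN, S_CA_SYN, S_GABA_SYN,
                       S_NA_AST, S_K_AST, S_GLU_AST, S_CA_AST, S_GABA_AST],
                      dtype=np.int64)

# --- parameter vector layout -------------------------------------------------
(P_VT, P_F_AST, P_F_SYN, P_MOL_SYN,
 P_CM, P_GNA, P_GK, P_GL, P_EL,
 P_GNMDA, P_GAMPA, P_GGABAA_PRE, P_GGABAA_POST,
 P_ENMDA, P_EAMPA, P_EGABAA,
 P_ANMDA, P_AAMPA, P_AGABAA, P_BNMDA, P_BAMPA, P_BGABAA,
 P_NA_IN, P_K_IN, P_MG,
 P_U, P_TAU_R, P_TAU_I, P_GLU_SCALE, P_K_RELEASE, P_RELEASE_CONT,
 P_INKA, P_KNAI, P_KKE, P_INCX, P_GAMMA, P_AEAAT, P_BEAAT,
 P_GKIR, P_GGAT, P_EKIR_OFF, P_INKCC, P_NKCC_ON, P_SNKAK,
 P_VA, P_HRATIO, P_CLRATIO,
 P_GLNA, P_GLK, P_GLGLU, P_GLCA,
 P_ZNA, P_ZK, P_ZGLU, P_ZCA, P_ZGABA,
 P_AMP, P_RATE, P_WIDTH, P_WSTART, P_WDUR,
 P_THRESH, P_REFRACT) = range(63)
NPARAMS = 63

TRACE_COLUMNS = (
    "t", "v_pre", "v_post",
    "na_syn", "k_syn", "glu_syn", "ca_syn", "gaba_syn",
    "na_ast", "k_ast", "glu_ast", "ca_ast", "gaba_ast",
    "x", "y", "z", "e_eaat", "e_gat",
    "i_eaat", "i_gat", "i_nka", "i_ncx", "i_kir", "i_nkcc",
    "i_na_leak", "i_k_leak", "i_glu_leak", "i_ca_leak",
    "i_na_ast", "i_k_ast", "i_glu_ast", "i_ca_ast", "i_gaba_ast",
    "i_app",
)
NCOLS = len(TRACE_COLUMNS)

STATUS_OK = 0
STATUS_NONFINITE = 1
STATUS_NONPOSITIVE = 2


@njit(cache=True)
def pulsed_current_kernel(t, amp, rate, width, wstart, wdur):
    """Square-pulse applied current density (canonical units)."""
    if t < wstart or t >= wstart + wdur:
        return 0.0
    phase = (t - wstart) % (1.0 / rate)
    if phase < width:
        return amp
    return 0.0


@njit(cache=True)
def integrate(state0, p, dt, n_steps, stride, n_rows, spike_cap):
    """Advance ``n_steps`` Euler steps from ``state0``.

    Returns (traces, spikes_pre, n_pre, spikes_post, n_post, status,
    fail_time, fail_slot, final_state).  Rows of ``traces`` are recorded
    every ``stride`` steps plus the final state.
    """
    s = state0.copy()
    traces = np.empty((n_rows, NCOLS))
    spikes_pre = np.empty(spike_cap)
    spikes_post = np.empty(spike_cap)
    n_pre = 0
    n_post = 0
    status = STATUS_OK
    fail_time = -1.0
    fail_slot = -1
    row = 0
    last_pre = -1e9
    last_post = -1e9

    vt = p[P_VT]
    for i in range(n_steps + 1):
        t = i * dt

        # --- neuronal reversal potentials (fixed internal concentrations)
        e_na_n = vt * np.log(s[S_NA_SYN] / p[P_NA_IN])
        e_k_n = vt * np.log(s[S_K_SYN] / p[P_K_IN])

        # --- presynaptic neuron
        i_na_pre, i_k_pre, i_l_pre = voltage_gated_currents(
            s[S_V_PRE], s[S_H_PRE], s[S_N_PRE],
            p[P_GNA], p[P_GK], p[P_GL], e_na_n, e_k_n, p[P_EL])
        i_gabaa_pre = p[P_GGABAA_PRE] * s[S_RG_PRE] * (s[S_V_PRE] - p[P_EGABAA])
        i_app = pulsed_current_kernel(t, p[P_AMP], p[P_RATE], p[P_WIDTH],
                                      p[P_WSTART], p[P_WDUR])
        dv_pre = (-(i_na_pre + i_k_pre + i_l_pre + i_gabaa_pre) + i_app) / p[P_CM]
        v_pre_mv = s[S_V_PRE] * 1e3
        dh_pre = (h_inf(v_pre_mv) - s[S_H_PRE]) / (tau_h_ms(v_pre_mv) * 1e-3)
        dn_pre = (n_inf(v_pre_mv) - s[S_N_PRE]) / (tau_n_ms(v_pre_mv) * 1e-3)
        drg_pre = receptor_kinetics_derivative(
            s[S_RG_PRE], s[S_GABA_SYN], p[P_AGABAA], p[P_BGABAA])

        # --- postsynaptic neuron
        i_na_post, i_k_post, i_l_post = voltage_gated_currents(
            s[S_V_POST], s[S_H_POST], s[S_N_POST],
            p[P_GNA], p[P_GK], p[P_GL], e_na_n, e_k_n, p[P_EL])
        i_nmda = (p[P_GNMDA] * s[S_RN_POST] * (s[S_V_POST] - p[P_ENMDA])
                  * mg_block(s[S_V_POST], p[P_MG]))
        i_ampa = p[P_GAMPA] * s[S_RA_POST] * (s[S_V_POST] - p[P_EAMPA])
        i_gabaa_post = p[P_GGABAA_POST] * s[S_RG_POST] * (s[S_V_POST] - p[P_EGABAA])
        dv_post = (-(i_na_post + i_k_post + i_l_post
                     + i_nmda + i_ampa + i_gabaa_post)) / p[P_CM]
        v_post_mv = s[S_V_POST] * 1e3
        dh_post = (h_inf(v_post_mv) - s[S_H_POST]) / (tau_h_ms(v_post_mv) * 1e-3)
        dn_post = (n_inf(v_post_mv) - s[S_N_POST]) / (tau_n_ms(v_post_mv) * 1e-3)
        drn_post = receptor_kinetics_derivative(
            s[S_RN_POST], s[S_GLU_SYN], p[P_ANMDA], p[P_BNMDA])
        dra_post = receptor_kinetics_derivative(
            s[S_RA_POST], s[S_GLU_SYN], p[P_AAMPA], p[P_BAMPA])
        drg_post = receptor_kinetics_derivative(
            s[S_RG_POST], s[S_GABA_SYN], p[P_AGABAA], p[P_BGABAA])

        # --- vesicle resources (continuous part)
        dx, dy, dz = resource_derivatives(s[S_X], s[S_Y], s[S_Z],
                                          p[P_TAU_R], p[P_TAU_I])

        # --- astrocytic currents
        e_eaat = eaat_reversal(s[S_NA_SYN], s[S_NA_AST], p[P_HRATIO],
                               s[S_GLU_SYN], s[S_GLU_AST],
                               s[S_K_SYN], s[S_K_AST], vt)
        e_gat = gat_reversal(s[S_NA_SYN], s[S_NA_AST], s[S_GABA_SYN],
                             s[S_GABA_AST], p[P_CLRATIO], vt)
        i_eaat = _eaat_current(p[P_VA], e_eaat, p[P_AEAAT], p[P_BEAAT])
        i_gat = gat_current(p[P_VA], e_gat, p[P_GGAT])
        i_nka = nka_current(s[S_NA_AST], s[S_K_SYN], p[P_INKA], p[P_KNAI], p[P_KKE])
        i_ncx = ncx_current(s[S_NA_AST], s[S_NA_SYN], s[S_CA_AST], s[S_CA_SYN],
                            p[P_VA], p[P_INCX], p[P_GAMMA], vt)
        e_k_ast = nernst(s[S_K_SYN], s[S_K_AST], p[P_ZK], vt)
        i_kir = kir_current(s[S_K_SYN], p[P_VA], e_k_ast, p[P_GKIR], p[P_EKIR_OFF])
        i_nkcc = 0.0
        if p[P_NKCC_ON] != 0.0:
            i_nkcc = nkcc_current(s[S_NA_SYN], s[S_NA_AST], s[S_K_SYN],
                                  s[S_K_AST], p[P_CLRATIO], p[P_INKCC])
        e_na_ast = nernst(s[S_NA_SYN], s[S_NA_AST], p[P_ZNA], vt)
        e_glu_ast = nernst(s[S_GLU_SYN], s[S_GLU_AST], p[P_ZGLU], vt)
        e_ca_ast = nernst(s[S_CA_SYN], s[S_CA_AST], p[P_ZCA], vt)
        i_na_leak = leak_current(p[P_GLNA], p[P_VA], e_na_ast)
        i_k_leak = leak_current(p[P_GLK], p[P_VA], e_k_ast)
        i_glu_leak = leak_current(p[P_GLGLU], p[P_VA], e_glu_ast)
        i_ca_leak = leak_current(p[P_GLCA], p[P_VA], e_ca_ast)
        i_na_sp, i_k_sp, i_glu_sp, i_ca_sp, i_gaba_sp = _species_currents(
            i_eaat, i_gat, i_nka, i_ncx, i_kir, i_nkcc,
            i_na_leak, i_k_leak, i_glu_leak, i_ca_leak,
            p[P_SNKAK], p[P_NKCC_ON] != 0.0)

        # --- concentration derivatives (Faraday conversion; astro currents only)
        f_ast = p[P_F_AST]
        f_syn = p[P_F_SYN]
        dna_ast = -f_ast * i_na_sp / p[P_ZNA]
        dna_syn = f_syn * i_na_sp / p[P_ZNA]
        dk_ast = -f_ast * i_k_sp / p[P_ZK]
        dk_syn = f_syn * i_k_sp / p[P_ZK]
        dglu_ast = -f_ast * i_glu_sp / p[P_ZGLU]
        dglu_syn = f_syn * i_glu_sp / p[P_ZGLU]
        dca_ast = -f_ast * i_ca_sp / p[P_ZCA]
        dca_syn = f_syn * i_ca_sp / p[P_ZCA]
        dgaba_ast = -f_ast * i_gaba_sp / p[P_ZGABA]
        dgaba_syn = f_syn * i_gaba_sp / p[P_ZGABA]
        dled_glu = 0.0
        if p[P_RELEASE_CONT] != 0.0:
            # continuous transmitter source proportional to the active pool
            src = p[P_GLU_SCALE] * s[S_Y]
            dglu_syn += src
            dled_glu = src * p[P_MOL_SYN]

        # --- record
        if i % stride == 0 or i == n_steps:
            traces[row, 0] = t
            traces[row, 1] = s[S_V_PRE]
            traces[row, 2] = s[S_V_POST]
            traces[row, 3] = s[S_NA_SYN]
            traces[row, 4] = s[S_K_SYN]
            traces[row, 5] = s[S_GLU_SYN]
            traces[row, 6] = s[S_CA_SYN]
            traces[row, 7] = s[S_GABA_SYN]
            traces[row, 8] = s[S_NA_AST]
            traces[row, 9] = s[S_K_AST]
            traces[row, 10] = s[S_GLU_AST]
            traces[row, 11] = s[S_CA_AST]
            traces[row, 12] = s[S_GABA_AST]
            traces[row, 13] = s[S_X]
            traces[row, 14] = s[S_Y]
            traces[row, 15] = s[S_Z]
            traces[row, 16] = e_eaat
            traces[row, 17] = e_gat
            traces[row, 18] = i_eaat
            traces[row, 19] = i_gat
            traces[row, 20] = i_nka
            traces[row, 21] = i_ncx
            traces[row, 22] = i_kir
            traces[row, 23] = i_nkcc
            traces[row, 24] = i_na_leak
            traces[row, 25] = i_k_leak
            traces[row, 26] = i_glu_leak
            traces[row, 27] = i_ca_leak
            traces[row, 28] = i_na_sp
            traces[row, 29] = i_k_sp
            traces[row, 30] = i_glu_sp
            traces[row, 31] = i_ca_sp
            traces[row, 32] = i_gaba_sp
            traces[row, 33] = i_app
            row += 1
        if i == n_steps:
            break

        # --- Euler update
        v_pre_old = s[S_V_PRE]
        v_post_old = s[S_V_POST]
        s[S_V_PRE] += dt * dv_pre
        s[S_H_PRE] += dt * dh_pre
        s[S_N_PRE] += dt * dn_pre
        s[S_RG_PRE] += dt * drg_pre
        s[S_V_POST] += dt * dv_post
        s[S_H_POST] += dt * dh_post
        s[S_N_POST] += dt * dn_post
        s[S_RN_POST] += dt * drn_post
        s[S_RA_POST] += dt * dra_post
        s[S_RG_POST] += dt * drg_post
        s[S_X] += dt * dx
        s[S_Y] += dt * dy
        s[S_Z] += dt * dz
        s[S_NA_SYN] += dt * dna_syn
        s[S_K_SYN] += dt * dk_syn
        s[S_GLU_SYN] += dt * dglu_syn
        s[S_CA_SYN] += dt * dca_syn
        s[S_GABA_SYN] += dt * dgaba_syn
        s[S_NA_AST] += dt * dna_ast
        s[S_K_AST] += dt * dk_ast
        s[S_GLU_AST] += dt * dglu_ast
        s[S_CA_AST] += dt * dca_ast
        s[S_GABA_AST] += dt * dgaba_ast
        s[S_LED_GLU] += dt * dled_glu
        t_new = t + dt

        # --- spike events (end of the step in which the crossing occurred)
        if (v_pre_old < p[P_THRESH] and s[S_V_PRE] >= p[P_THRESH]
                and t_new - last_pre >= p[P_REFRACT]):
            last_pre = t_new
            if n_pre < spike_cap:
                spikes_pre[n_pre] = t_new
                n_pre += 1
            x_new, y_new, z_new, released = apply_spike(
                s[S_X], s[S_Y], s[S_Z], p[P_U])
            s[S_X] = x_new
            s[S_Y] = y_new
            s[S_Z] = z_new
            if p[P_RELEASE_CONT] == 0.0 and released > 0.0:
                dglu = p[P_GLU_SCALE] * released
                s[S_GLU_SYN] += dglu
                s[S_LED_GLU] += dglu * p[P_MOL_SYN]
            if released > 0.0:
                s[S_K_SYN] += p[P_K_RELEASE]
                s[S_LED_K] += p[P_K_RELEASE] * p[P_MOL_SYN]
        if (v_post_old < p[P_THRESH] and s[S_V_POST] >= p[P_THRESH]
                and t_new - last_post >= p[P_REFRACT]):
            last_post = t_new
            if n_post < spike_cap:
                spikes_post[n_post] = t_new
                n_post += 1

        # --- sanity: finite state, positive concentrations
        ok = True
        for j in range(NSTATE):
            if not np.isfinite(s[j]):
                status = STATUS_NONFINITE
                fail_slot = j
                ok = False
                break
        if ok:
            for j in CONC_SLOTS:
                if s[j] <= 0.0:
                    status = STATUS_NONPOSITIVE
                    fail_slot = j
                    ok = False
                    break
        if not ok:
            fail_time = t_new
            break

    return (traces[:row], spikes_pre[:n_pre], spikes_post[:n_post],
            status, fail_time, fail_slot, s)
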