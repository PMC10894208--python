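"""Numba-compiled integrator for the two-compartment microcircuit.

State layout: per neuron a soma (index 0) and dendrite (index 1)
voltage; Hodgkin-Huxley gates on both compartments (inactive gates have
zero conductance and are integrated harmlessly); per synapse a pair of
exponentially decaying states (A rise, B decay) whose difference is the
dual-exponential conductance.  Gating variables advance by exponential
Euler; voltages by a semi-implicit update (implicit in the compartment's
own voltage, explicit in the neighbor's).  Spikes are upward 0 mV
crossings at the soma with a 1 ms refractory window.

The exogenous uniform field enters through the extracellular-potential
difference across the soma-dendrite axis: the axial coupling current of
compartment c is g_c * (V_other - V_c +/- dVe(t)) with
dVe = V_e(dendrite) - V_e(soma) = -E(t) . axis * L.
"""

from __future__ import annotations

import numba
import numpy as np

from .channels import na_rates, kv_rates, km_gate, ca_rates, mg_block, vtrap

DIVERGENCE_MV = 200.0
REFRACTORY_MS = 1.0


@numba.njit(cache=True)
def integrate(n_steps, dt,
              # per-neuron, per-compartment parameters: shape (n, 2)
              area, cm, g_leak, e_leak, g_na, g_kv, g_km, g_ca, g_kca,
              # per-neuron parameters: shape (n,)
              v_t, gc_us, dve_coeff,
              # reversals / kinetics constants
              e_na, e_k, e_ca, alpha_ca, ca_rest, tau_ca, kd_kca, mg, tau_max_m,
              # field (times in ms inside the kernel)
              f_amp, f_cyc_per_ms, t_on_ms, t_off_ms, ramp_ms,
              # synapses: shape (n_syn,)
              syn_src, syn_tgt, syn_comp, syn_e, syn_is_nmda,
              dec_r, dec_d, inc_amp, delay_steps,
              # outgoing synapse lists, CSR over neurons
              out_start, out_syn,
              # poisson events: sorted step indices + target synapse ids
              pois_steps, pois_syn,
              # outputs
              spike_steps, spike_counts, v_rec, rec_stride,
              v_init):
    n = area.shape[0]
    n_syn = syn_src.shape[0]

    v = np.empty((n, 2))
    for i in range(n):
        v[i, 0] = v_init
        v[i, 1] = v_init
    # gates: m, h, nk, p, q, r per compartment; calcium per compartment
    gm_ = np.empty((n, 2)); gh = np.empty((n, 2)); gn = np.empty((n, 2))
    gp = np.empty((n, 2)); gq = np.empty((n, 2)); gr = np.empty((n, 2))
    ca = np.empty((n, 2))
    for i in range(n):
        for c in range(2):
            vv = v[i, c]
            am, bm, ah, bh = na_rates(vv, v_t[i])
            an, bn = kv_rates(vv, v_t[i])
            p_inf, _ = km_gate(vv, tau_max_m)
            aq, bq, ar, br = ca_rates(vv)
            gm_[i, c] = am / (am + bm)
            gh[i, c] = ah / (ah + bh)
            gn[i, c] = an / (an + bn)
            gp[i, c] = p_inf
            gq[i, c] = aq / (aq + bq)
            gr[i, c] = ar / (ar + br)
            ca[i, c] = ca_rest

    syn_a = np.zeros(n_syn)
    syn_b = np.zeros(n_syn)
    max_delay = 0
    for s in range(n_syn):
        if delay_steps[s] > max_delay:
            max_delay = delay_steps[s]
    ring_len = max_delay + 1
    ring = np.zeros((n_syn, ring_len))

    last_spike = np.full(n, -1e12)
    refr_steps = REFRACTORY_MS / dt
    n_pois = pois_steps.shape[0]
    p_ptr = 0
    rec_i = 0

    for step in range(n_steps):
        t = step * dt
        slot = step % ring_len

        # --- synaptic state update: decay, then apply due events
        for s in range(n_syn):
            syn_a[s] *= dec_r[s]
            syn_b[s] *= dec_d[s]
            due = ring[s, slot]
            if due > 0.0:
                syn_a[s] += due
                syn_b[s] += due
                ring[s, slot] = 0.0
        while p_ptr < n_pois and pois_steps[p_ptr] == step:
            s = pois_syn[p_ptr]
            syn_a[s] += inc_amp[s]
            syn_b[s] += inc_amp[s]
            p_ptr += 1

        # --- field scalar
        e_scal = 0.0
        if f_amp > 0.0 and t_on_ms <= t < t_off_ms:
            env = 1.0
            if ramp_ms > 0.0:
                up = (t - t_on_ms) / ramp_ms
                down = (t_off_ms - t) / ramp_ms
                if up < env:
                    env = up
                if down < env:
                    env = down
                if env < 0.0:
                    env = 0.0
            e_scal = f_amp * env * np.cos(2.0 * np.pi * f_cyc_per_ms * (t - t_on_ms))

        # --- per-compartment synaptic conductance sums (uS)
        g_syn = np.zeros((n, 2))
        ge_syn = np.zeros((n, 2))
        for s in range(n_syn):
            g = syn_b[s] - syn_a[s]
            if g <= 0.0:
                continue
            i = syn_tgt[s]
            c = syn_comp[s]
            if syn_is_nmda[s] == 1:
                g *= mg_block(v[i, c], mg)
            g_syn[i, c] += g
            ge_syn[i, c] += g * syn_e[s]

        # --- neurons
        for i in range(n):
            dve = dve_coeff[i] * e_scal  # mV, V_e(dend) - V_e(soma)
            vs_old = v[i, 0]
            for c in range(2):
                vv = v[i, c]
                # gate updates (exponential Euler)
                am, bm, ah, bh = na_rates(vv, v_t[i])
                an, bn = kv_rates(vv, v_t[i])
                asum = am + bm
                gm_[i, c] += (am / asum - gm_[i, c]) * (1.0 - np.exp(-dt * asum))
                hsum = ah + bh
                gh[i, c] += (ah / hsum - gh[i, c]) * (1.0 - np.exp(-dt * hsum))
                nsum = an + bn
                gn[i, c] += (an / nsum - gn[i, c]) * (1.0 - np.exp(-dt * nsum))
                if g_km[i, c] > 0.0:
                    p_inf, tau_p = km_gate(vv, tau_max_m)
                    gp[i, c] += (p_inf - gp[i, c]) * (1.0 - np.exp(-dt / tau_p))
                if g_ca[i, c] > 0.0 or g_kca[i, c] > 0.0:
                    aq, bq, ar, br = ca_rates(vv)
                    qsum = aq + bq
                    gq[i, c] += (aq / qsum - gq[i, c]) * (1.0 - np.exp(-dt * qsum))
                    rsum = ar + br
                    gr[i, c] += (ar / rsum - gr[i, c]) * (1.0 - np.exp(-dt * rsum))

                # ionic conductances (mS/cm^2) and their reversal-weighted sum
                gtot = g_leak[i, c]
                gets = g_leak[i, c] * e_leak[i, c]
                if g_na[i, c] > 0.0:
                    gna = g_na[i, c] * gm_[i, c] ** 3 * gh[i, c]
                    gtot += gna
                    gets += gna * e_na
                if g_kv[i, c] > 0.0:
                    gkv = g_kv[i, c] * gn[i, c] ** 4
                    gtot += gkv
                    gets += gkv * e_k
                if g_km[i, c] > 0.0:
                    gkm = g_km[i, c] * gp[i, c]
                    gtot += gkm
                    gets += gkm * e_k
                i_ca_spec = 0.0
                if g_ca[i, c] > 0.0:
                    gca = g_ca[i, c] * gq[i, c] ** 2 * gr[i, c]
                    gtot += gca
                    gets += gca * e_ca
                    i_ca_spec = gca * (vv - e_ca)
                if g_kca[i, c] > 0.0:
                    caf = ca[i, c] / (ca[i, c] + kd_kca)
                    gkca = g_kca[i, c] * caf
                    gtot += gkca
                    gets += gkca * e_k
                # calcium pool
                if g_ca[i, c] > 0.0 or g_kca[i, c] > 0.0:
                    ca[i, c] += dt * (-alpha_ca * i_ca_spec
                                      - (ca[i, c] - ca_rest) / tau_ca)
                    if ca[i, c] < 0.0:
                        ca[i, c] = 0.0

                # synaptic + axial terms as specific conductances
                a = area[i, c]
                gs = g_syn[i, c] * 1e-3 / a       # mS/cm^2
                ges = ge_syn[i, c] * 1e-3 / a
                gc_spec = gc_us[i] * 1e-3 / a
                if c == 0:
                    rev_ax = v[i, 1] + dve
                else:
                    rev_ax = vs_old - dve

                denom = 1.0 + (dt / cm[i, c]) * (gtot + gs + gc_spec)
                num = vv + (dt / cm[i, c]) * (gets + ges + gc_spec * rev_ax)
                v[i, c] = num / denom

            # spike detection at the soma
            if vs_old < 0.0 <= v[i, 0] and (step - last_spike[i]) > refr_steps:
                last_spike[i] = step
                k = spike_counts[i]
                if k < spike_steps.shape[1]:
                    spike_steps[i, k] = step
                spike_counts[i] = k + 1
                for o in range(out_start[i], out_start[i + 1]):
                    s = out_syn[o]
                    ring[s, (step + delay_steps[s]) % ring_len] += inc_amp[s]

            if abs(v[i, 0]) > DIVERGENCE_MV or abs(v[i, 1]) > DIVERGENCE_MV:
                return step

        if rec_stride > 0 and step % rec_stride == 0:
            if rec_i < v_rec.shape[2]:
                for i in range(n):
                    v_rec[i, 0, rec_i] = v[i, 0]
                    v_rec[i, 1, rec_i] = v[i, 1]
                rec_i += 1

    return -1


def dual_exp_peak_norm(tau_r: float, tau_d: float) -> float:
    """Peak of exp(-t/tau_d) - exp(-t/tau_r) for unit state increments."""
    t_star = (tau_r * tau_d / (tau_d - tau_r)) * np.log(tau_d / tau_r)
    return float(np.exp(-t_star / tau_d) - np.exp(-t_star / tau_r))
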