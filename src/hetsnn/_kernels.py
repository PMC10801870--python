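"""Numba-compiled Euler integration kernels.

Two kernels do all the heavy lifting: one for networks of Izhikevich
spiking neurons (arbitrary number of populations and synapse types,
event-driven synaptic increments on a sparse out-edge structure), and
one for the coupled mean-field rate equations. Both use the explicit
Euler scheme; all rates are in spikes/ms internally.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# stimulus segment waveforms
SEG_STEP = 0
SEG_RAMP = 1
SEG_SINUSOID = 2

# kernel status codes
OK = 0
ERR_OVERFLOW = -1
ERR_NONFINITE = -2


@njit(cache=True)
def snn_euler(
    v, u, s,                     # v:(N,), u:(n_pop,) or (N,), s:(n_types, N)
    pop_of, pop_count,           # (N,) int32, (n_pop,)
    vth, C, k, vr,               # per-neuron arrays
    vp, v0,                      # per-neuron spike cutoff / reset
    b_u, tau_u, kappa, vr_u,     # per-pop (global u) or per-neuron arrays
    type_tau, type_g, type_E,    # (n_types,)
    edge_indptr, edge_indices, edge_data,   # (n_types, N+1), concat indices/data
    base_I,                      # (N,)
    seg_ton, seg_toff, seg_amp, seg_kind, seg_freq,  # (n_seg,)
    seg_mask,                    # (n_seg, N) bool
    dt, n_steps, t0,
    u_per_neuron,                # bool
    rec_every,
    rec_v, rec_u, rec_s,         # (n_rec, n_pop), (n_rec, n_u), (n_rec, n_types)
    rate_counts, rate_bin_steps, # (n_bins, n_pop) spike counts per bin
    spike_ids, spike_ts,         # preallocated outputs
):
    n = v.shape[0]
    n_pop = pop_count.shape[0]
    n_types = type_tau.shape[0]
    n_seg = seg_ton.shape[0]
    max_spikes = spike_ids.shape[0]
    n_spikes = 0

    drive = np.zeros(n)
    for step in range(n_steps):
        t = t0 + step * dt

        # record state before the update at sampling instants
        if rec_every > 0 and step % rec_every == 0:
            ri = step // rec_every
            if ri < rec_v.shape[0]:
                for p in range(n_pop):
                    rec_v[ri, p] = 0.0
                for i in range(n):
                    rec_v[ri, pop_of[i]] += v[i]
                for p in range(n_pop):
                    rec_v[ri, p] /= pop_count[p]
                for j in range(rec_u.shape[1]):
                    rec_u[ri, j] = u[j]
                for m in range(n_types):
                    acc = 0.0
                    for i in range(n):
                        acc += s[m, i]
                    rec_s[ri, m] = acc / n

        # instantaneous input current per neuron
        for i in range(n):
            drive[i] = base_I[i]
        for g_ in range(n_seg):
            if seg_ton[g_] <= t < seg_toff[g_]:
                if seg_kind[g_] == SEG_STEP:
                    amp = seg_amp[g_]
                elif seg_kind[g_] == SEG_RAMP:
                    amp = seg_amp[g_] * (t - seg_ton[g_]) / (seg_toff[g_] - seg_ton[g_])
                else:
                    amp = seg_amp[g_] * np.sin(
                        2.0 * np.pi * seg_freq[g_] * (t - seg_ton[g_]) * 1e-3)
                for i in range(n):
                    if seg_mask[g_, i]:
                        drive[i] += amp

        # membrane update
        if u_per_neuron:
            for i in range(n):
                syn = 0.0
                for m in range(n_types):
                    syn += type_g[m] * s[m, i] * (type_E[m] - v[i])
                dv = (k[i] * (v[i] - vr[i]) * (v[i] - vth[i]) - u[i]
                      + drive[i] + syn) / C[i]
                v[i] = v[i] + dt * dv
                u[i] = u[i] + dt * (-u[i] + b_u[i] * (v[i] - vr_u[i])) / tau_u[i]
        else:
            mean_v = np.zeros(n_pop)
            for i in range(n):
                mean_v[pop_of[i]] += v[i]
            for p in range(n_pop):
                mean_v[p] /= pop_count[p]
            for i in range(n):
                syn = 0.0
                for m in range(n_types):
                    syn += type_g[m] * s[m, i] * (type_E[m] - v[i])
                dv = (k[i] * (v[i] - vr[i]) * (v[i] - vth[i]) - u[pop_of[i]]
                      + drive[i] + syn) / C[i]
                v[i] = v[i] + dt * dv
            for p in range(n_pop):
                u[p] = u[p] + dt * (-u[p] + b_u[p] * (mean_v[p] - vr_u[p])) / tau_u[p]

        # synaptic decay
        for m in range(n_types):
            decay = dt / type_tau[m]
            for i in range(n):
                s[m, i] -= decay * s[m, i]

        # spikes: reset, record, propagate, recovery kick
        for i in range(n):
            if v[i] >= vp[i]:
                if n_spikes >= max_spikes:
                    return ERR_OVERFLOW, n_spikes, step
                spike_ids[n_spikes] = i
                spike_ts[n_spikes] = t + dt
                n_spikes += 1
                v[i] = v0[i]
                p = pop_of[i]
                if rate_bin_steps > 0:
                    bi = step // rate_bin_steps
                    if bi < rate_counts.shape[0]:
                        rate_counts[bi, p] += 1
                if u_per_neuron:
                    u[i] += kappa[i]
                else:
                    u[p] += kappa[p] / pop_count[p]
                for m in range(n_types):
                    lo = edge_indptr[m, i]
                    hi = edge_indptr[m, i + 1]
                    for e in range(lo, hi):
                        s[m, edge_indices[e]] += edge_data[e]
            elif not (-1e7 < v[i] < 1e7):
                return ERR_NONFINITE, n_spikes, step

    return OK, n_spikes, n_steps


@njit(cache=True)
def mf_euler(
    r, v, u,                     # (n_pop,) state, updated in place
    s,                           # (n_syn,) per-synapse activation
    C, k, vr, vth, tau_u, b, kappa, delta,   # (n_pop,)
    syn_pre, syn_post,           # (n_syn,) int32
    syn_J, syn_g, syn_E, syn_tau,  # (n_syn,)
    I_t,                         # (n_pop, n_steps)
    dt, n_steps,
    rec_every,
    rec,                         # (n_rec, n_pop, 3) -> r, v, u
    rec_s,                       # (n_rec, n_syn)
):
    n_pop = r.shape[0]
    n_syn = s.shape[0]
    gs = np.zeros(n_pop)
    gsE = np.zeros(n_pop)
    dr = np.zeros(n_pop)
    dv = np.zeros(n_pop)
    du = np.zeros(n_pop)
    ds = np.zeros(n_syn)
    pi = np.pi
    for step in range(n_steps):
        if rec_every > 0 and step % rec_every == 0:
            ri = step // rec_every
            if ri < rec.shape[0]:
                for p in range(n_pop):
                    rec[ri, p, 0] = r[p]
                    rec[ri, p, 1] = v[p]
                    rec[ri, p, 2] = u[p]
                for m in range(n_syn):
                    rec_s[ri, m] = s[m]

        for p in range(n_pop):
            gs[p] = 0.0
            gsE[p] = 0.0
        for m in range(n_syn):
            p = syn_post[m]
            gs[p] += syn_g[m] * s[m]
            gsE[p] += syn_g[m] * s[m] * (syn_E[m] - v[p])

        for p in range(n_pop):
            dvr = v[p] - vr[p]
            sigma = 1.0 if dvr > 0 else (-1.0 if dvr < 0 else 0.0)
            dr[p] = (delta[p] * k[p] * k[p] * sigma * dvr / (pi * C[p])
                     + r[p] * (k[p] * (2.0 * v[p] - vr[p] - vth[p]) - gs[p])) / C[p]
            dv[p] = (k[p] * v[p] * (v[p] - vr[p] - vth[p])
                     - pi * C[p] * r[p] * (delta[p] * sigma + pi * C[p] * r[p] / k[p])
                     + k[p] * vr[p] * vth[p] - u[p] + I_t[p, step] + gsE[p]) / C[p]
            du[p] = (b[p] * dvr - u[p]) / tau_u[p] + kappa[p] * r[p]
        for m in range(n_syn):
            ds[m] = (-s[m] + syn_tau[m] * syn_J[m] * r[syn_pre[m]]) / syn_tau[m]

        for p in range(n_pop):
            r[p] += dt * dr[p]
            v[p] += dt * dv[p]
            u[p] += dt * du[p]
            if not (-1e12 < v[p] < 1e12):
                return ERR_NONFINITE, step
        for m in range(n_syn):
            s[m] += dt * ds[m]
    return OK, n_steps
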