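"""Numba-compiled inner loop of the simulation.

All randomness (membrane-noise increments, L4 channel counts, baseline
counts) is pre-drawn with numpy generators outside the kernel, so the numba
and pure-numpy backends consume identical random streams and produce the
same trajectories (up to floating-point summation order).  The kernel
advances one block of steps and mutates state, weights and traces in place.

The weight-bound convention exploits that the two plastic pathways have
distinct postsynaptic classes: ``wmax_post[i]`` is the upper bound of any
plastic synapse onto neuron i (0.25 nS for PCs, 1 nS for PVs), and
``inc_pre[j]`` / ``inc_post[i]`` are the trace increments (A_plus / A_minus)
of the pathway neuron j (i) belongs to.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco


@njit(cache=True)
def run_block(
    # state (mutated in place)
    v, gE, gI, Isp, W, a_pre, a_post,
    # static per-neuron data
    is_exc, wmax_post, inc_pre, inc_post, M,
    # scalars
    plastic, eta,
    gl, Vl, VE, VI, vth, c_over, noise_amp,
    decay_E, decay_I, decay_spk, decay_trace,
    c_gap, w_gap,
    # gap-junction pools: (G, 2) start/stop index bounds
    pv_bounds,
    # inputs
    ch_counts, ch_pc_start, ch_pc_stop, ch_sst_start, ch_sst_stop,
    w_pc, w_sst_arr, ch_feeds_relay, reward_gate,
    relay_start, relay_stop, w_relay,
    base_idx, base_w, base_block,
    noise_block,
    # recording
    rec_cur, cur_idx, cE, cI,
    spk_steps, spk_ids, n_spk0,
    k0,
):
    n = v.shape[0]
    m = noise_block.shape[0]
    C = ch_counts.shape[0]
    cap = spk_steps.shape[0]
    n_spk = n_spk0
    spk_buf = np.empty(n, np.int64)
    gap_cur = np.zeros(n, np.float64)

    for k in range(m):
        kk = k0 + k
        if rec_cur:
            for q in range(cur_idx.shape[0]):
                i = cur_idx[q]
                cE[kk, q] = gE[i] * (VE - v[i])
                cI[kk, q] = gI[i] * (v[i] - VI)

        # ---- membrane integration (forward Euler, exact conductance decay)
        if w_gap > 0.0:
            # subthreshold coupling w_gap * sum_j (v_j - v_i), all-to-all
            # within each PV pool, evaluated on pre-update potentials
            for g in range(pv_bounds.shape[0]):
                lo, hi = pv_bounds[g, 0], pv_bounds[g, 1]
                s = 0.0
                for i in range(lo, hi):
                    s += v[i]
                n_pool = hi - lo
                for i in range(lo, hi):
                    gap_cur[i] = w_gap * (s - n_pool * v[i])
        for i in range(n):
            I = (-gl * (v[i] - Vl) - gE[i] * (v[i] - VE)
                 - gI[i] * (v[i] - VI) + Isp[i] + gap_cur[i])
            v[i] = v[i] + c_over * I + noise_amp * noise_block[k, i]
            gE[i] *= decay_E
            gI[i] *= decay_I
            Isp[i] *= decay_spk

        # ---- threshold and reset
        nspk = 0
        for i in range(n):
            if v[i] >= vth:
                v[i] = Vl
                spk_buf[nspk] = i
                nspk += 1
        if nspk:
            if n_spk + nspk > cap:
                return -1
            for s in range(nspk):
                spk_steps[n_spk + s] = kk
                spk_ids[n_spk + s] = spk_buf[s]
            n_spk += nspk

            # gap-junction spikelets: all-to-all within each PV pool
            for g in range(pv_bounds.shape[0]):
                lo, hi = pv_bounds[g, 0], pv_bounds[g, 1]
                npv_spk = 0
                for s in range(nspk):
                    j = spk_buf[s]
                    if lo <= j < hi:
                        npv_spk += 1
                if npv_spk:
                    for i in range(lo, hi):
                        Isp[i] += c_gap * npv_spk
                    for s in range(nspk):
                        j = spk_buf[s]
                        if lo <= j < hi:
                            Isp[j] -= c_gap

            # synaptic delivery through the dense matrix
            for s in range(nspk):
                j = spk_buf[s]
                if is_exc[j]:
                    for i in range(n):
                        gE[i] += W[i, j]
                else:
                    for i in range(n):
                        gI[i] += W[i, j]

        # ---- plasticity (online trace STDP with hard bounds)
        if plastic:
            for i in range(n):
                a_pre[i] *= decay_trace
                a_post[i] *= decay_trace
            if nspk:
                for s in range(nspk):  # presynaptic spikes: depression
                    j = spk_buf[s]
                    if inc_pre[j] > 0.0:
                        for i in range(n):
                            if M[i, j]:
                                w = W[i, j] - eta * a_post[i]
                                if w < 0.0:
                                    w = 0.0
                                elif w > wmax_post[i]:
                                    w = wmax_post[i]
                                W[i, j] = w
                for s in range(nspk):  # postsynaptic spikes: potentiation
                    i = spk_buf[s]
                    if inc_post[i] > 0.0:
                        wm = wmax_post[i]
                        for j in range(n):
                            if M[i, j]:
                                w = W[i, j] + eta * a_pre[j]
                                if w < 0.0:
                                    w = 0.0
                                elif w > wm:
                                    w = wm
                                W[i, j] = w
                # simultaneous pre+post pairs count as dt = 0: potentiation
                for s in range(nspk):
                    j = spk_buf[s]
                    if inc_pre[j] > 0.0:
                        for t in range(nspk):
                            i = spk_buf[t]
                            if inc_post[i] > 0.0 and M[i, j]:
                                w = W[i, j] + eta * inc_pre[j]
                                if w > wmax_post[i]:
                                    w = wmax_post[i]
                                W[i, j] = w
                for s in range(nspk):
                    j = spk_buf[s]
                    a_pre[j] += inc_pre[j]
                    a_post[j] += inc_post[j]

        # ---- external inputs (effective from the next step)
        ws = w_sst_arr[kk]
        for c in range(C):
            kc = ch_counts[c, kk]
            if kc:
                for i in range(ch_pc_start[c], ch_pc_stop[c]):
                    gE[i] += w_pc * kc
                for i in range(ch_sst_start[c], ch_sst_stop[c]):
                    gE[i] += ws * kc
                if ch_feeds_relay[c] and reward_gate[kk]:
                    for i in range(relay_start, relay_stop):
                        gE[i] += w_relay * kc
        for q in range(base_idx.shape[0]):
            cnt = base_block[k, q]
            if cnt:
                gE[base_idx[q]] += base_w[q] * cnt

    return n_spk
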