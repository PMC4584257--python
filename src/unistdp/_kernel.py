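"""Numba inner loop for the feedforward network simulation.

The kernel advances the whole network state in place so that
consecutive schedule blocks (receptive-field switches) chain exactly:
membrane dynamics by forward Euler at ``dt``; input Poisson spikes by
per-step Bernoulli draws; plasticity event-wise at spike times using
the exact exponential trace/STP updates, so the step size only affects
the membrane integration.

Scalar synapse-shared state (postsynaptic traces, membrane, adaptation,
synaptic current, last post-spike time) travels in a 7-slot ``misc``
array; per-synapse state in the P/q/r/p/x_plus/t_pre arrays.  Times are
milliseconds throughout; currents are nA at the synapse and pA inside
the membrane update.

Homeostasis is the scheduled subtractive normalization of q: every
``homeo_steps`` steps each synapse loses ``alpha`` times the mean
accumulated q drift ``mean(q) - q_target_mean``, softly conserving the
total postsynaptic weight on a timescale of (interval / alpha) while
leaving relative differences -- including hidden memory traces -- to
decay only slowly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# misc slot layout
Y_PLUS, Y_MINUS, T_POST, V_MEMB, W_ADAPT, I_SYN, T_NOW = range(7)

NEG_INF = -1.0e18


@njit(cache=False)
def run_block(
    seed,
    n_steps,
    dt,
    rates_hz,  # (n,) input rates
    P,
    q,
    r,
    p,
    x_plus,
    t_pre,
    q_target_mean,
    misc,
    # plasticity constants (already lr-scaled); no_block kills y_plus readout
    d_minus,
    d_plus,
    c_plus,
    tau_ym,
    tau_yp,
    tau_xp,
    no_block,
    freeze_P,
    # STP
    D,
    F,
    # bounds / homeostasis
    q_lo,
    q_hi,
    alpha,
    homeo_steps,
    # AdEx (pF, nS, mV, ms, pA)
    C_m,
    g_L,
    E_L,
    V_T,
    Delta_T,
    a_w,
    b_w,
    tau_w,
    V_reset,
    V_cut,
    tau_syn,
    record_steps,
):
    n = rates_hz.size
    np.random.seed(seed)
    p_step = rates_hz * dt * 1e-3  # spike probability per step

    n_rec = n_steps // record_steps
    rec_t = np.empty(n_rec)
    rec_P = np.empty((n_rec, n))
    rec_q = np.empty((n_rec, n))
    max_spikes = int(600 * n_steps * dt * 1e-3) + 64
    post_spikes = np.empty(max_spikes)
    n_post = 0
    status = 0  # 1 = runaway firing, 2 = non-finite state

    syn_decay = np.exp(-dt / tau_syn)
    sec_count = 0
    sec_edge = misc[T_NOW] + 1000.0
    rec_i = 0

    for s in range(n_steps):
        t = misc[T_NOW] + dt
        misc[T_NOW] = t
        misc[I_SYN] *= syn_decay

        # --- input spikes: plasticity + STP + release ---
        for j in range(n):
            if np.random.random() < p_step[j]:
                y_m = misc[Y_MINUS] * np.exp(-(t - misc[T_POST]) / tau_ym)
                if no_block:
                    y_p = 0.0
                else:
                    y_p = misc[Y_PLUS] * np.exp(-(t - misc[T_POST]) / tau_yp)
                x_val = x_plus[j] * np.exp(-(t - t_pre[j]) / tau_xp)
                Pj = P[j]
                if not freeze_P:
                    Pj = Pj - d_minus * y_m * y_p + d_plus * y_p * x_val
                    if Pj < 0.0:
                        Pj = 0.0
                    elif Pj > 1.0:
                        Pj = 1.0
                    P[j] = Pj
                if t_pre[j] > NEG_INF * 0.5:
                    dtp = t - t_pre[j]
                    r[j] = 1.0 - (1.0 - r[j] * (1.0 - p[j])) * np.exp(-dtp / D)
                    p[j] = Pj + p[j] * (1.0 - Pj) * np.exp(-dtp / F)
                else:
                    r[j] = 1.0
                    p[j] = Pj
                x_plus[j] = x_val + 1.0
                t_pre[j] = t
                misc[I_SYN] += q[j] * r[j] * p[j]  # nA

        # --- membrane (forward Euler) ---
        V = misc[V_MEMB]
        w = misc[W_ADAPT]  # pA
        ex = (V - V_T) / Delta_T
        if ex > 30.0:
            ex = 30.0
        I_pA = misc[I_SYN] * 1000.0
        dV = dt * (-g_L * (V - E_L) + g_L * Delta_T * np.exp(ex) - w + I_pA) / C_m
        dw = dt * (a_w * (V - E_L) - w) / tau_w
        V += dV
        w += dw
        if not (np.isfinite(V) and np.isfinite(w)):
            status = 2
            break

        if V >= V_cut:
            V = V_reset
            w += b_w * 1000.0  # b in nA -> pA
            if n_post < max_spikes:
                post_spikes[n_post] = t
            n_post += 1
            sec_count += 1
            # --- postsynaptic plasticity on all synapses ---
            y_m = misc[Y_MINUS] * np.exp(-(t - misc[T_POST]) / tau_ym)
            y_p = misc[Y_PLUS] * np.exp(-(t - misc[T_POST]) / tau_yp)
            for j in range(n):
                x_val = x_plus[j] * np.exp(-(t - t_pre[j]) / tau_xp)
                dq = c_plus * x_val * y_m
                qn = q[j] + dq
                if qn < q_lo:
                    qn = q_lo
                elif qn > q_hi:
                    qn = q_hi
                q[j] = qn
            misc[Y_MINUS] = y_m + 1.0
            misc[Y_PLUS] = y_p + 1.0
            misc[T_POST] = t
        misc[V_MEMB] = V
        misc[W_ADAPT] = w

        # --- runaway guard: > 500 spikes within any simulated second ---
        if t >= sec_edge:
            sec_edge += 1000.0
            sec_count = 0
        if sec_count > 500:
            status = 1
            break

        # --- homeostasis: subtract alpha * (mean accumulated q drift) ---
        if alpha > 0.0 and (s + 1) % homeo_steps == 0:
            m = 0.0
            for j in range(n):
                m += q[j]
            m = alpha * (m / n - q_target_mean)
            for j in range(n):
                qn = q[j] - m
                if qn < q_lo:
                    qn = q_lo
                elif qn > q_hi:
                    qn = q_hi
                q[j] = qn

        # --- recording ---
        if (s + 1) % record_steps == 0 and rec_i < n_rec:
            rec_t[rec_i] = t
            for j in range(n):
                rec_P[rec_i, j] = P[j]
                rec_q[rec_i, j] = q[j]
            rec_i += 1

    n_saved = n_post if n_post < max_spikes else max_spikes
    return rec_t[:rec_i], rec_P[:rec_i], rec_q[:rec_i], post_spikes[:n_saved], n_post, status
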