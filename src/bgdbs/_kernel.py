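"""Compiled inner loop of the trial simulation.

The rate network is tiny (25 integrated units, ~70 fixed synapse groups), so
the simulation cost is dominated by per-step dispatch overhead rather than
arithmetic.  This module runs the full trial state machine — integration,
dopamine dynamics, plasticity, decision thresholding, reward delivery,
trial-start logging and snapshots — inside one compiled loop over global
1 ms steps, with each simulation of the batch advancing its own phase
machine.  Execution returns to Python only to refill per-seed noise blocks
(counter-based draws are generated in blocks of 1024 steps) and at
completion, so results are bit-reproducible for a given seed regardless of
batch composition.

Phase codes and semantics match :mod:`bgdbs.task`; the Python implementation
of a single step (``Simulator.step``) is the readable reference used for
open-ended probes (e.g., extended no-decision trials).
"""
from __future__ import annotations

import numpy as np
from numba import njit

# return codes
RC_DONE = 0
RC_NEED_NOISE = 1
RC_BUDGET = 2

PH_PRE, PH_DECIDE, PH_REWARD, PH_DONE = 0, 1, 2, 3

NOISE_BLOCK = 1024


@njit(cache=True, fastmath=False)
def run_steps(
    # mutable state ------------------------------------------------------
    mp, rr,                    # (S, Nf) membrane potentials / rates
    mp_snc, r_snc, delta, alpha_gate,   # (S,)
    t, trial, phase, phase_step,        # (S,) int64
    wbuf,                      # (S, Wtot) packed plastic weights
    # fixed network ------------------------------------------------------
    wf_i, wf_j, wf_v,          # sparse fixed weights (signed)
    axon_bias,                 # (Nf,) constant axonal drive
    kvec, Bvec,                # (Nf,)
    noise_lo, lam,             # first noise column; (Nn,) amplitudes
    # plastic projections (packed metadata) ------------------------------
    p_off, p_pre0, p_pren, p_post0, p_postn,    # (P,) int64
    p_sign,                    # (P,) float
    p_axon,                    # (P,) float axonal stimulation rate
    p_kind,                    # (P,) 0 frozen, 1 shortcut, 2 dopamine, 3 prediction
    p_tau, p_tau_dip, p_pol, p_dev, p_wmax,     # (P,) rule parameters
    p_thal_exc,                # (P,) 1 if the projection excites the thalamus
    sc_tau_w, sc_theta_reg, sc_theta_post, sc_beta_reg,
    snc_B, snc_tau, rpe_neg, da_base, tau_pred,
    # thalamic input split (fixed part) ----------------------------------
    te_i, te_j, te_v, te_bias,  # fixed excitatory inputs to the 2 thalamic units
    ti_i, ti_j, ti_v, ti_bias,  # fixed inhibitory inputs
    # column layout ------------------------------------------------------
    corin0, n_corin, ppn0, strd10, n_strd1, thal0, n_thal,
    cordec0, n_cordec, gpi0, n_gpi,
    ppn_w, alpha_suppress,
    pop_off,                   # (n_pops+1,) population column offsets
    # task ----------------------------------------------------------------
    n_trials, pre_ms, thr, max_ms, reward_ms, reset_flag,
    schedule,                  # (S, T, 2) uint8
    # noise ---------------------------------------------------------------
    noise_buf, noise_block,    # (S, NOISE_BLOCK, Nn), (S,) int64
    noise_need,                # (S,) uint8 out-flag
    # outputs -------------------------------------------------------------
    choices, rewarded, latency,          # (S, T)
    psp_short_out, psp_gpi_out,          # (S, T, 2)
    acc_exc, acc_inh, acc_steps,         # (S,2),(S,2),(S,)
    rate_out, acc_rate,                  # (S, T, n_pops), (S, n_pops)
    wlog,                                # (S, T, Wtot) trial-start weights
    snap_index,                # (T,) -> snapshot row or -1
    snap_mp, snap_rr, snap_w,  # (K,S,Nf),(K,S,Nf),(K,S,Wtot)
    snap_mp_snc, snap_t,       # (K,S),(K,S)
    # control -------------------------------------------------------------
    until_trial, max_steps, steps_out,
):
    S, Nf = mp.shape
    n_pops = pop_off.shape[0] - 1
    psp = np.empty(Nf)
    for _ in range(max_steps):
        # termination / noise availability pre-pass (no mutation yet)
        alldone = True
        need = False
        for s in range(S):
            if phase[s] != PH_DONE and trial[s] < until_trial:
                alldone = False
                if (t[s] >> 10) != noise_block[s]:
                    noise_need[s] = 1
                    need = True
        if alldone:
            return RC_DONE
        if need:
            return RC_NEED_NOISE
        steps_out[0] += 1

        for s in range(S):
            if phase[s] == PH_DONE or trial[s] >= until_trial:
                continue
            ph = phase[s]
            tr = trial[s]
            if tr >= n_trials:
                tr = n_trials - 1
            stim = ph == PH_DECIDE or ph == PH_REWARD
            rew_now = ph == PH_REWARD and rewarded[s, tr]
            alpha = 1.0 if ph == PH_REWARD else 0.0
            alpha_gate[s] = alpha
            b_cor = 1.0 if stim else 0.0
            b_ppn = 1.0 if rew_now else 0.0
            for j in range(n_corin):
                rr[s, corin0 + j] = b_cor
                mp[s, corin0 + j] = b_cor
            rr[s, ppn0] = b_ppn
            mp[s, ppn0] = b_ppn

            # --- summed signed psp ---
            for j in range(Nf):
                psp[j] = axon_bias[j]
            for k in range(wf_v.shape[0]):
                psp[wf_j[k]] += wf_v[k] * rr[s, wf_i[k]]
            for p in range(p_off.shape[0]):
                if p_kind[p] == 3:  # prediction weights target the dopamine unit
                    continue
                off = p_off[p]
                npre = p_pren[p]
                npost = p_postn[p]
                pre0 = p_pre0[p]
                post0 = p_post0[p]
                sg = p_sign[p]
                ax = p_axon[p]
                for i in range(npre):
                    ri = rr[s, pre0 + i] + ax
                    base = off + i * npost
                    for j in range(npost):
                        psp[post0 + j] += sg * wbuf[s, base + j] * ri

            # --- integrate ---
            nidx = t[s] & (NOISE_BLOCK - 1)
            for j in range(Nf):
                if kvec[j] == 0.0:
                    continue
                d = psp[j] - mp[s, j] + Bvec[j]
                if j >= noise_lo:
                    d += lam[j - noise_lo] * noise_buf[s, nidx, j - noise_lo]
                if alpha_suppress > 0.0 and j >= gpi0 and j < gpi0 + n_gpi:
                    x = -1.0 - mp[s, j]
                    if x < 0.0:
                        d += alpha_suppress * x
                mp[s, j] += kvec[j] * d
                rr[s, j] = mp[s, j] if mp[s, j] > 0.0 else 0.0

            # --- dopamine unit ---
            psp_ppn = ppn_w * rr[s, ppn0]
            psp_pred = 0.0
            for p in range(p_off.shape[0]):
                if p_kind[p] == 3:
                    off = p_off[p]
                    for i in range(p_pren[p]):
                        psp_pred += wbuf[s, off + i] * rr[s, p_pre0[p] + i]
            if psp_ppn > 0.0:
                dlt = 1.0 - snc_B - psp_pred
                if dlt < 0.0:
                    dlt = 0.0
            else:
                dlt = -rpe_neg * psp_pred
            mp_snc[s] += (1.0 / snc_tau) * (-mp_snc[s] + alpha * dlt + snc_B)
            r_snc[s] = mp_snc[s] if mp_snc[s] > 0.0 else 0.0
            delta[s] = dlt

            # --- plasticity ---
            if stim:
                # thalamic mean for the shortcut rule
                tmean = 0.0
                for j in range(n_thal):
                    tmean += rr[s, thal0 + j]
                tmean /= n_thal
                for p in range(p_off.shape[0]):
                    if p_kind[p] != 1:
                        continue
                    off = p_off[p]
                    npost = p_postn[p]
                    for j in range(npost):
                        rpost = rr[s, p_post0[p] + j]
                        v = rpost - tmean - sc_theta_post
                        if v < 0.0:
                            v = 0.0
                        areg = rpost - sc_theta_reg
                        areg = sc_beta_reg * areg if areg > 0.0 else 0.0
                        for i in range(p_pren[p]):
                            idx = off + i * npost + j
                            wv = wbuf[s, idx] + (
                                rr[s, p_pre0[p] + i] * v - areg * v * v * wbuf[s, idx]
                            ) / sc_tau_w
                            wbuf[s, idx] = wv if wv > 0.0 else 0.0
            dadev = r_snc[s] - da_base
            if dadev > 1e-4 or dadev < -1e-4:
                for p in range(p_off.shape[0]):
                    kind = p_kind[p]
                    if kind == 2:
                        tau = p_tau[p] if r_snc[s] >= da_base else p_tau_dip[p]
                        kap = p_pol[p] * dadev / tau
                        npost = p_postn[p]
                        pmean = 0.0
                        for j in range(npost):
                            pmean += rr[s, p_post0[p] + j]
                        pmean /= npost
                        off = p_off[p]
                        for j in range(npost):
                            dev = rr[s, p_post0[p] + j] - pmean
                            if p_dev[p] == 1:
                                dev = -dev
                            if dev <= 0.0:
                                continue
                            for i in range(p_pren[p]):
                                idx = off + i * npost + j
                                wv = wbuf[s, idx] + kap * rr[s, p_pre0[p] + i] * dev
                                if wv < 0.0:
                                    wv = 0.0
                                elif wv > p_wmax[p]:
                                    wv = p_wmax[p]
                                wbuf[s, idx] = wv
                    elif kind == 3 and alpha > 0.0:
                        off = p_off[p]
                        g = alpha * dlt / tau_pred
                        for i in range(p_pren[p]):
                            idx = off + i
                            wv = wbuf[s, idx] + g * rr[s, p_pre0[p] + i]
                            wbuf[s, idx] = wv if wv > 0.0 else 0.0

            # --- decision-epoch traces ---
            if ph == PH_DECIDE:
                for j in range(n_thal):
                    e = te_bias[j]
                    inh = ti_bias[j]
                    acc_exc[s, j] += e
                    acc_inh[s, j] += inh
                for k in range(te_v.shape[0]):
                    acc_exc[s, te_j[k]] += te_v[k] * rr[s, te_i[k]]
                for k in range(ti_v.shape[0]):
                    acc_inh[s, ti_j[k]] += ti_v[k] * rr[s, ti_i[k]]
                for p in range(p_off.shape[0]):
                    if p_thal_exc[p] == 1:
                        off = p_off[p]
                        npost = p_postn[p]
                        ax = p_axon[p]
                        for i in range(p_pren[p]):
                            ri = rr[s, p_pre0[p] + i] + ax
                            for j in range(npost):
                                acc_exc[s, j] += wbuf[s, off + i * npost + j] * ri
                acc_steps[s] += 1
                for g in range(n_pops):
                    m = 0.0
                    for j in range(pop_off[g], pop_off[g + 1]):
                        m += rr[s, j]
                    acc_rate[s, g] += m / (pop_off[g + 1] - pop_off[g])

            # --- phase transitions ---
            phase_step[s] += 1
            if ph == PH_PRE:
                if phase_step[s] >= pre_ms:
                    phase[s] = PH_DECIDE
                    phase_step[s] = 0
            elif ph == PH_DECIDE:
                best = 0
                bestr = rr[s, cordec0]
                for j in range(1, n_cordec):
                    if rr[s, cordec0 + j] > bestr:
                        bestr = rr[s, cordec0 + j]
                        best = j
                if bestr > thr or phase_step[s] >= max_ms:
                    choices[s, tr] = best
                    latency[s, tr] = phase_step[s]
                    rewarded[s, tr] = schedule[s, tr, best] != 0
                    ns = acc_steps[s] if acc_steps[s] > 0 else 1
                    for j in range(n_thal):
                        psp_short_out[s, tr, j] = acc_exc[s, j] / ns
                        psp_gpi_out[s, tr, j] = acc_inh[s, j] / ns
                        acc_exc[s, j] = 0.0
                        acc_inh[s, j] = 0.0
                    for g in range(n_pops):
                        rate_out[s, tr, g] = acc_rate[s, g] / ns
                        acc_rate[s, g] = 0.0
                    acc_steps[s] = 0
                    phase[s] = PH_REWARD
                    phase_step[s] = 0
            elif ph == PH_REWARD:
                if phase_step[s] >= reward_ms:
                    if reset_flag:
                        for j in range(Nf):
                            mp[s, j] = 0.0
                            rr[s, j] = 0.0
                        mp_snc[s] = snc_B
                        r_snc[s] = snc_B
                        delta[s] = 0.0
                    trial[s] += 1
                    phase_step[s] = 0
                    if trial[s] >= n_trials:
                        phase[s] = PH_DONE
                    else:
                        phase[s] = PH_PRE
                        ntr = trial[s]
                        for k in range(wbuf.shape[1]):
                            wlog[s, ntr, k] = wbuf[s, k]
                        sk = snap_index[ntr]
                        if sk >= 0:
                            for j in range(Nf):
                                snap_mp[sk, s, j] = mp[s, j]
                                snap_rr[sk, s, j] = rr[s, j]
                            for k in range(wbuf.shape[1]):
                                snap_w[sk, s, k] = wbuf[s, k]
                            snap_mp_snc[sk, s] = mp_snc[s]
                            snap_t[sk, s] = t[s] + 1
            t[s] += 1
    return RC_BUDGET
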