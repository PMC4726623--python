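"""Fused numba kernel for one 1000-ms trial of network + plasticity.

This is a performance path only: it implements, step for step, the same
per-ms update order as the pure-numpy reference implementations in
:mod:`babblesim.network` and :mod:`babblesim.plasticity` (an equivalence
test pins the two against each other).  Per millisecond:

* neurons at/above 30 mV emit a spike and are reset; their synaptic
  weights are delivered as input current during this step,
* plasticity bookkeeping runs in its fixed statement order (dopamine
  decay; eligibility growth on motor spikes; 10-ms potentiation with
  cap; presynaptic trace set-then-decay; 10-ms normalization and
  eligibility decay),
* membrane variables are integrated (two 0.5-ms sub-steps for v).

A pending reward bumps dopamine by +1 at the trial's first millisecond,
after that ms's plasticity statements (the distal-reward delay).

Invariant diagnostics (minimum weight, maximum weight right after the
cap, worst deviation of the weight mean from 1 after normalization) are
accumulated inside the loop and returned, so long runs can assert the
plasticity invariants at every 10-ms boundary without re-simulating.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_trial_kernel(v_res, u_res, v_mot, u_mot,
                     fan_targets, fan_weights,   # (n_res, fanout) adjacency
                     a_res, b_res, c_res, dr_res,
                     a_mot, b_mot, c_mot, dr_mot,
                     out_map,              # (n_res,) int64: output index or -1
                     output_ids,           # (n_out,) int64
                     s, e, ctr, d,
                     noise_res, noise_mot,  # (trial_ms, n_res/n_mot)
                     t_global_start,        # 1-based global ms of the first step
                     reward_pending,
                     da_decay, trace_bump, trace_decay, elig_decay,
                     weight_cap, da_bump, update_interval, normalize_by_sum):
    n_res = v_res.shape[0]
    n_mot = v_mot.shape[0]
    n_out = s.shape[0]
    trial_ms = noise_res.shape[0]
    half = n_mot // 2

    agonist_counts = np.zeros(trial_ms)
    antagonist_counts = np.zeros(trial_ms)
    res_spike_total = 0

    min_s = np.inf
    max_s_postcap = -np.inf
    max_mean_dev = 0.0

    i_res = np.empty(n_res)
    i_mot = np.empty(n_mot)
    fired_res = np.empty(n_res, np.bool_)
    fired_mot = np.empty(n_mot, np.bool_)

    for t_local in range(trial_ms):
        t = t_global_start + t_local
        boundary = t % update_interval == 0

        # -- spike detection and reset ---------------------------------
        for i in range(n_res):
            if v_res[i] >= 30.0:
                fired_res[i] = True
                v_res[i] = c_res[i]
                u_res[i] += dr_res[i]
                res_spike_total += 1
            else:
                fired_res[i] = False
        for i in range(n_mot):
            if v_mot[i] >= 30.0:
                fired_mot[i] = True
                v_mot[i] = c_mot[i]
                u_mot[i] += dr_mot[i]
                if i < half:
                    agonist_counts[t_local] += 1.0
                else:
                    antagonist_counts[t_local] += 1.0
            else:
                fired_mot[i] = False

        # -- synaptic currents from the spikes just registered ---------
        for j in range(n_res):
            i_res[j] = noise_res[t_local, j]
        for j in range(n_mot):
            i_mot[j] = noise_mot[t_local, j]
        fanout = fan_targets.shape[1]
        for pre in range(n_res):
            if fired_res[pre]:
                for q in range(fanout):
                    i_res[fan_targets[pre, q]] += fan_weights[pre, q]
                k = out_map[pre]
                if k >= 0:
                    for j in range(n_mot):
                        i_mot[j] += s[k, j]

        # -- plasticity (fixed statement order) ------------------------
        d = da_decay * d
        for j in range(n_mot):
            if fired_mot[j]:
                for k in range(n_out):
                    e[k, j] += ctr[k]
        if boundary:
            for k in range(n_out):
                for j in range(n_mot):
                    val = s[k, j] + e[k, j] * d
                    if val > weight_cap:
                        val = weight_cap
                    s[k, j] = val
                    if val > max_s_postcap:
                        max_s_postcap = val
        for k in range(n_out):
            if fired_res[output_ids[k]]:
                ctr[k] = trace_bump
            ctr[k] = trace_decay * ctr[k]
        if boundary:
            total = 0.0
            for k in range(n_out):
                for j in range(n_mot):
                    total += s[k, j]
            divisor = total if normalize_by_sum else total / (n_out * n_mot)
            check = 0.0
            for k in range(n_out):
                for j in range(n_mot):
                    s[k, j] /= divisor
                    check += s[k, j]
                    if s[k, j] < min_s:
                        min_s = s[k, j]
                    e[k, j] *= elig_decay
            dev = abs(check / (n_out * n_mot) - 1.0)
            if not normalize_by_sum and dev > max_mean_dev:
                max_mean_dev = dev

        if reward_pending and t_local == 0:
            d = d + da_bump

        # -- membrane integration --------------------------------------
        for i in range(n_res):
            v = v_res[i]
            u = u_res[i]
            cur = i_res[i]
            v += 0.5 * (0.04 * v * v + 5.0 * v + 140.0 - u + cur)
            v += 0.5 * (0.04 * v * v + 5.0 * v + 140.0 - u + cur)
            u += a_res[i] * (b_res[i] * v - u)
            v_res[i] = v
            u_res[i] = u
        for i in range(n_mot):
            v = v_mot[i]
            u = u_mot[i]
            cur = i_mot[i]
            v += 0.5 * (0.04 * v * v + 5.0 * v + 140.0 - u + cur)
            v += 0.5 * (0.04 * v * v + 5.0 * v + 140.0 - u + cur)
            u += a_mot[i] * (b_mot[i] * v - u)
            v_mot[i] = v
            u_mot[i] = u

    return (agonist_counts, antagonist_counts, d, res_spike_total,
            min_s, max_s_postcap, max_mean_dev)
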