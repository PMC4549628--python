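"""Compiled teacher-forced replay kernels.

Model fitting evaluates thousands of candidate parameterizations, each of
which replays a full session under teacher forcing (policy evaluated at every
trial, model then updated with the recorded choice and outcome).  These
numba kernels mirror the reference agents in :mod:`dualsys.agents` trial for
trial -- the equivalence is asserted in the test suite -- and return, per
trial, the probability assigned to the recorded action, the number of memory
items processed, and the entropy of the final policy (the inputs of the
simulated-RT model).

Working-memory decay is applied in closed form: an item decayed k times is
the mixture (1-eps)^k * fresh + (1 - (1-eps)^k) * uniform, which is exactly
what k successive uniform blends produce.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "replay_qlearning",
    "replay_bwm",
    "replay_entropy_coordination",
    "replay_weight_mixture",
    "replay_vpi_selection",
]

_LN2 = math.log(2.0)
_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)
_EPS_DIV = 1e-8  # must match working_memory._EPS_DIV


@njit(cache=True)
def _softmax(values, beta, out):
    m = values[0]
    for k in range(1, values.size):
        if values[k] > m:
            m = values[k]
    z = 0.0
    for k in range(values.size):
        out[k] = math.exp(beta * (values[k] - m))
        z += out[k]
    for k in range(values.size):
        out[k] /= z


@njit(cache=True)
def _entropy_bits(p):
    h = 0.0
    for k in range(p.size):
        if p[k] > 0.0:
            h -= p[k] * math.log(p[k]) / _LN2
    return h


@njit(cache=True)
def _bwm_reset(joint, p_out, n_s, n_a):
    u = 1.0 / (n_s * n_a * 2.0)
    for a in range(n_a):
        joint[a, 0] = u
        joint[a, 1] = u
        p_out[a] = 1.0 / n_a


@njit(cache=True)
def _bwm_add_item(joint, mem_s, mem_a, mem_r, mem_k, j, s_t, eps, n_s, n_a):
    d = (1.0 - eps) ** mem_k[j]
    same = mem_s[j] == s_t
    w_s = (1.0 - d) / n_s
    if same:
        w_s += d
    for a in range(n_a):
        if same:
            p_a = (1.0 - d) / n_a
            if a == mem_a[j]:
                p_a += d
            if a == mem_a[j]:
                p_r1 = d * mem_r[j] + (1.0 - d) * 0.5
            else:
                p_r1 = 0.5
        else:
            p_a = 1.0 / n_a
            p_r1 = 0.5
        joint[a, 1] += w_s * p_a * p_r1
        joint[a, 0] += w_s * p_a * (1.0 - p_r1)


@njit(cache=True)
def _bwm_policy(joint, p_out, n_a):
    s0 = 0.0
    s1 = 0.0
    for a in range(n_a):
        s0 += joint[a, 0]
        s1 += joint[a, 1]
    z = 0.0
    for a in range(n_a):
        denom = joint[a, 0] / s0
        if denom < _EPS_DIV:
            denom = _EPS_DIV
        q = (joint[a, 1] / s1) / denom
        p_out[a] = q
        z += q
    for a in range(n_a):
        p_out[a] /= z
    return _entropy_bits(p_out)


@njit(cache=True)
def _bwm_decide(joint, p_out, mem_s, mem_a, mem_r, mem_k, n, s_t, eps, theta,
                n_s, n_a):
    _bwm_reset(joint, p_out, n_s, n_a)
    h = math.log(n_a) / _LN2
    i = 0
    while h > theta and i < n:
        _bwm_add_item(joint, mem_s, mem_a, mem_r, mem_k, i, s_t, eps, n_s, n_a)
        i += 1
        h = _bwm_policy(joint, p_out, n_a)
    return i, h


@njit(cache=True)
def _mem_push(mem_s, mem_a, mem_r, mem_k, n, cap, s, a, r):
    keep = n if n < cap else cap - 1
    for j in range(keep - 1, -1, -1):
        mem_s[j + 1] = mem_s[j]
        mem_a[j + 1] = mem_a[j]
        mem_r[j + 1] = mem_r[j]
        mem_k[j + 1] = mem_k[j] + 1
    mem_s[0] = s
    mem_a[0] = a
    mem_r[0] = r
    mem_k[0] = 0
    return keep + 1


@njit(cache=True)
def replay_qlearning(alpha, beta, s_arr, a_arr, r_arr, b_arr, n_s, n_a):
    T = s_arr.size
    out_p = np.empty(T)
    out_i = np.zeros(T, dtype=np.int64)
    out_h = np.empty(T)
    Q = np.zeros((n_s, n_a))
    p = np.empty(n_a)
    cur_block = -1
    for t in range(T):
        if b_arr[t] != cur_block:
            Q[:, :] = 0.0
            cur_block = b_arr[t]
        s = s_arr[t]
        _softmax(Q[s], beta, p)
        out_p[t] = p[a_arr[t]]
        out_h[t] = _entropy_bits(p)
        Q[s, a_arr[t]] += alpha * (r_arr[t] - Q[s, a_arr[t]])
    return out_p, out_i, out_h


@njit(cache=True)
def replay_bwm(cap, theta, eps, s_arr, a_arr, r_arr, b_arr, n_s, n_a):
    T = s_arr.size
    out_p = np.empty(T)
    out_i = np.zeros(T, dtype=np.int64)
    out_h = np.empty(T)
    mem_s = np.zeros(cap, dtype=np.int64)
    mem_a = np.zeros(cap, dtype=np.int64)
    mem_r = np.zeros(cap, dtype=np.int64)
    mem_k = np.zeros(cap, dtype=np.int64)
    joint = np.empty((n_a, 2))
    p = np.empty(n_a)
    n = 0
    cur_block = -1
    for t in range(T):
        if b_arr[t] != cur_block:
            n = 0
            cur_block = b_arr[t]
        i, h = _bwm_decide(joint, p, mem_s, mem_a, mem_r, mem_k, n,
                           s_arr[t], eps, theta, n_s, n_a)
        out_p[t] = p[a_arr[t]]
        out_i[t] = i
        out_h[t] = h
        n = _mem_push(mem_s, mem_a, mem_r, mem_k, n, cap,
                      s_arr[t], a_arr[t], r_arr[t])
    return out_p, out_i, out_h


@njit(cache=True)
def replay_entropy_coordination(alpha, beta, beta_final, cap, eps, lam1, lam2,
                                s_arr, a_arr, r_arr, b_arr, n_s, n_a, seed):
    np.random.seed(seed)
    T = s_arr.size
    h_max = math.log(n_a) / _LN2
    out_p = np.empty(T)
    out_i = np.zeros(T, dtype=np.int64)
    out_h = np.empty(T)
    Q = np.zeros((n_s, n_a))
    mem_s = np.zeros(cap, dtype=np.int64)
    mem_a = np.zeros(cap, dtype=np.int64)
    mem_r = np.zeros(cap, dtype=np.int64)
    mem_k = np.zeros(cap, dtype=np.int64)
    joint = np.empty((n_a, 2))
    p_bwm = np.empty(n_a)
    p_ql = np.empty(n_a)
    q_final = np.empty(n_a)
    p = np.empty(n_a)
    n = 0
    cur_block = -1
    for t in range(T):
        if b_arr[t] != cur_block:
            Q[:, :] = 0.0
            n = 0
            cur_block = b_arr[t]
        s = s_arr[t]
        _softmax(Q[s], beta, p_ql)
        h_ql = _entropy_bits(p_ql)
        _bwm_reset(joint, p_bwm, n_s, n_a)
        h_bwm = h_max
        i = 0
        while True:
            p_dec = 1.0 / (1.0 + lam1 * (n - i)
                           * math.exp(-lam2 * (2.0 * h_max - h_bwm - h_ql)))
            if i >= n or np.random.random() < p_dec:
                break
            _bwm_add_item(joint, mem_s, mem_a, mem_r, mem_k, i, s, eps, n_s, n_a)
            i += 1
            h_bwm = _bwm_policy(joint, p_bwm, n_a)
        for a in range(n_a):
            q_final[a] = p_bwm[a] + Q[s, a]
        _softmax(q_final, beta_final, p)
        out_p[t] = p[a_arr[t]]
        out_i[t] = i
        out_h[t] = _entropy_bits(p)
        Q[s, a_arr[t]] += alpha * (r_arr[t] - Q[s, a_arr[t]])
        n = _mem_push(mem_s, mem_a, mem_r, mem_k, n, cap, s, a_arr[t], r_arr[t])
    return out_p, out_i, out_h


@njit(cache=True)
def replay_weight_mixture(alpha, beta, cap, theta, eps, w0,
                          s_arr, a_arr, r_arr, b_arr, n_s, n_a):
    T = s_arr.size
    out_p = np.empty(T)
    out_i = np.zeros(T, dtype=np.int64)
    out_h = np.empty(T)
    Q = np.zeros((n_s, n_a))
    w = np.full(n_s, w0)
    mem_s = np.zeros(cap, dtype=np.int64)
    mem_a = np.zeros(cap, dtype=np.int64)
    mem_r = np.zeros(cap, dtype=np.int64)
    mem_k = np.zeros(cap, dtype=np.int64)
    joint = np.empty((n_a, 2))
    p_bwm = np.empty(n_a)
    p_ql = np.empty(n_a)
    p = np.empty(n_a)
    n = 0
    cur_block = -1
    for t in range(T):
        if b_arr[t] != cur_block:
            Q[:, :] = 0.0
            w[:] = w0
            n = 0
            cur_block = b_arr[t]
        s = s_arr[t]
        _softmax(Q[s], beta, p_ql)
        i, _ = _bwm_decide(joint, p_bwm, mem_s, mem_a, mem_r, mem_k, n,
                           s, eps, theta, n_s, n_a)
        for a in range(n_a):
            p[a] = (1.0 - w[s]) * p_ql[a] + w[s] * p_bwm[a]
        a_t = a_arr[t]
        r_t = r_arr[t]
        out_p[t] = p[a_t]
        out_i[t] = i
        out_h[t] = _entropy_bits(p)
        lik_bwm = p_bwm[a_t] if r_t == 1 else 1.0 - p_bwm[a_t]
        lik_ql = p_ql[a_t] if r_t == 1 else 1.0 - p_ql[a_t]
        denom = lik_bwm * w[s] + lik_ql * (1.0 - w[s])
        if denom > 0.0:
            w[s] = lik_bwm * w[s] / denom
        Q[s, a_t] += alpha * (r_t - Q[s, a_t])
        n = _mem_push(mem_s, mem_a, mem_r, mem_k, n, cap, s, a_t, r_t)
    return out_p, out_i, out_h


@njit(cache=True)
def replay_vpi_selection(beta, cap, theta, eps, eta, sigma_r,
                         s_arr, a_arr, r_arr, b_arr, n_s, n_a):
    T = s_arr.size
    out_p = np.empty(T)
    out_i = np.zeros(T, dtype=np.int64)
    out_h = np.empty(T)
    mean = np.zeros((n_s, n_a))
    var = np.full((n_s, n_a), eta)
    rate = np.zeros(n_s)
    mem_s = np.zeros(cap, dtype=np.int64)
    mem_a = np.zeros(cap, dtype=np.int64)
    mem_r = np.zeros(cap, dtype=np.int64)
    mem_k = np.zeros(cap, dtype=np.int64)
    joint = np.empty((n_a, 2))
    p_bwm = np.empty(n_a)
    vpi_vals = np.empty(n_a)
    q = np.empty(n_a)
    p = np.empty(n_a)
    n = 0
    cur_block = -1
    for t in range(T):
        if b_arr[t] != cur_block:
            mean[:, :] = 0.0
            var[:, :] = eta
            rate[:] = 0.0
            n = 0
            cur_block = b_arr[t]
        s = s_arr[t]
        # best and second best by posterior mean, ties to lowest index
        a1 = 0
        for a in range(1, n_a):
            if mean[s, a] > mean[s, a1]:
                a1 = a
        a2 = 0 if a1 != 0 else 1
        for a in range(n_a):
            if a != a1 and mean[s, a] > mean[s, a2]:
                a2 = a
        any_above = False
        for a in range(n_a):
            if a == a1:
                gap = mean[s, a2] - mean[s, a1]
                sd = math.sqrt(var[s, a1])
            else:
                gap = mean[s, a] - mean[s, a1]
                sd = math.sqrt(var[s, a])
            if sd == 0.0:
                v = 0.0
            else:
                z = gap / sd
                cdf = 0.5 * (1.0 + math.erf(z / _SQRT2))
                v = gap * cdf + sd * _INV_SQRT_2PI * math.exp(-0.5 * z * z)
                if v < 0.0:
                    v = 0.0
            vpi_vals[a] = v
            if v > rate[s]:
                any_above = True
        if any_above:
            i, _ = _bwm_decide(joint, p_bwm, mem_s, mem_a, mem_r, mem_k, n,
                               s, eps, theta, n_s, n_a)
            for a in range(n_a):
                q[a] = p_bwm[a] if vpi_vals[a] > rate[s] else mean[s, a]
        else:
            i = 0
            for a in range(n_a):
                q[a] = mean[s, a]
        _softmax(q, beta, p)
        a_t = a_arr[t]
        r_t = r_arr[t]
        out_p[t] = p[a_t]
        out_i[t] = i
        out_h[t] = _entropy_bits(p)
        gain = var[s, a_t] / (var[s, a_t] + eta)  # observation noise = eta
        mean[s, a_t] += gain * (r_t - mean[s, a_t])
        var[s, a_t] = (1.0 - gain) * var[s, a_t]
        rate[s] = (1.0 - sigma_r) * rate[s] + sigma_r * r_t
        n = _mem_push(mem_s, mem_a, mem_r, mem_k, n, cap, s, a_t, r_t)
    return out_p, out_i, out_h
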