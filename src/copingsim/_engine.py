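"""Packed-array Euler loop shared by every simulation entry point.

The loop is written in a numba-compilable style (plain loops plus
``np.dot``) and is jitted when numba is importable; otherwise the same
function runs as pure Python/numpy.  Both paths compute identical arithmetic.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _loop(
    u0,
    W0,
    l0,
    d0,
    tau_u,
    baseline,
    mul_e,
    mul_d,
    add_e,
    add_d,
    pool_src,
    pool_w,
    pool_th,
    pool_tau,
    pool_dtau,
    ext_gain,
    ext,
    dtar,
    rule_post,
    rule_pre,
    rule_eta,
    rule_thpost,
    rule_thpre,
    rule_sign,
    dt,
    stride,
    bound,
):
    n_steps = ext.shape[0]
    n = u0.shape[0]
    m = l0.shape[0]
    n_rules = rule_post.shape[0]
    n_rec = n_steps // stride + 1

    times = np.empty(n_rec)
    U = np.empty((n_rec, n))
    A = np.empty((n_rec, n))
    L = np.empty((n_rec, m))
    PW = np.empty((n_rec, n_rules))

    u = u0.copy()
    W = W0.copy()
    l = l0.copy()
    d = d0.copy()
    a = np.empty(n)
    for j in range(n):
        a[j] = max(np.tanh(u[j]), 0.0)

    rec = 0
    times[rec] = 0.0
    for j in range(n):
        U[rec, j] = u[j]
        A[rec, j] = a[j]
    for j in range(m):
        L[rec, j] = l[j]
    for r in range(n_rules):
        PW[rec, r] = W[rule_post[r], rule_pre[r]]

    status = 0
    bad = -1
    for k in range(n_steps):
        syn = np.dot(W, a)
        me = np.dot(mul_e, l)
        md = np.dot(mul_d, l)
        ae = np.dot(add_e, l)
        ad = np.dot(add_d, l)
        ek = ext[k]
        for j in range(n):
            drive = (baseline[j] + syn[j] + ek * ext_gain[j]) * (1.0 + me[j]) / (
                1.0 + md[j]
            ) + ae[j] - ad[j]
            u[j] = u[j] + (dt / tau_u[j]) * (drive - u[j])
            if abs(u[j]) > bound:
                status = 1
                bad = j
        # Hebbian update uses the pre-step activations (pre and post sampled
        # on the same grid as the unit update).
        for r in range(n_rules):
            post = a[rule_post[r]] - rule_thpost[r]
            pre = a[rule_pre[r]] - rule_thpre[r]
            if post > 0.0 and pre > 0.0:
                W[rule_post[r], rule_pre[r]] += (
                    rule_sign[r] * dt * rule_eta[r] * post * pre
                )
        for j in range(m):
            release = (1.0 - d[j]) * pool_w[j] * a[pool_src[j]]
            l[j] = l[j] + (dt / pool_tau[j]) * (release - pool_th[j] * np.tanh(l[j]))
            if l[j] < 0.0:
                l[j] = 0.0
            d[j] = d[j] + (dt / pool_dtau[j]) * (dtar[k, j] - d[j])
            if d[j] < 0.0:
                d[j] = 0.0
            elif d[j] > 1.0:
                d[j] = 1.0
        for j in range(n):
            a[j] = max(np.tanh(u[j]), 0.0)
        if status != 0:
            break
        if (k + 1) % stride == 0:
            rec += 1
            times[rec] = (k + 1) * dt
            for j in range(n):
                U[rec, j] = u[j]
                A[rec, j] = a[j]
            for j in range(m):
                L[rec, j] = l[j]
            for r in range(n_rules):
                PW[rec, r] = W[rule_post[r], rule_pre[r]]

    wfin = np.empty(n_rules)
    for r in range(n_rules):
        wfin[r] = W[rule_post[r], rule_pre[r]]
    return status, bad, times, U, A, L, PW, u, l, d, wfin


def run_packed(
    u0,
    W0,
    l0,
    d0,
    tau_u,
    baseline,
    mul_e,
    mul_d,
    add_e,
    add_d,
    pool_src,
    pool_w,
    pool_th,
    pool_tau,
    pool_dtau,
    ext_gain,
    ext,
    dtar,
    rule_post,
    rule_pre,
    rule_eta,
    rule_thpost,
    rule_thpre,
    rule_sign,
    dt,
    stride,
    bound,
):
    """Run the packed loop and return (status, bad_unit, times, U, A, L, PW, finals)."""
    status, bad, times, U, A, L, PW, u, l, d, wfin = _loop(
        np.ascontiguousarray(u0, dtype=np.float64),
        np.ascontiguousarray(W0, dtype=np.float64),
        np.ascontiguousarray(l0, dtype=np.float64),
        np.ascontiguousarray(d0, dtype=np.float64),
        np.ascontiguousarray(tau_u, dtype=np.float64),
        np.ascontiguousarray(baseline, dtype=np.float64),
        np.ascontiguousarray(mul_e, dtype=np.float64),
        np.ascontiguousarray(mul_d, dtype=np.float64),
        np.ascontiguousarray(add_e, dtype=np.float64),
        np.ascontiguousarray(add_d, dtype=np.float64),
        np.ascontiguousarray(pool_src, dtype=np.int64),
        np.ascontiguousarray(pool_w, dtype=np.float64),
        np.ascontiguousarray(pool_th, dtype=np.float64),
        np.ascontiguousarray(pool_tau, dtype=np.float64),
        np.ascontiguousarray(pool_dtau, dtype=np.float64),
        np.ascontiguousarray(ext_gain, dtype=np.float64),
        np.ascontiguousarray(ext, dtype=np.float64),
        np.ascontiguousarray(dtar, dtype=np.float64),
        np.ascontiguousarray(rule_post, dtype=np.int64),
        np.ascontiguousarray(rule_pre, dtype=np.int64),
        np.ascontiguousarray(rule_eta, dtype=np.float64),
        np.ascontiguousarray(rule_thpost, dtype=np.float64),
        np.ascontiguousarray(rule_thpre, dtype=np.float64),
        np.ascontiguousarray(rule_sign, dtype=np.float64),
        float(dt),
        int(stride),
        float(bound),
    )
    return status, bad, times, U, A, L, PW, u, l, d, wfin
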