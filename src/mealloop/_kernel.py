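"""Compiled fixed-step integrator for the meal-model state equations.

The state layout and parameter packing mirror :mod:`mealloop.model`:
``y = [D, I, X, Q, C_f[0..nf-1], C_s[0..ns-1]]`` and
``p = [k_sc, V_I, CL_I, p_2, S_I, I_b, V_G, S_G, EGB, F_b, phi, k_fast,
k_slow]``.  Inputs (insulin delivery and ingestion rate) are constant on each
knot interval; knots include every square-pulse edge, so the right-hand side
is smooth wherever the integrator takes a step.  Classic fourth-order
Runge-Kutta with a step no larger than ``h_max`` is then accurate far beyond
measurement precision and, being adaptivity-free, yields an objective that is
smooth in the parameters for finite-difference Jacobians.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _rhs(y, dy, u, r, p, nf, ns):
    k_sc = p[0]
    V_I = p[1]
    CL_I = p[2]
    p_2 = p[3]
    S_I = p[4]
    I_b = p[5]
    V_G = p[6]
    S_G = p[7]
    egb = p[8]
    F_b = p[9]
    phi = p[10]
    k_f = p[11]
    k_s = p[12]

    D = y[0]
    ins = y[1]
    X = y[2]
    Q = y[3]
    G = 1000.0 * Q / V_G
    ogi = k_f * y[3 + nf] + k_s * y[3 + nf + ns]

    dy[0] = u - k_sc * D
    dy[1] = k_sc * D / V_I - (CL_I / V_I) * ins
    dy[2] = p_2 * (S_I * (ins - I_b) - X)
    dy[3] = ogi + egb - F_b - (S_G + X) * G / 1000.0

    dy[4] = phi * r - k_f * y[4]
    for j in range(1, nf):
        dy[4 + j] = k_f * (y[3 + j] - y[4 + j])
    base = 4 + nf
    dy[base] = (1.0 - phi) * r - k_s * y[base]
    for j in range(1, ns):
        dy[base + j] = k_s * (y[base + j - 1] - y[base + j])


@njit(cache=True)
def rk4_path(y0, knots, u_arr, r_arr, p, nf, ns, h_max):
    """Integrate knot-to-knot with RK4, returning the state at every knot."""
    n = y0.size
    m = knots.size
    out = np.empty((m, n))
    y = y0.copy()
    out[0] = y
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    yt = np.empty(n)
    for i in range(m - 1):
        span = knots[i + 1] - knots[i]
        nsub = int(np.ceil(span / h_max))
        if nsub < 1:
            nsub = 1
        h = span / nsub
        u = u_arr[i]
        r = r_arr[i]
        for _ in range(nsub):
            _rhs(y, k1, u, r, p, nf, ns)
            for j in range(n):
                yt[j] = y[j] + 0.5 * h * k1[j]
            _rhs(yt, k2, u, r, p, nf, ns)
            for j in range(n):
                yt[j] = y[j] + 0.5 * h * k2[j]
            _rhs(yt, k3, u, r, p, nf, ns)
            for j in range(n):
                yt[j] = y[j] + h * k3[j]
            _rhs(yt, k4, u, r, p, nf, ns)
            for j in range(n):
                y[j] = y[j] + (h / 6.0) * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        out[i + 1] = y
    return out
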