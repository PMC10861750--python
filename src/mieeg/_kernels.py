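"""Compiled fixed-step RK4 integration kernels.

Both kernels integrate many independent realizations (columns) at once so
that whole trial ensembles are advanced in a single pass. Forcing inputs are
applied by zero-order hold: every Runge-Kutta stage of the step k -> k+1
uses the input sample at index k. A trajectory magnitude guard aborts the
integration and reports the offending step instead of propagating inf/nan.

`nmm_deriv` is the compiled twin of :func:`mieeg.neural_mass.nmm_derivatives`;
a unit test pins the two against each other.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _sigm(v, e0, r):
    # firing-rate sigmoid centred on 0, range (-e0, +e0); exp overflow guarded
    x = r * v
    if x > 50.0:
        return e0
    if x < -50.0:
        return -e0
    return 2.0 * e0 / (1.0 + np.exp(-x)) - e0


@njit(cache=True)
def vdp_rk4(lam, p, gain, y0, yd0, forcing, dt, bound):
    """Integrate van der Pol columns; returns (Y trajectory, blowup step).

    y0, yd0 : (n,) initial state per column.
    forcing : (T, n) forcing samples (zero-order hold).
    Output Y has shape (T, n); blowup step is -1 when the bound never trips.
    """
    T, n = forcing.shape
    out = np.empty((T, n))
    y = y0.copy()
    yd = yd0.copy()
    p2 = p * p
    for k in range(T):
        for j in range(n):
            out[k, j] = y[j]
        if k == T - 1:
            break
        for j in range(n):
            f = gain * forcing[k, j]
            a1 = yd[j]
            b1 = (lam - y[j] * y[j]) * a1 - p2 * y[j] + f
            ya = y[j] + 0.5 * dt * a1
            a2 = yd[j] + 0.5 * dt * b1
            b2 = (lam - ya * ya) * a2 - p2 * ya + f
            yb = y[j] + 0.5 * dt * a2
            a3 = yd[j] + 0.5 * dt * b2
            b3 = (lam - yb * yb) * a3 - p2 * yb + f
            yc = y[j] + dt * a3
            a4 = yd[j] + dt * b3
            b4 = (lam - yc * yc) * a4 - p2 * yc + f
            y[j] += dt * (a1 + 2.0 * a2 + 2.0 * a3 + a4) / 6.0
            yd[j] += dt * (b1 + 2.0 * b2 + 2.0 * b3 + b4) / 6.0
            if not (np.abs(y[j]) < bound and np.abs(yd[j]) < bound):
                return out, k + 1
    return out, -1


@njit(cache=True)
def nmm_deriv(s, C12, C21, C13, C31, C14, C41, C43, C44,
              G2, G3, G4, w2, w3, w4, e0, r, u1, u4):
    """Ten coupled first-order derivatives of one column state `s`."""
    y1, x1, y2, x2, y3, x3, y4, x4, y4p, x4p = (
        s[0], s[1], s[2], s[3], s[4], s[5], s[6], s[7], s[8], s[9])
    v1 = C12 * y2 - C13 * y3 - C14 * y4
    v2 = C21 * y1
    v3 = C31 * y1
    v4 = C41 * y1 - C43 * y3 - C44 * y4 + y4p
    z1 = _sigm(v1, e0, r)
    z2 = _sigm(v2, e0, r)
    z3 = _sigm(v3, e0, r)
    z4 = _sigm(v4, e0, r)
    d = np.empty(10)
    if u1 != 0.0:
        u1_term = u1 / C12
    else:
        u1_term = 0.0
    d[0] = x1
    d[1] = G2 * w2 * z1 - 2.0 * w2 * x1 - w2 * w2 * y1
    d[2] = x2
    d[3] = G2 * w2 * (z2 + u1_term) - 2.0 * w2 * x2 - w2 * w2 * y2
    d[4] = x3
    d[5] = G3 * w3 * z3 - 2.0 * w3 * x3 - w3 * w3 * y3
    d[6] = x4
    d[7] = G4 * w4 * z4 - 2.0 * w4 * x4 - w4 * w4 * y4
    d[8] = x4p
    d[9] = G2 * w2 * u4 - 2.0 * w2 * x4p - w2 * w2 * y4p
    return d


@njit(cache=True)
def nmm_rk4(C12, C21, C13, C31, C14, C41, C43, C44,
            G2, G3, G4, w2, w3, w4, e0, r,
            u1, u4, dt, bound, state0, record_states):
    """Integrate NMM columns; returns (v1, states, blowup step).

    u1, u4 : (T, n) inputs; state0 : (10, n) initial state.
    v1 has shape (T, n). `states` is (T, 10, n) when record_states else
    (1, 10, n) (final state only).
    """
    T, n = u1.shape
    v1 = np.empty((T, n))
    if record_states:
        states = np.empty((T, 10, n))
    else:
        states = np.empty((1, 10, n))
    s = state0.copy()
    col = np.empty(10)
    blow = -1
    for k in range(T):
        for j in range(n):
            v1[k, j] = C12 * s[2, j] - C13 * s[4, j] - C14 * s[6, j]
        if record_states:
            for i in range(10):
                for j in range(n):
                    states[k, i, j] = s[i, j]
        if k == T - 1:
            break
        for j in range(n):
            for i in range(10):
                col[i] = s[i, j]
            k1 = nmm_deriv(col, C12, C21, C13, C31, C14, C41, C43, C44,
                           G2, G3, G4, w2, w3, w4, e0, r, u1[k, j], u4[k, j])
            k2 = nmm_deriv(col + 0.5 * dt * k1, C12, C21, C13, C31, C14, C41,
                           C43, C44, G2, G3, G4, w2, w3, w4, e0, r,
                           u1[k, j], u4[k, j])
            k3 = nmm_deriv(col + 0.5 * dt * k2, C12, C21, C13, C31, C14, C41,
                           C43, C44, G2, G3, G4, w2, w3, w4, e0, r,
                           u1[k, j], u4[k, j])
            k4 = nmm_deriv(col + dt * k3, C12, C21, C13, C31, C14, C41,
                           C43, C44, G2, G3, G4, w2, w3, w4, e0, r,
                           u1[k, j], u4[k, j])
            ok = True
            for i in range(10):
                s[i, j] = col[i] + dt * (k1[i] + 2.0 * k2[i]
                                         + 2.0 * k3[i] + k4[i]) / 6.0
                if not (np.abs(s[i, j]) < bound):
                    ok = False
            if not ok:
                return v1, states, k + 1
    if not record_states:
        for i in range(10):
            for j in range(n):
                states[0, i, j] = s[i, j]
    return v1, states, blow
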