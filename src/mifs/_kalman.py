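"""Compiled Kalman recursions.

The filter uses the univariate (sequential) measurement-update treatment:
with a diagonal measurement-noise covariance the indicators of one occasion
can be processed one at a time as scalar updates, which yields exactly the
same posterior moments and prediction-error-decomposition log-likelihood as
the joint update while handling partially missing occasions by simply
skipping the missing rows.  The backward pass is the fixed-interval
(Rauch-Tung-Striebel) smoother.

Data layout: all persons' rows stacked and sorted by (person, time);
``starts`` holds the row offset of each person block (length n_persons + 1).
"""

import numpy as np
from numba import njit

__all__ = ["filter_loglik", "rts_smooth"]


@njit(cache=True)
def filter_loglik(y, obs, x, starts, tau, lam, amat, evar, F, alpha, B, Q,
                  a1, P1, store):
    """Kalman filter + prediction-error-decomposition log-likelihood.

    Returns (loglik, att, Ptt, apred, Ppred).  ``obs`` is a uint8 mask
    (1 = observed); missing cells of ``y`` are ignored.  When ``store`` is
    false the moment arrays are left empty (likelihood-only evaluation).
    """
    N, p = y.shape
    q = F.shape[0]
    r = x.shape[1]
    n_persons = starts.shape[0] - 1

    if store:
        att = np.empty((N, q))
        Ptt = np.empty((N, q, q))
        apred = np.empty((N, q))
        Ppred = np.empty((N, q, q))
    else:
        att = np.empty((0, q))
        Ptt = np.empty((0, q, q))
        apred = np.empty((0, q))
        Ppred = np.empty((0, q, q))

    log2pi = np.log(2.0 * np.pi)
    ll = 0.0
    a = np.empty(q)
    P = np.empty((q, q))
    PZ = np.empty(q)
    anew = np.empty(q)
    FP = np.empty((q, q))
    Pnew = np.empty((q, q))

    for i in range(n_persons):
        for t in range(starts[i], starts[i + 1]):
            if t == starts[i]:
                for k in range(q):
                    a[k] = a1[k]
                    for l in range(q):
                        P[k, l] = P1[k, l]
            else:
                # time update: a = alpha + F a + B x_t, P = F P F' + Q
                for k in range(q):
                    s = alpha[k]
                    for l in range(q):
                        s += F[k, l] * a[l]
                    for j in range(r):
                        s += B[k, j] * x[t, j]
                    anew[k] = s
                for k in range(q):
                    for l in range(q):
                        s = 0.0
                        for m in range(q):
                            s += F[k, m] * P[m, l]
                        FP[k, l] = s
                for k in range(q):
                    for l in range(q):
                        s = Q[k, l]
                        for m in range(q):
                            s += FP[k, m] * F[l, m]
                        Pnew[k, l] = s
                for k in range(q):
                    a[k] = anew[k]
                    for l in range(q):
                        P[k, l] = 0.5 * (Pnew[k, l] + Pnew[l, k])
            if store:
                for k in range(q):
                    apred[t, k] = a[k]
                    for l in range(q):
                        Ppred[t, k, l] = P[k, l]
            # sequential scalar measurement updates over observed rows
            for j in range(p):
                if obs[t, j] == 0:
                    continue
                pred = tau[j]
                for k in range(q):
                    pred += lam[j, k] * a[k]
                for m in range(r):
                    pred += amat[j, m] * x[t, m]
                v = y[t, j] - pred
                f = evar[j]
                for k in range(q):
                    PZ[k] = 0.0
                    for l in range(q):
                        PZ[k] += P[k, l] * lam[j, l]
                    f += lam[j, k] * PZ[k]
                if f <= 1e-300 or not np.isfinite(f):
                    return np.nan, att, Ptt, apred, Ppred
                ll += -0.5 * (log2pi + np.log(f) + v * v / f)
                inv_f = 1.0 / f
                for k in range(q):
                    a[k] += PZ[k] * inv_f * v
                for k in range(q):
                    for l in range(q):
                        P[k, l] -= PZ[k] * PZ[l] * inv_f
            if store:
                for k in range(q):
                    att[t, k] = a[k]
                    for l in range(q):
                        Ptt[t, k, l] = P[k, l]
    return ll, att, Ptt, apred, Ppred


@njit(cache=True)
def rts_smooth(att, Ptt, apred, Ppred, F, starts):
    """Fixed-interval smoother: E[eta_t | y_1..T] and its covariance."""
    N, q = att.shape
    asm = np.empty((N, q))
    Psm = np.empty((N, q, q))
    n_persons = starts.shape[0] - 1
    for i in range(n_persons):
        last = starts[i + 1] - 1
        asm[last] = att[last]
        Psm[last] = Ptt[last]
        for t in range(last - 1, starts[i] - 1, -1):
            # J = Ptt[t] F' Ppred[t+1]^-1
            C = Ptt[t] @ F.T
            J = np.linalg.solve(Ppred[t + 1].T, C.T).T
            asm[t] = att[t] + J @ (asm[t + 1] - apred[t + 1])
            Pn = Ptt[t] + J @ (Psm[t + 1] - Ppred[t + 1]) @ J.T
            Psm[t] = 0.5 * (Pn + Pn.T)
    return asm, Psm
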