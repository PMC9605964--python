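"""Compiled Baum-Welch core (2 states, binary symbols) with per-fit early stop.

The shuffle null refits thousands of small HMMs; the numba path runs each
fit in compiled loops and stops as soon as that fit's log-likelihood change
drops below tolerance, which the batched NumPy path (``_hmm.py``) cannot do
per element.  Both paths implement the same scaled Rabiner recursions and
are cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _bw_single(obs, lengths, A, B, pi, max_iter, tol):
    """EM for one dataset in place; returns final log-likelihood."""
    S = obs.shape[0]
    Tmax = obs.shape[1]
    alpha = np.empty((Tmax, 2))
    cvec = np.empty(Tmax)
    ll_prev = -1e300
    ll = 0.0
    for _ in range(max_iter):
        xi = np.zeros((2, 2))
        ball = np.zeros(2)
        bh = np.zeros(2)
        pia = np.zeros(2)
        ll = 0.0
        for s in range(S):
            L = lengths[s]
            # forward (scaled)
            o0 = obs[s, 0]
            a0 = pi[0] * B[0, o0]
            a1 = pi[1] * B[1, o0]
            c = a0 + a1
            alpha[0, 0] = a0 / c
            alpha[0, 1] = a1 / c
            cvec[0] = c
            ll += np.log(c)
            for t in range(1, L):
                ot = obs[s, t]
                a0 = (alpha[t - 1, 0] * A[0, 0] + alpha[t - 1, 1] * A[1, 0]) * B[0, ot]
                a1 = (alpha[t - 1, 0] * A[0, 1] + alpha[t - 1, 1] * A[1, 1]) * B[1, ot]
                c = a0 + a1
                alpha[t, 0] = a0 / c
                alpha[t, 1] = a1 / c
                cvec[t] = c
                ll += np.log(c)
            # backward with on-the-fly accumulation
            b0 = 1.0
            b1 = 1.0
            for t in range(L - 1, -1, -1):
                if t < L - 1:
                    ot1 = obs[s, t + 1]
                    eb0 = B[0, ot1] * b0 / cvec[t + 1]
                    eb1 = B[1, ot1] * b1 / cvec[t + 1]
                    xi[0, 0] += alpha[t, 0] * A[0, 0] * eb0
                    xi[0, 1] += alpha[t, 0] * A[0, 1] * eb1
                    xi[1, 0] += alpha[t, 1] * A[1, 0] * eb0
                    xi[1, 1] += alpha[t, 1] * A[1, 1] * eb1
                    nb0 = A[0, 0] * eb0 + A[0, 1] * eb1
                    nb1 = A[1, 0] * eb0 + A[1, 1] * eb1
                    b0 = nb0
                    b1 = nb1
                g0 = alpha[t, 0] * b0
                g1 = alpha[t, 1] * b1
                ball[0] += g0
                ball[1] += g1
                if obs[s, t] == 1:
                    bh[0] += g0
                    bh[1] += g1
                if t == 0:
                    pia[0] += g0
                    pia[1] += g1
        # M step (zero-mass rows keep previous values)
        for i in range(2):
            row = xi[i, 0] + xi[i, 1]
            if row > 1e-300:
                A[i, 0] = xi[i, 0] / row
                A[i, 1] = xi[i, 1] / row
            if ball[i] > 1e-300:
                B[i, 1] = bh[i] / ball[i]
                B[i, 0] = 1.0 - B[i, 1]
        tot = pia[0] + pia[1]
        if tot > 1e-300:
            pi[0] = pia[0] / tot
            pi[1] = pia[1] / tot
        if np.abs(ll - ll_prev) < tol:
            break
        ll_prev = ll
    return ll


@njit(cache=True)
def bw_batch_numba(obs_batch, lengths, A, B, pi, max_iter, tol):
    """Run EM independently for every batch element (in place)."""
    nb = obs_batch.shape[0]
    ll = np.empty(nb)
    for b in range(nb):
        ll[b] = _bw_single(obs_batch[b], lengths, A[b], B[b], pi[b], max_iter, tol)
    return ll
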