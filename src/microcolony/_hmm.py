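"""Batched Baum-Welch for 2-state HMMs over binary symbol sequences.

The shuffle-null randomization test refits thousands of HMMs (replicates x
random restarts), so the EM recursions here are vectorized over a batch
axis: every replicate/restart runs simultaneously as NumPy array ops.  Only
the forward/backward recursions loop over time; all sufficient statistics
are accumulated in single vectorized contractions.

Sequences of unequal length are padded and masked: padded steps freeze the
forward/backward variables and contribute nothing to the statistics.
Scaled recursions follow Rabiner's classic formulation.
"""

from __future__ import annotations

import numpy as np

N_STATES = 2
N_SYMBOLS = 2


def pack_sequences(seqs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pad integer sequences to (S, T_max); returns (obs, mask)."""
    S = len(seqs)
    T = max(len(s) for s in seqs)
    obs = np.zeros((S, T), dtype=np.int8)
    mask = np.zeros((S, T), dtype=bool)
    for i, s in enumerate(seqs):
        obs[i, : len(s)] = s
        mask[i, : len(s)] = True
    return obs, mask


def random_params(rng: np.random.Generator, batch: int):
    """Random row-stochastic initial parameters for ``batch`` fits."""

    def rows(shape):
        g = rng.gamma(1.0, size=shape) + 1e-3
        return g / g.sum(axis=-1, keepdims=True)

    A = rows((batch, N_STATES, N_STATES))
    B = rows((batch, N_STATES, N_SYMBOLS))
    pi = rows((batch, N_STATES))
    return A, B, pi


def baum_welch_batch(
    obs: np.ndarray,
    mask: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    pi: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
):
    """Run EM on a batch of parameter sets over (possibly batched) data.

    Parameters
    ----------
    obs : int array (Bo, S, T) with Bo in {1, batch}
        Symbol sequences; broadcast over the batch axis when Bo == 1.
    mask : bool array (S, T)
        True at valid (unpadded) steps; shared across the batch.
    A, B, pi : arrays (batch, 2, 2), (batch, 2, 2), (batch, 2)
        Initial transition, emission and initial-state probabilities.

    Returns
    -------
    (A, B, pi, loglik, ll_history)
        Final parameters, per-batch log-likelihood, and the per-iteration
        batch log-likelihood trace (monotone non-decreasing).
    """
    A = A.copy()
    B = B.copy()
    pi = pi.copy()
    nb = A.shape[0]
    S, T = mask.shape
    # padding is tail-only: mask[s, t] >= mask[s, t+1]
    ot = np.ascontiguousarray(
        np.broadcast_to(obs, (nb,) + obs.shape[1:]).transpose(2, 0, 1)
    )  # (T, nb, S)
    is_high = (ot == 1)[..., None]  # (T, nb, S, 1)
    mvalid = mask.T[:, None, :]  # (T, 1, S)
    mvalid_e = mvalid[..., None]  # (T, 1, S, 1)

    prev_ll = np.full(nb, -np.inf)
    history = []
    alphas = np.empty((T, nb, S, N_STATES))
    betas = np.empty((T, nb, S, N_STATES))
    c = np.empty((T, nb, S))
    for _ in range(max_iter):
        # emission probabilities at every step: e[t,b,s,i] = B[b,i,obs]
        e_all = np.where(is_high, B[None, :, None, :, 1], B[None, :, None, :, 0])

        # --- scaled forward
        a = pi[:, None, :] * e_all[0]
        c0 = np.where(mvalid[0], a.sum(-1), 1.0)
        a = a / c0[..., None]
        alphas[0], c[0] = a, c0
        for t in range(1, T):
            anew = np.einsum("bsi,bij->bsj", a, A) * e_all[t]
            ct = np.where(mvalid[t], anew.sum(-1), 1.0)
            a = np.where(mvalid_e[t], anew / ct[..., None], a)
            alphas[t], c[t] = a, ct
        ll = np.log(c).sum(axis=(0, 2))  # padded steps contribute log 1 = 0
        history.append(ll)

        # --- scaled backward
        beta = np.ones((nb, S, N_STATES))
        betas[T - 1] = beta
        for t in range(T - 2, -1, -1):
            ebt = e_all[t + 1] * beta / c[t + 1][..., None]
            beta = np.where(
                mvalid_e[t + 1], np.einsum("bij,bsj->bsi", A, ebt), beta
            )
            betas[t] = beta

        # --- sufficient statistics (vectorized over time)
        gamma = alphas * betas  # (T, nb, S, 2); rows sum to 1 at valid steps
        gw = gamma * mvalid_e
        eb = np.where(mvalid_e[1:], e_all[1:] * betas[1:] / c[1:, ..., None], 0.0)
        xi_sum = A * np.einsum("tbsi,tbsj->bij", alphas[:-1], eb)
        b_high = (gw * is_high).sum(axis=(0, 2))
        b_all = gw.sum(axis=(0, 2))
        pi_acc = gw[0].sum(axis=1)

        # --- M step (rows with no mass keep their old values)
        rowA = xi_sum.sum(-1, keepdims=True)
        A = np.where(rowA > 1e-300, xi_sum / np.maximum(rowA, 1e-300), A)
        rowB = b_all[..., None]
        Bnew = np.stack([b_all - b_high, b_high], axis=-1)
        B = np.where(rowB > 1e-300, Bnew / np.maximum(rowB, 1e-300), B)
        pi = pi_acc / np.maximum(pi_acc.sum(-1, keepdims=True), 1e-300)

        if np.all(np.abs(ll - prev_ll) < tol):
            prev_ll = ll
            break
        prev_ll = ll

    return A, B, pi, prev_ll, np.array(history)


def canonical_order(A, B, pi):
    """Reorder states so state 1 has the larger HIGH-emission probability.

    Resolves Baum-Welch label switching: after reordering, state 0 is the
    LOW-emitting state and state 1 the HIGH-emitting state, so transition
    entries are comparable across fits.
    """
    swap = B[:, 0, 1] > B[:, 1, 1]  # state 0 emits HIGH more often -> swap
    idx = np.where(swap[:, None], np.array([1, 0])[None, :], np.array([0, 1])[None, :])
    bi = np.arange(A.shape[0])[:, None]
    A2 = A[bi[:, :, None], idx[:, :, None], idx[:, None, :]]
    B2 = B[bi, idx][:, :, :]
    pi2 = pi[bi, idx]
    return A2, B2, pi2


def fit_best_of_restarts(
    obs, mask, seed_seq: np.random.SeedSequence, n_restarts: int = 5,
    max_iter: int = 100, tol: float = 1e-6, n_datasets: int = 1,
    backend: str = "numba",
):
    """Fit each dataset with ``n_restarts`` random inits; keep the best.

    ``obs`` has shape (n_datasets, S, T); the batch axis is expanded to
    n_datasets * n_restarts internally.  Returns canonical-ordered
    (A, B, pi, loglik) per dataset.  ``backend`` selects the compiled
    per-fit-early-stopping core ("numba", default) or the pure-NumPy
    reference recursions ("numpy"); both give the same fits.
    """
    rng = np.random.default_rng(seed_seq)
    batch = n_datasets * n_restarts
    A0, B0, pi0 = random_params(rng, batch)
    obs_rep = np.repeat(obs, n_restarts, axis=0)
    if backend == "numba":
        from ._hmm_numba import bw_batch_numba

        lengths = mask.sum(axis=1).astype(np.int64)
        obs_c = np.ascontiguousarray(
            np.broadcast_to(obs_rep, (batch,) + obs.shape[1:]), dtype=np.int8
        )
        A, B, pi = A0, B0, pi0
        ll = bw_batch_numba(obs_c, lengths, A, B, pi, max_iter, tol)
    else:
        A, B, pi, ll, _ = baum_welch_batch(
            obs_rep, mask, A0, B0, pi0, max_iter=max_iter, tol=tol
        )
    ll = ll.reshape(n_datasets, n_restarts)
    best = ll.argmax(axis=1)
    sel = np.arange(n_datasets) * n_restarts + best
    A, B, pi = canonical_order(A[sel], B[sel], pi[sel])
    return A, B, pi, ll[np.arange(n_datasets), best]
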