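"""Shared hidden-Markov machinery: scaled forward/backward and Viterbi.

Used by both the Markov-switching conditional logistic regression and the
movement-only HMM.  All routines take a matrix of per-observation, per-state
log densities (or log choice probabilities) and a segmentation into
independent bursts; each burst restarts the chain at the initial distribution
and the burst log-likelihoods add.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "forward_backward",
    "viterbi",
    "tpm_from_logits",
    "logits_from_tpm",
    "tpm_logit_gradient",
]


def tpm_from_logits(logits: np.ndarray, n: int) -> np.ndarray:
    """Row-softmax transition matrix from N(N-1) free logits (diagonal fixed at 0)."""
    g = np.zeros((n, n))
    logits = np.asarray(logits, dtype=float).reshape(n, n - 1)
    for i in range(n):
        g[i, np.arange(n) != i] = logits[i]
    g -= g.max(axis=1, keepdims=True)
    e = np.exp(g)
    return e / e.sum(axis=1, keepdims=True)


def logits_from_tpm(tpm: np.ndarray) -> np.ndarray:
    """Inverse of :func:`tpm_from_logits` (log ratio to the diagonal entry)."""
    tpm = np.asarray(tpm, dtype=float)
    n = tpm.shape[0]
    out = np.empty((n, n - 1))
    for i in range(n):
        out[i] = np.log(tpm[i, np.arange(n) != i] / tpm[i, i])
    return out.ravel()


def forward_backward(log_p, tpm, delta, segments):
    """Scaled forward-backward pass over independent segments.

    Parameters
    ----------
    log_p : ndarray, shape (S, N)
        Per-observation, per-state log densities.
    tpm : ndarray, shape (N, N)
    delta : ndarray, shape (N,)
        Initial distribution, restarted at every segment.
    segments : sequence of (start, end)

    Returns
    -------
    loglik : float
    u : ndarray, shape (S, N)
        Posterior state probabilities ``P(S_t = i | data)``.
    xi_sum : ndarray, shape (N, N)
        Summed pairwise posteriors ``sum_t P(S_t = i, S_t+1 = j | data)``.
    v0 : ndarray, shape (N,)
        Summed sensitivities ``d loglik / d delta_i`` over segments.
    """
    log_p = np.asarray(log_p, dtype=float)
    S, N = log_p.shape
    u = np.empty_like(log_p)
    xi_sum = np.zeros((N, N))
    v0 = np.zeros(N)
    loglik = 0.0
    for a, b in segments:
        m = log_p[a:b].max(axis=1, keepdims=True)
        p = np.exp(log_p[a:b] - m)  # (L, N), each row max 1
        L = b - a
        phi = np.empty((L, N))
        c = np.empty(L)
        f = delta * p[0]
        c[0] = f.sum()
        phi[0] = f / c[0]
        for t in range(1, L):
            f = (phi[t - 1] @ tpm) * p[t]
            c[t] = f.sum()
            phi[t] = f / c[t]
        if not np.all(np.isfinite(phi)) or np.any(c <= 0):
            raise FloatingPointError(
                f"forward recursion underflow in segment [{a}, {b})"
            )
        loglik += float(np.log(c).sum() + m.sum())
        beta = np.empty((L, N))
        beta[-1] = 1.0
        for t in range(L - 2, -1, -1):
            beta[t] = (tpm @ (p[t + 1] * beta[t + 1])) / c[t + 1]
        u[a:b] = phi * beta
        if L > 1:
            # xi_sum += Gamma * sum_t outer(phi_t, p_{t+1} beta_{t+1} / c_{t+1})
            right = p[1:] * beta[1:] / c[1:, None]
            xi_sum += tpm * (phi[:-1].T @ right)
        v0 += p[0] * beta[0] / c[0]
    return loglik, u, xi_sum, v0


def viterbi(log_p, tpm, delta, segments) -> np.ndarray:
    """Most likely state sequence (0-based), ties broken toward lower index."""
    log_p = np.asarray(log_p, dtype=float)
    S, N = log_p.shape
    with np.errstate(divide="ignore"):
        lt = np.log(tpm)
        ld = np.log(delta)
    path = np.empty(S, dtype=np.int64)
    for a, b in segments:
        L = b - a
        score = ld + log_p[a]
        back = np.empty((L, N), dtype=np.int64)
        for t in range(1, L):
            cand = score[:, None] + lt  # (from, to)
            back[t] = cand.argmax(axis=0)
            score = cand.max(axis=0) + log_p[a + t]
        s = int(score.argmax())
        path[b - 1] = s
        for t in range(L - 1, 0, -1):
            s = int(back[t, s])
            path[a + t - 1] = s
    return path


def tpm_logit_gradient(xi_sum, tpm, delta, v0) -> np.ndarray:
    """Gradient of the log-likelihood w.r.t. the free transition logits.

    Combines the pairwise-posterior term with the exact implicit-function
    derivative of the stationary initial distribution ``delta`` through the
    transition matrix (``delta' = 1' (I - Gamma + U)^{-1}``), where ``v0`` is
    ``d loglik / d delta`` from the forward-backward pass.
    """
    n = tpm.shape[0]
    D = xi_sum / tpm
    A = np.eye(n) - tpm + np.ones((n, n))
    # sensitivity of loglik to Gamma via delta: coefficient of dGamma_{i,j}
    # is delta_i (A^{-1} v0)_j because v0' A^{-T} = (A^{-1} v0)'
    D = D + np.outer(delta, np.linalg.solve(A, v0))
    inner = np.einsum("il,il->i", D, tpm)
    dG = tpm * (D - inner[:, None])
    out = np.empty((n, n - 1))
    for i in range(n):
        out[i] = dG[i, np.arange(n) != i]
    return out.ravel()
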