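"""Scaled forward-backward recursions shared by the package's HMMs.

Emission likelihoods are precomputed per observation as a (T, K) matrix, so
the same core serves the Beta-emission methylome HMM and the multi-track
Bernoulli meta-HMM.  Chains never cross chromosome boundaries; callers run
one recursion per chromosome.  Hot loops are numba-compiled.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TINY = 1e-300


@njit(cache=False)
def forward_scaled(pi, A, B):
    """Scaled forward pass.

    pi: (K,) initial probabilities, A: (K, K) transitions, B: (T, K)
    emission likelihoods.  Returns (alpha, scale, loglik) with
    alpha[t] the normalized forward vector and loglik = sum(log scale).
    """
    T, K = B.shape
    alpha = np.empty((T, K))
    scale = np.empty(T)
    a = pi * B[0]
    c = a.sum()
    if c < TINY:
        c = TINY
    alpha[0] = a / c
    scale[0] = c
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c = a.sum()
        if c < TINY:
            c = TINY
        alpha[t] = a / c
        scale[t] = c
    return alpha, scale, np.log(scale).sum()


@njit(cache=False)
def backward_scaled(A, B, scale):
    T, K = B.shape
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / scale[t + 1]
    return beta


@njit(cache=False)
def xi_sum(A, B, alpha, beta, scale):
    """Sum over t of the joint posterior of (state_t, state_{t+1})."""
    T, K = B.shape
    out = np.zeros((K, K))
    for t in range(T - 1):
        w = B[t + 1] * beta[t + 1] / scale[t + 1]
        for i in range(K):
            ai = alpha[t, i]
            for j in range(K):
                out[i, j] += ai * A[i, j] * w[j]
    return out


def forward_backward(pi, A, B):
    """Posteriors, transition counts and log-likelihood for one chain."""
    pi = np.ascontiguousarray(pi)
    A = np.ascontiguousarray(A)
    B = np.ascontiguousarray(B)
    alpha, scale, ll = forward_scaled(pi, A, B)
    beta = backward_scaled(A, B, scale)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi = xi_sum(A, B, alpha, beta, scale)
    return gamma, xi, ll


def brute_force_loglik(pi, A, B):
    """Exact log-likelihood by enumerating every state path (oracle for tests)."""
    T, K = B.shape
    total = 0.0
    for path in np.ndindex(*([K] * T)):
        p = pi[path[0]] * B[0, path[0]]
        for t in range(1, T):
            p *= A[path[t - 1], path[t]] * B[t, path[t]]
        total += p
    return np.log(total)
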