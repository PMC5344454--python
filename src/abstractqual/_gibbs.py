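"""Numba kernels for collapsed Gibbs sampling.

All randomness flows through numba's own RNG, seeded once per fit via
``seed_rng`` so fits are deterministic given the seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def init_assignments(words, docs, K, ndk, nkw, nk):
    """Random topic init; fills count matrices in place, returns z."""
    T = words.shape[0]
    z = np.empty(T, dtype=np.int32)
    for i in range(T):
        k = np.random.randint(0, K)
        z[i] = k
        ndk[docs[i], k] += 1
        nkw[k, words[i]] += 1
        nk[k] += 1
    return z


@njit(cache=True)
def gibbs_sweep(
    z, words, docs, ndk, nkw, nk,
    alpha, beta,
    eta, base, dot, y, doc_len,
    supervised,
):
    """One full sweep over all tokens.

    When ``supervised`` the conditional for token i in doc d is multiplied by
    p(y_d | zbar with z_i = k), where the response linear predictor is
    base[d] + eta . zbar[d]; ``dot[d]`` caches eta . ndk[d] and is maintained
    incrementally.
    """
    K = ndk.shape[1]
    V = nkw.shape[1]
    vbeta = V * beta
    probs = np.empty(K)
    T = words.shape[0]
    for i in range(T):
        d = docs[i]
        w = words[i]
        k0 = z[i]
        ndk[d, k0] -= 1
        nkw[k0, w] -= 1
        nk[k0] -= 1
        if supervised:
            dot[d] -= eta[k0]
        total = 0.0
        for k in range(K):
            p = (ndk[d, k] + alpha) * (nkw[k, w] + beta) / (nk[k] + vbeta)
            if supervised:
                lin = base[d] + (dot[d] + eta[k]) / doc_len[d]
                s = 1.0 / (1.0 + np.exp(-lin))
                if y[d] == 1:
                    p *= s
                else:
                    p *= 1.0 - s
            probs[k] = p
            total += p
        u = np.random.random() * total
        k = 0
        acc = probs[0]
        while acc < u and k < K - 1:
            k += 1
            acc += probs[k]
        z[i] = k
        ndk[d, k] += 1
        nkw[k, w] += 1
        nk[k] += 1
        if supervised:
            dot[d] += eta[k]


@njit(cache=True)
def fold_in(words, phi, alpha, n_iter, burn_in):
    """Infer a document-topic mixture for new tokens with phi fixed."""
    K = phi.shape[0]
    T = words.shape[0]
    nd = np.zeros(K)
    z = np.empty(T, dtype=np.int32)
    for i in range(T):
        k = np.random.randint(0, K)
        z[i] = k
        nd[k] += 1
    acc = np.zeros(K)
    probs = np.empty(K)
    for it in range(n_iter):
        for i in range(T):
            w = words[i]
            nd[z[i]] -= 1
            total = 0.0
            for k in range(K):
                p = (nd[k] + alpha) * phi[k, w]
                probs[k] = p
                total += p
            u = np.random.random() * total
            k = 0
            s = probs[0]
            while s < u and k < K - 1:
                k += 1
                s += probs[k]
            z[i] = k
            nd[k] += 1
        if it >= burn_in:
            acc += nd
    theta = acc + alpha
    return theta / theta.sum()
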