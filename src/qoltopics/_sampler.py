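"""Numba kernel for collapsed Gibbs sampling.

The RNG is an in-kernel xorshift64* generator seeded through splitmix64, so
a run is bitwise reproducible for a fixed seed regardless of platform,
thread count or numpy version. Draw order is fixed: documents in index
order, positions left to right.
"""

from __future__ import annotations

import numpy as np
from numba import njit, uint64

_U64 = np.uint64
_INV_2_53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True)
def _seed_state(seed):
    # splitmix64 of the seed; guarantees a nonzero xorshift state
    z = uint64(seed) + uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> uint64(30))) * uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> uint64(27))) * uint64(0x94D049BB133111EB)
    z = z ^ (z >> uint64(31))
    if z == uint64(0):
        z = uint64(0x9E3779B97F4A7C15)
    return z


@njit(cache=True)
def _next_u01(state):
    # xorshift64*; returns (uniform in [0,1), new state)
    s = state
    s ^= s >> uint64(12)
    s ^= s << uint64(25)
    s ^= s >> uint64(27)
    out = s * uint64(0x2545F4914F6CDD1D)
    return (out >> uint64(11)) * _INV_2_53, s


@njit(cache=True)
def gibbs_run(words, doc_of, n_docs, K, V, alpha, beta,
              n_iter, burn_in, seed):
    """Collapsed Gibbs chain over token-topic assignments.

    words   : int64[N] term id per position (documents concatenated)
    doc_of  : int64[N] document index per position

    Returns (z, sum_ndt, sum_ntw, sum_nt, n_retained): final assignments and
    count tables summed over the post-burn-in sweeps.
    """
    N = words.shape[0]
    n_dt = np.zeros((n_docs, K), dtype=np.int64)
    n_tw = np.zeros((K, V), dtype=np.int64)
    n_t = np.zeros(K, dtype=np.int64)
    z = np.empty(N, dtype=np.int64)
    p = np.empty(K, dtype=np.float64)

    state = _seed_state(seed)

    # uniform random initialization
    for i in range(N):
        u, state = _next_u01(state)
        t = int(u * K)
        if t == K:
            t = K - 1
        z[i] = t
        d = doc_of[i]
        w = words[i]
        n_dt[d, t] += 1
        n_tw[t, w] += 1
        n_t[t] += 1

    sum_ndt = np.zeros((n_docs, K), dtype=np.float64)
    sum_ntw = np.zeros((K, V), dtype=np.float64)
    sum_nt = np.zeros(K, dtype=np.float64)
    n_retained = 0
    vbeta = V * beta

    for sweep in range(n_iter):
        for i in range(N):
            d = doc_of[i]
            w = words[i]
            t_old = z[i]
            n_dt[d, t_old] -= 1
            n_tw[t_old, w] -= 1
            n_t[t_old] -= 1

            total = 0.0
            for t in range(K):
                total += (n_dt[d, t] + alpha) * (n_tw[t, w] + beta) \
                    / (n_t[t] + vbeta)
                p[t] = total
            u, state = _next_u01(state)
            target = u * total
            t_new = 0
            while t_new < K - 1 and p[t_new] <= target:
                t_new += 1

            z[i] = t_new
            n_dt[d, t_new] += 1
            n_tw[t_new, w] += 1
            n_t[t_new] += 1

        if sweep >= burn_in:
            n_retained += 1
            sum_ndt += n_dt
            sum_ntw += n_tw
            sum_nt += n_t

    return z, sum_ndt, sum_ntw, sum_nt, n_retained


@njit(cache=True)
def gibbs_run_cooc(words, doc_of, n_docs, K, V, alpha, beta,
                   n_iter, burn_in, seed):
    """Like :func:`gibbs_run`, additionally accumulating the pairwise
    same-topic indicator 1[z_i == z_j] over retained sweeps.

    The co-occurrence posterior mean is invariant to topic relabeling, which
    makes it a sharp diagnostic against exhaustive enumeration on tiny
    instances (the posterior mean of theta itself is 1/K by label symmetry).
    Only intended for small N: the accumulator is N x N per sweep.
    """
    N = words.shape[0]
    n_dt = np.zeros((n_docs, K), dtype=np.int64)
    n_tw = np.zeros((K, V), dtype=np.int64)
    n_t = np.zeros(K, dtype=np.int64)
    z = np.empty(N, dtype=np.int64)
    p = np.empty(K, dtype=np.float64)
    state = _seed_state(seed)

    for i in range(N):
        u, state = _next_u01(state)
        t = int(u * K)
        if t == K:
            t = K - 1
        z[i] = t
        n_dt[doc_of[i], t] += 1
        n_tw[t, words[i]] += 1
        n_t[t] += 1

    sum_ndt = np.zeros((n_docs, K), dtype=np.float64)
    sum_cooc = np.zeros((N, N), dtype=np.float64)
    n_retained = 0
    vbeta = V * beta

    for sweep in range(n_iter):
        for i in range(N):
            d = doc_of[i]
            w = words[i]
            t_old = z[i]
            n_dt[d, t_old] -= 1
            n_tw[t_old, w] -= 1
            n_t[t_old] -= 1
            total = 0.0
            for t in range(K):
                total += (n_dt[d, t] + alpha) * (n_tw[t, w] + beta) \
                    / (n_t[t] + vbeta)
                p[t] = total
            u, state = _next_u01(state)
            target = u * total
            t_new = 0
            while t_new < K - 1 and p[t_new] <= target:
                t_new += 1
            z[i] = t_new
            n_dt[d, t_new] += 1
            n_tw[t_new, w] += 1
            n_t[t_new] += 1

        if sweep >= burn_in:
            n_retained += 1
            sum_ndt += n_dt
            for i in range(N):
                for j in range(N):
                    if z[i] == z[j]:
                        sum_cooc[i, j] += 1.0

    return z, sum_ndt, sum_cooc, n_retained
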