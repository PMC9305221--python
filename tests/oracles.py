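"""Independent brute-force oracles, deliberately written as plain loops.

These re-derive WNODF, Barber modularity and the best-partition search from
their definitions without sharing any code with the package, so agreement
is a genuine cross-check.
"""

import numpy as np


def wnodf_oracle(W):
    """WNODF (0-100) by direct enumeration of row and column pairs."""
    W = np.asarray(W, dtype=float)

    def guild(M):
        n = M.shape[0]
        total = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if M[i].sum() > M[j].sum():  # i is the richer species
                    occupied = [c for c in range(M.shape[1]) if M[j, c] > 0]
                    less = [c for c in occupied if M[j, c] < M[i, c]]
                    total += 100.0 * len(less) / len(occupied)
        return total, n * (n - 1) // 2

    rs, rp = guild(W)
    cs, cp = guild(W.T)
    return (rs + cs) / (rp + cp)


def barber_q_oracle(W, g, h):
    """Barber bipartite modularity by the definitional double sum."""
    W = np.asarray(W, dtype=float)
    F = W.sum()
    k = W.sum(axis=1)
    d = W.sum(axis=0)
    q = 0.0
    for i in range(W.shape[0]):
        for j in range(W.shape[1]):
            if g[i] == h[j]:
                q += W[i, j] - k[i] * d[j] / F
    return q / F


def set_partitions(n):
    """All set partitions of range(n) as restricted-growth label strings."""

    def rec(prefix, maxi):
        if len(prefix) == n:
            yield prefix
            return
        for v in range(maxi + 2):
            yield from rec(prefix + [v], max(maxi, v))

    yield from rec([], -1)


def exhaustive_best_q(W):
    """Max Barber Q over every joint partition of the R+C nodes."""
    W = np.asarray(W, dtype=float)
    R, C = W.shape
    F = W.sum()
    B = W - np.outer(W.sum(axis=1), W.sum(axis=0)) / F
    best = -np.inf
    for labels in set_partitions(R + C):
        g = np.asarray(labels[:R])
        h = np.asarray(labels[R:])
        q = (B * (g[:, None] == h[None, :])).sum() / F
        best = max(best, q)
    return best
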