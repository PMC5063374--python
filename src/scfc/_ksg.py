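"""Compiled core of the Kraskov k-nearest-neighbor information estimator.

Brute-force max-norm neighbor search; sample counts are a few thousand at
most, where the quadratic scan beats tree construction and keeps memory
O(n).  Ties are resolved deterministically by the partial sort; no jitter
is added.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def ksg_counts(data: np.ndarray, k: int) -> np.ndarray:
    """Per-point marginal neighbor counts for KSG algorithm 1.

    ``data`` is (d, n).  For each point i, ``eps_i`` is the max-norm distance
    to its k-th nearest neighbor in the joint space; the returned
    ``counts[i, a]`` is the number of points j != i with
    ``|data[a, j] - data[a, i]| < eps_i``.
    """
    d, n = data.shape
    counts = np.zeros((n, d), dtype=np.int64)
    dist = np.empty(n)
    for i in range(n):
        for j in range(n):
            m = 0.0
            for a in range(d):
                v = abs(data[a, j] - data[a, i])
                if v > m:
                    m = v
            dist[j] = m
        dist[i] = np.inf
        eps = np.partition(dist, k - 1)[k - 1]
        for a in range(d):
            c = 0
            for j in range(n):
                if j != i and abs(data[a, j] - data[a, i]) < eps:
                    c += 1
            counts[i, a] = c
    return counts
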