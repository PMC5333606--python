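"""Numba kernel for the Information Content merge procedure.

Greedy agglomeration: while more than one node remains, every candidate pair
(u, v) is scored by the information needed to encode where their connection
patterns disagree,

    loss(u, v) = m * H2(d / m),   m = (#remaining nodes) - 2,

where d counts the remaining nodes (other than u and v themselves) whose
links to u and to v differ, and H2 is the binary entropy in bits. The
minimum-loss pair is merged (ties: lexicographically smallest index pair);
the merged node keeps the union of the two link sets. The returned IC is
the accumulated loss over all merges.

Complexity O(n^3): pairwise disagreement counts are maintained incrementally
rather than recomputed from the adjacency matrix, and a histogram of the
counts locates each step's minimum loss so the pair scan can stop at the
first pair achieving it (the same pair a full lexicographic argmin scan
would select).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _binary_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -(p * np.log2(p) + (1.0 - p) * np.log2(1.0 - p))


@njit(cache=True)
def ic_kernel_with_hamming(A: np.ndarray, H: np.ndarray) -> float:
    """IC given the initial row hamming-distance matrix (both are mutated).

    ``H[u, v]`` must equal the number of positions t where rows u and v of
    ``A`` differ (the caller can get it cheaply as ``A@(1-A)^T + (1-A)@A^T``).
    ``d = H[u, v] - 2*A[u, v]`` is then the disagreement count over the
    *other* nodes, because the diagonal of ``A`` is zero.
    """
    n = A.shape[0]
    if n <= 2:
        return 0.0
    alive = np.ones(n, np.uint8)
    idx = np.empty(n, np.int64)
    losses = np.empty(n - 1, np.float64)
    hist = np.zeros(n + 1, np.int64)  # pairs per disagreement count d
    for u in range(n):
        for v in range(u + 1, n):
            hist[H[u, v] - 2 * A[u, v]] += 1
    m = n
    total = 0.0
    while m > 2:
        mm = m - 2
        for d in range(mm + 1):
            losses[d] = mm * _binary_entropy(d / mm)
        j = 0
        for u in range(n):
            if alive[u]:
                idx[j] = u
                j += 1
        best = np.inf
        for d in range(mm + 1):
            if hist[d] > 0 and losses[d] < best:
                best = losses[d]
        # first pair (lexicographic) whose loss equals the minimum — the
        # same pair a full argmin scan with `<` would keep
        bu = -1
        bv = -1
        done = False
        for i in range(m):
            u = idx[i]
            for k in range(i + 1, m):
                v = idx[k]
                if losses[H[u, v] - 2 * A[u, v]] == best:
                    bu = u
                    bv = v
                    done = True
                    break
            if done:
                break
        total += best
        # Merge bv into bu: union pattern. Positions change for everyone:
        # column bv disappears, column bu becomes (old bu OR old bv).
        # Each survivor's relation to the merge is a 2-bit code
        # (link-to-bu, link-to-bv); the hamming delta of a pair depends
        # only on the two codes, via a 4x4 table.
        code = np.empty(m, np.int64)
        for i in range(m):
            a = idx[i]
            code[i] = 2 * A[a, bu] + A[a, bv]
        delta = np.empty((4, 4), np.int64)
        for ca in range(4):
            for cb in range(4):
                d0 = -1 if (ca >> 1) != (cb >> 1) else 0
                d1 = -1 if (ca & 1) != (cb & 1) else 0
                d2 = 1 if (ca != 0) != (cb != 0) else 0
                delta[ca, cb] = d0 + d1 + d2
        for i in range(m):
            a = idx[i]
            if a == bu or a == bv:
                continue
            ca = code[i]
            for k in range(i + 1, m):
                b = idx[k]
                if b == bu or b == bv:
                    continue
                dd = delta[ca, code[k]]
                if dd != 0:
                    h = H[a, b]
                    aab = 2 * A[a, b]
                    hist[h - aab] -= 1
                    hist[h + dd - aab] += 1
                    H[a, b] = h + dd
                    H[b, a] = h + dd
        # drop all pairs that involved bu or bv from the histogram
        for i in range(m):
            a = idx[i]
            if a == bu or a == bv:
                continue
            hist[H[a, bu] - 2 * A[a, bu]] -= 1
            hist[H[a, bv] - 2 * A[a, bv]] -= 1
        hist[H[bu, bv] - 2 * A[bu, bv]] -= 1
        alive[bv] = 0
        m -= 1
        j = 0
        for u in range(n):
            if alive[u]:
                idx[j] = u
                j += 1
        # new row/column bu = union of old bu, bv links (no self loop)
        for i in range(m):
            t = idx[i]
            if t != bu:
                val = 1 if (A[bu, t] or A[bv, t]) else 0
                A[bu, t] = val
                A[t, bu] = val
        A[bu, bu] = 0
        # recompute H for pairs involving the merged node; re-add to hist
        for i in range(m):
            b = idx[i]
            if b == bu:
                continue
            h = 0
            for k in range(m):
                t = idx[k]
                if A[bu, t] != A[b, t]:
                    h += 1
            H[bu, b] = h
            H[b, bu] = h
            hist[h - 2 * A[bu, b]] += 1
    return total


def initial_hamming(A: np.ndarray) -> np.ndarray:
    """Row hamming-distance matrix of a 0/1 matrix via two BLAS matmuls."""
    F = A.astype(np.float32)
    G = 1.0 - F
    return np.ascontiguousarray((F @ G.T + G @ F.T), dtype=np.int64)


def ic_kernel(A: np.ndarray) -> float:
    """Information Content (bits) of a simple undirected graph.

    Parameters
    ----------
    A : (n, n) uint8 symmetric adjacency matrix, zero diagonal, n >= 1.
    """
    A = np.ascontiguousarray(A, dtype=np.uint8)
    return float(ic_kernel_with_hamming(A.copy(), initial_hamming(A)))
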