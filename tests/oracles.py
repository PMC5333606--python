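"""Independent brute-force re-derivations used as test oracles.

Deliberately written from first principles (explicit normal equations,
per-step pattern recomputation, python sets) with no code shared with the
package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def ols_pair_oracle(x, y):
    """(alpha, beta, sigma) for y ~ alpha + beta*x via the normal equations.

    sigma is the sample standard deviation (ddof=1) of the residuals.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        return float(y.mean()), 0.0, float(np.std(y, ddof=1))
    beta = float(np.sum((x - x.mean()) * (y - y.mean()))) / sxx
    alpha = float(y.mean()) - beta * float(x.mean())
    resid = y - (alpha + beta * x)
    sigma = math.sqrt(float(np.sum(resid ** 2)) / (n - 1))
    return alpha, beta, sigma


def network_weights_oracle(subject, controls, sigma_tol=1e-8, var_tol=1e-12):
    """Per-pair Z-score weights for one subject, all pairs k < l.

    ``controls`` is an (n, p) array; ``subject`` a length-p vector.
    Returns a dict {(k, l): w}; degenerate pairs map to 0.
    """
    controls = np.asarray(controls, dtype=float)
    subject = np.asarray(subject, dtype=float)
    p = controls.shape[1]
    out = {}
    for k in range(p):
        for l in range(k + 1, p):
            x, y = controls[:, k], controls[:, l]
            if np.var(x, ddof=1) < var_tol:
                out[(k, l)] = 0.0
                continue
            alpha, beta, sigma = ols_pair_oracle(x, y)
            if sigma < sigma_tol:
                out[(k, l)] = 0.0
            else:
                out[(k, l)] = (subject[l] - (alpha + beta * subject[k])) / sigma
    return out


def _h2(p):
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))


def ic_oracle(adjacency):
    """Information Content by straightforward merging with python sets.

    Same decided rule as the implementation: cost m*H2(d/m) over the other
    remaining nodes, greedy minimum, lexicographic tie-break, union merge.
    """
    A = np.asarray(adjacency)
    n = A.shape[0]
    links = {u: {v for v in range(n) if A[u, v] and v != u} for u in range(n)}
    nodes = sorted(links)
    total = 0.0
    while len(nodes) > 2:
        m = len(nodes) - 2
        best = None
        for u, v in itertools.combinations(nodes, 2):
            d = sum(1 for t in nodes
                    if t != u and t != v and ((t in links[u]) != (t in links[v])))
            loss = m * _h2(d / m)
            if best is None or loss < best[0]:
                best = (loss, u, v)
        loss, u, v = best
        total += loss
        links[u] = (links[u] | links[v]) - {u, v}
        del links[v]
        nodes.remove(v)
        for t in nodes:
            if t == u:
                continue
            links[t].discard(v)
            if t in links[u]:
                links[t].add(u)
            else:
                links[t].discard(u)
    return total
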