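"""Topological features of binarized deviation networks.

Two scalars summarize each patient's network for classification:

* **link density** — realized links divided by all possible links,
  ``n_f * (n_f - 1) / 2``; high density means many feature pairs deviate
  from the reference relations.
* **Information Content (IC)** — bits of information lost while greedily
  merging the most similar node pairs until one node remains; sensitive to
  mesoscale structure (groups of nodes with similar connection patterns).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._ic import ic_kernel, ic_kernel_with_hamming, initial_hamming
from .networks import ParencliticNetwork, condensed_to_square


def _require_binary(network: ParencliticNetwork) -> None:
    if network.binary is None:
        raise ValueError("network must be binarized first (see binarize())")


def link_density(network: ParencliticNetwork) -> float:
    """Fraction of realized links among all possible node pairs."""
    _require_binary(network)
    if network.n_nodes < 2:
        raise ValueError("link density needs at least 2 nodes")
    return float(network.binary.sum()) / len(network.binary)


def information_content(network: ParencliticNetwork) -> float:
    """IC (bits) of the binarized network; permutation invariant."""
    _require_binary(network)
    return ic_from_adjacency(network.adjacency_matrix())


_WL_HASH = np.random.default_rng(0x5EED).integers(
    1, 2 ** 62, size=4096, dtype=np.int64)  # fixed content-based colour keys


def _wl_ranks(A: np.ndarray) -> np.ndarray:
    """Iterated colour refinement: invariant node ranks (may have ties).

    Each round a node's signature is (own rank, sum of fixed pseudo-random
    keys of its neighbours' ranks) — an order-free multiset digest. Ranks
    are assigned by sorting signatures by content, so the result depends
    only on graph structure, never on the input labelling; a (vanishingly
    unlikely) digest collision merely coarsens the refinement, which the
    caller detects and resolves exactly.
    """
    n = A.shape[0]
    Af = A.astype(np.int64)
    ranks = np.unique(A.sum(axis=1), return_inverse=True)[1]
    for _ in range(n):
        digest = Af @ _WL_HASH[ranks % len(_WL_HASH)]
        order = np.lexsort((digest, ranks))
        boundary = np.empty(n, dtype=bool)
        boundary[0] = False
        boundary[1:] = (np.diff(ranks[order]) != 0) | (np.diff(digest[order]) != 0)
        new = np.empty(n, dtype=np.int64)
        new[order] = np.cumsum(boundary)
        n_colors = new.max() + 1
        if np.array_equal(new, ranks) or n_colors == n:
            return new
        ranks = new
    return ranks


def canonical_adjacency(A: np.ndarray) -> np.ndarray:
    """Canonical (isomorphism-invariant) relabeling of an adjacency matrix.

    Node order comes from colour refinement when it individualizes every
    node (the typical case for the dense irregular graphs this pipeline
    produces); otherwise from BLISS canonical labelling (igraph). Either
    way any two isomorphic graphs map to the same matrix, so merge order
    and tie-breaking in the IC computation depend only on graph structure.
    """
    n = A.shape[0]
    if n <= 2:
        return A
    ranks = _wl_ranks(A)
    n_colors = int(ranks.max()) + 1
    if n_colors == n:
        order = np.argsort(ranks)
        return A[np.ix_(order, order)]
    # Colour refinement cannot split *twins* — nodes whose connection
    # patterns agree everywhere outside the class. Swapping twins leaves
    # the adjacency matrix literally unchanged, so if every unresolved
    # class is a twin set, any within-class order yields the same matrix
    # and the WL order is already canonical.
    if n_colors < n:
        all_twins = True
        counts = np.bincount(ranks, minlength=n_colors)
        for color in np.nonzero(counts > 1)[0]:
            cls = np.nonzero(ranks == color)[0]
            outside = np.setdiff1d(np.arange(n), cls, assume_unique=True)
            B = A[np.ix_(cls, outside)]
            if not (B == B[0]).all():
                all_twins = False
                break
            S = A[np.ix_(cls, cls)]
            off = S[~np.eye(len(cls), dtype=bool)]
            if off.size and not (off == off[0]).all():
                all_twins = False
                break
        if all_twins:
            order = np.argsort(ranks, kind="stable")
            return A[np.ix_(order, order)]
    import igraph as ig

    rows, cols = np.nonzero(np.triu(A, 1))
    g = ig.Graph(n=n, edges=list(zip(rows.tolist(), cols.tolist())))
    perm = np.asarray(g.canonical_permutation(), dtype=int)  # old -> new index
    inv = np.argsort(perm)
    return A[np.ix_(inv, inv)]


def ic_from_adjacency(A: np.ndarray) -> float:
    """IC of a simple undirected graph given as an adjacency matrix.

    The merge cost of a candidate pair is ``m * H2(d / m)`` with ``m`` the
    number of other remaining nodes and ``d`` of them connected to exactly
    one of the pair; the minimum-cost pair is merged into a node carrying
    the union of both link sets, and the costs accumulate until a single
    node remains. Ties are broken by the lowest index pair *in a canonical
    labeling* of the graph, so the value is a true graph invariant.
    Complete graphs and stars score 0; graphs of fewer than 3 nodes score 0
    by convention.
    """
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency matrix must be square")
    if A.shape[0] == 0:
        raise ValueError("empty node set has no Information Content")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency matrix must be symmetric")
    A = (A != 0).astype(np.uint8)
    np.fill_diagonal(A, 0)
    return float(ic_kernel(canonical_adjacency(A)))


def featurize(networks: list[ParencliticNetwork]) -> pd.DataFrame:
    """One row per subject: ``subject_id, link_density, information_content``.

    All networks must be binarized and share a node set.
    """
    if not networks:
        return pd.DataFrame(
            columns=["link_density", "information_content"],
            index=pd.Index([], name="subject_id"), dtype=float)
    node_set = networks[0].feature_names
    rows = {}
    for net in networks:
        if net.feature_names != node_set:
            raise ValueError(
                f"network {net.subject_id!r} has a different node set")
        rows[net.subject_id] = (link_density(net), information_content(net))
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=["link_density", "information_content"])
    frame.index.name = "subject_id"
    return frame


def features_from_zscores(W: np.ndarray, degenerate: np.ndarray,
                          n_features: int, threshold: float = 0.5) -> np.ndarray:
    """Vectorized (link_density, IC) per subject from a Z-score matrix.

    ``W`` has shape (n_subjects, n_pairs) in condensed pair order; degenerate
    pairs never form links. Fast path used by the cross-validation loop;
    agrees with binarize + link_density + information_content per network.
    """
    links = (np.abs(W) > threshold) & ~degenerate
    density = links.sum(axis=1) / W.shape[1]
    ic = np.empty(W.shape[0])
    for i in range(W.shape[0]):
        A = condensed_to_square(links[i].astype(np.uint8), n_features)
        B = np.ascontiguousarray(canonical_adjacency(A))
        ic[i] = ic_kernel_with_hamming(B, initial_hamming(B))
    return np.column_stack([density, ic])
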