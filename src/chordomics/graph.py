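"""k-nearest-neighbour / shared-nearest-neighbour graphs and Louvain
community detection, shared by segment-level and pixel-level clustering."""

from __future__ import annotations

import random
import warnings

import igraph as ig
import numpy as np
from sklearn.neighbors import NearestNeighbors


def knn_indices(X: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest neighbours (excluding self) per row."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < number of observations ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    return idx[:, 1:]


def snn_graph(X: np.ndarray, k: int) -> ig.Graph:
    """Shared-nearest-neighbour graph with Jaccard edge weights.

    Two observations are connected if either is among the other's k nearest
    neighbours; the edge weight is the Jaccard overlap of their augmented
    neighbourhoods (self included), as in the usual SNN construction for
    expression data.  Zero-overlap edges are pruned.
    """
    idx = knn_indices(X, k)
    n = idx.shape[0]
    neigh = [set(row) | {i} for i, row in enumerate(idx)]
    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j <= i and i in neigh[j]:
                continue  # already added (or will be) from the other side
            inter = len(neigh[i] & neigh[j])
            union = len(neigh[i] | neigh[j])
            w = inter / union
            if w > 0:
                edges.append((min(i, j), max(i, j)))
                weights.append(w)
    # deduplicate mutual edges
    seen = {}
    for e, w in zip(edges, weights):
        seen[e] = w
    g = ig.Graph(n=n, edges=list(seen.keys()))
    g.es["weight"] = list(seen.values())
    return g


def louvain(graph: ig.Graph, resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Louvain (multilevel) community membership at a given resolution."""
    ig.set_random_number_generator(random.Random(seed))
    part = graph.community_multilevel(
        weights=graph.es["weight"] if "weight" in graph.es.attributes() else None,
        resolution=resolution,
    )
    return np.asarray(part.membership)


def louvain_fixed_k(
    graph: ig.Graph,
    k_target: int,
    seed: int = 0,
    max_iter: int = 60,
    resolution_bounds: tuple[float, float] = (1e-4, 50.0),
) -> tuple[np.ndarray, float]:
    """Binary-search the Louvain resolution until exactly ``k_target``
    communities are found.

    Returns (membership, resolution).  Raises RuntimeError with the achieved
    community counts if the search fails.
    """
    lo, hi = resolution_bounds
    achieved = []
    for it in range(max_iter):
        res = np.sqrt(lo * hi) if it > 0 else 1.0
        member = louvain(graph, resolution=res, seed=seed)
        n_comm = len(np.unique(member))
        achieved.append((res, n_comm))
        if n_comm == k_target:
            return member, res
        if n_comm < k_target:
            lo = res
        else:
            hi = res
        if hi / lo < 1 + 1e-9:
            break
    raise RuntimeError(
        f"could not reach exactly {k_target} communities; "
        f"tried (resolution, count): {achieved[-6:]}"
    )
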