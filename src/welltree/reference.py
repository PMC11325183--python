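"""Naive reference DBSCAN for verification.

A deliberately simple, algorithmically independent implementation used to
cross-check the production clustering in :mod:`welltree.tree`: it builds
the full pairwise distance matrix, thresholds it into an ε-neighborhood
graph, and takes connected components of the core-core subgraph with
:func:`scipy.sparse.csgraph.connected_components`.  Border points follow
the same documented convention as the production code (lowest-index core
neighbor), and clusters are renumbered in order of their lowest-index core
point, so on identical input the two routes must agree exactly.

O(n²) memory and time — fine for verification sizes (n ≤ a few thousand),
not for production use.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .tree import NOISE, ClusterLevel

__all__ = ["brute_force_dbscan"]


def brute_force_dbscan(points: np.ndarray, eps: float, minpts: int) -> ClusterLevel:
    """Distance-matrix DBSCAN: neighborhood graph + connected components."""
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x.reshape(-1, 1)
    n = x.shape[0]
    if n == 0:
        return ClusterLevel(eps=eps, assignment=np.empty(0, dtype=int),
                            n_clusters=0)
    dist = cdist(x, x)
    adjacency = dist <= eps  # includes the self-loop (distance 0)
    core = adjacency.sum(axis=1) >= minpts
    labels = np.full(n, NOISE, dtype=int)
    core_idx = np.flatnonzero(core)
    if core_idx.size:
        sub = csr_matrix(adjacency[np.ix_(core_idx, core_idx)])
        n_comp, comp = connected_components(sub, directed=False)
        # renumber components by their lowest core frame index
        order = {}
        for pos, c in enumerate(comp):
            if c not in order:
                order[c] = len(order)
        labels[core_idx] = [order[c] for c in comp]
        n_clusters = n_comp
    else:
        n_clusters = 0
    for i in np.flatnonzero(~core):
        core_nb = core_idx[adjacency[i, core_idx]]
        if core_nb.size:
            labels[i] = labels[core_nb.min()]
    return ClusterLevel(eps=eps, assignment=labels, n_clusters=n_clusters)
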