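"""Global semantic hypergraph via k nearest neighbours in feature space.

Each ROI's feature vector is its row of the FC matrix.  For every focal
ROI i a hyperedge is formed from i plus the k other ROIs whose feature
rows are closest in Euclidean distance, so hyperedges overlap freely
and may connect spatially distant but functionally similar regions.
"""
from __future__ import annotations

import numpy as np

from .fc import FCMatrix
from .hypergraph import Hypergraph, build_incidence

__all__ = ["knn_hyperedges"]


def knn_hyperedges(fc: FCMatrix, k: int = 5) -> Hypergraph:
    """One hyperedge of size k+1 per focal ROI.

    Distance ties are broken toward the smaller vertex id so the
    construction is deterministic.  Identical vertex sets arising from
    different focal nodes are kept as separate columns.
    """
    x = fc.features()
    n = x.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must satisfy 1 <= k <= N-1 = {n - 1}, got {k}")
    # squared Euclidean distances between feature rows
    sq = np.sum(x * x, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.clip(d2, 0.0, None, out=d2)
    np.fill_diagonal(d2, np.inf)  # self-exclusion before taking k neighbours
    ids = np.arange(n)
    edges = []
    for i in range(n):
        order = np.lexsort((ids, d2[i]))  # distance, then vertex id
        edges.append([i, *order[:k].tolist()])
    return build_incidence(n, edges, provenance="global")
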