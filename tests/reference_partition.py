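"""Straight-line reference implementation of the local decomposition.

Written independently of the package internals (networkx graphs,
dictionary bookkeeping, brute-force pair enumeration) so it can serve
as an oracle for the production implementation: threshold the FC
matrix, pick top-degree centres, assign vertices by hop distance,
then recursively bipartition with the summed-average-degree
acceptance rule.  Returns the leaf vertex groups sorted by smallest
member.
"""
import itertools
import math

import networkx as nx
import numpy as np


def reference_partition(fc_values, t, d_max, n_centers=None):
    n = fc_values.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if abs(fc_values[i, j]) >= t:
                g.add_edge(i, j)
    if n < 4:
        return [tuple(range(n))]

    s = n_centers if n_centers is not None else math.ceil(math.sqrt(n))
    s = min(max(s, 1), n)
    deg = dict(g.degree())
    centers = sorted(range(n), key=lambda v: (-deg[v], v))[:s]

    dists = {c: nx.single_source_shortest_path_length(g, c) for c in centers}
    assign = {}
    for v in range(n):
        best = None
        for ci, c in enumerate(centers):
            if v in dists[c]:
                d = dists[c][v]
                if best is None or d < best[0]:
                    best = (d, ci)
        if best is not None:
            assign[v] = best[1]
        else:  # unreachable from every centre: nearest FC feature row
            gaps = [float(np.linalg.norm(fc_values[c] - fc_values[v])) for c in centers]
            assign[v] = int(np.argmin(gaps))
    for ci, c in enumerate(centers):
        assign[c] = ci
    groups = [
        sorted(v for v in range(n) if assign[v] == ci) for ci in range(len(centers))
    ]

    def avg_deg(sub):
        h = g.subgraph(sub)
        return 2.0 * h.number_of_edges() / len(sub)

    leaves = []

    def split(sub, depth):
        if len(sub) <= 3:
            leaves.append(tuple(sorted(sub)))
            return
        if depth >= d_max:
            leaves.append(tuple(sorted(sub)))
            return
        h = g.subgraph(sub)
        hop = dict(nx.all_pairs_shortest_path_length(h))
        degs = dict(h.degree())
        best = None
        for x, y in itertools.combinations(sorted(sub), 2):
            if hop[x].get(y, math.inf) <= 2:
                continue
            key = (tuple(sorted((degs[x], degs[y]), reverse=True)), (-x, -y))
            if best is None or key > best[0]:
                best = (key, (x, y))
        if best is None:
            leaves.append(tuple(sorted(sub)))
            return
        x, y = best[1]
        if (degs[y], -y) > (degs[x], -x):
            x, y = y, x
        du, dv = hop[x], hop[y]
        right = [v for v in sub if dv.get(v, math.inf) < du.get(v, math.inf)]
        left = [v for v in sub if v not in right]
        if avg_deg(left) + avg_deg(right) > avg_deg(sub):
            split(left, depth + 1)
            split(right, depth + 1)
        else:
            leaves.append(tuple(sorted(sub)))

    for grp in groups:
        split(grp, 0)
    leaves.sort(key=lambda e: e[0])
    return leaves
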