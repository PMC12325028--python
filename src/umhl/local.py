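"""Granularity-adaptive local hypergraph construction.

The FC matrix is thresholded into a binary graph, high-degree nodes
seed an initial set of subnetworks via shortest-path assignment, and
each subnetwork is then recursively bipartitioned by a two-seed
multi-source BFS.  A split is accepted only when the summed average
degree (2|E|/|V|, a topological connection-strength measure) of the two
children exceeds the parent's, which keeps densely connected groups
intact while carving loosely coupled ones apart.  The final leaves,
which always partition the vertex set, become the hyperedges of the
local view.

All tie-breaks (degree sorting, centre assignment, BFS fronts, seed
pairs) resolve by ascending vertex id, making the whole construction
deterministic.
"""
from __future__ import annotations

import json
import math
import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fc import FCMatrix
from .hypergraph import Hypergraph, build_incidence

__all__ = [
    "BinaryAdjacency",
    "Subnetwork",
    "PartitionTree",
    "threshold_adjacency",
    "select_centers",
    "assign_to_centers",
    "choose_split_seeds",
    "bipartition_bfs",
    "average_degree",
    "recursive_partition",
]

#: a subnetwork this small is never split (a split would leave a side
#: at or below the minimum meaningful size of 2)
MIN_SPLIT_SIZE = 4
#: default recursion depth cap
DEFAULT_D_MAX = 4
#: default absolute-correlation threshold for the binary adjacency
DEFAULT_THRESHOLD = 0.3

STOP_REASONS = ("strength", "size", "depth", "no_seed_pair")


@dataclass
class BinaryAdjacency:
    """Symmetric 0/1 adjacency with zero diagonal, from thresholding FC."""

    values: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(v, v.T):
            raise ValueError("adjacency must be symmetric")
        if np.diag(v).any():
            raise ValueError("adjacency must have zero diagonal")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        self.values = v.astype(np.int8)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def degrees(self) -> np.ndarray:
        return self.values.sum(axis=1).astype(int)

    def neighbors(self, v: int) -> np.ndarray:
        return np.flatnonzero(self.values[v])


@dataclass
class Subnetwork:
    """A vertex group with its induced edges in the binary graph."""

    vertex_ids: tuple[int, ...]
    internal_edges: frozenset[tuple[int, int]]
    center: int
    depth: int = 0

    def __post_init__(self) -> None:
        self.vertex_ids = tuple(sorted(set(self.vertex_ids)))
        vs = set(self.vertex_ids)
        for a, b in self.internal_edges:
            if a not in vs or b not in vs:
                raise ValueError(f"internal edge ({a},{b}) leaves the vertex set")
        if self.center not in vs:
            raise ValueError("center must belong to the subnetwork")

    @property
    def size(self) -> int:
        return len(self.vertex_ids)


@dataclass
class _TreeNode:
    subnetwork: Subnetwork
    children: list["_TreeNode"] = field(default_factory=list)
    stop_reason: str | None = None  # set on leaves only
    seeds: tuple[int, int] | None = None  # split seeds if a split was attempted

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def to_dict(self) -> dict:
        d: dict = {
            "members": list(self.subnetwork.vertex_ids),
            "center": self.subnetwork.center,
            "depth": self.subnetwork.depth,
            "n_internal_edges": len(self.subnetwork.internal_edges),
        }
        if self.seeds is not None:
            d["seeds"] = list(self.seeds)
        if self.is_leaf:
            d["stop_reason"] = self.stop_reason
        else:
            d["children"] = [c.to_dict() for c in self.children]
        return d


@dataclass
class PartitionTree:
    """Record of the recursive decomposition (one tree per initial centre)."""

    roots: list[_TreeNode]
    centers: list[int]
    threshold: float
    d_max: int

    def leaves(self) -> list[_TreeNode]:
        out: list[_TreeNode] = []

        def walk(node: _TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                for c in node.children:
                    walk(c)

        for r in self.roots:
            walk(r)
        # deterministic hyperedge order: by smallest member id
        out.sort(key=lambda nd: nd.subnetwork.vertex_ids[0])
        return out

    def leaf_subnetworks(self) -> list[Subnetwork]:
        return [nd.subnetwork for nd in self.leaves()]

    def to_json(self, path: str | Path) -> None:
        data = {
            "threshold": self.threshold,
            "d_max": self.d_max,
            "centers": self.centers,
            "trees": [r.to_dict() for r in self.roots],
        }
        Path(path).write_text(json.dumps(data, indent=1), encoding="utf-8")


def threshold_adjacency(fc: FCMatrix, t: float = DEFAULT_THRESHOLD) -> BinaryAdjacency:
    """Binary adjacency: edge (i, j) iff i != j and |F(i,j)| >= t.

    The absolute value keeps strong anticorrelations as edges; only the
    magnitude of coupling matters for the topological decomposition.
    """
    if t < 0:
        raise ValueError("threshold must be non-negative")
    a = (np.abs(fc.values) >= t).astype(np.int8)
    np.fill_diagonal(a, 0)
    return BinaryAdjacency(values=a, threshold_used=float(t))


def select_centers(adj: BinaryAdjacency, n_centers: int | None = None) -> list[int]:
    """Top-S nodes by degree (S = ceil(sqrt(N)) by default).

    Nodes are sorted by degree descending with ties broken by ascending
    vertex id.
    """
    n = adj.n
    if n < 1:
        raise ValueError("graph has no vertices")
    s = int(n_centers) if n_centers is not None else math.ceil(math.sqrt(n))
    s = max(1, min(s, n))
    deg = adj.degrees()
    order = sorted(range(n), key=lambda v: (-deg[v], v))
    return order[:s]


def _bfs_distances(adj: BinaryAdjacency, source: int, allowed: np.ndarray | None = None) -> np.ndarray:
    """Unweighted hop distances from ``source``; np.inf if unreachable.

    ``allowed`` restricts the search to an induced subgraph (boolean
    mask over all vertices).
    """
    n = adj.n
    dist = np.full(n, np.inf)
    if allowed is not None and not allowed[source]:
        return dist
    dist[source] = 0.0
    q = deque([source])
    while q:
        u = q.popleft()
        for w in adj.neighbors(u):
            if allowed is not None and not allowed[w]:
                continue
            if np.isinf(dist[w]):
                dist[w] = dist[u] + 1.0
                q.append(int(w))
    return dist


def _induced_edges(adj: BinaryAdjacency, vertices: tuple[int, ...]) -> frozenset[tuple[int, int]]:
    vs = list(vertices)
    sub = adj.values[np.ix_(vs, vs)]
    ii, jj = np.nonzero(np.triu(sub, 1))
    return frozenset((vs[a], vs[b]) for a, b in zip(ii.tolist(), jj.tolist()))


def assign_to_centers(
    adj: BinaryAdjacency,
    centers: list[int],
    fc: FCMatrix | None = None,
) -> list[Subnetwork]:
    """Assign every vertex to its hop-closest centre.

    Ties go to the centre appearing earlier in ``centers`` (the
    higher-degree one).  A vertex unreachable from every centre falls
    back to the centre whose FC feature row is closest in Euclidean
    distance; without feature information it goes to the first centre.
    """
    if not centers:
        raise ValueError("need at least one center")
    n = adj.n
    dists = np.stack([_bfs_distances(adj, c) for c in centers])  # (S, N)
    owner = np.argmin(dists, axis=0)  # first minimum = earliest center on ties
    unreachable = np.isinf(dists.min(axis=0))
    if unreachable.any():
        if fc is not None:
            x = fc.features()
            for v in np.flatnonzero(unreachable):
                gaps = np.linalg.norm(x[centers] - x[v], axis=1)
                owner[v] = int(np.argmin(gaps))  # ties -> earlier center
        else:
            owner[unreachable] = 0
    # centers always own themselves
    for ci, c in enumerate(centers):
        owner[c] = ci
    subs = []
    for ci, c in enumerate(centers):
        members = tuple(sorted(np.flatnonzero(owner == ci).tolist()))
        subs.append(
            Subnetwork(
                vertex_ids=members,
                internal_edges=_induced_edges(adj, members),
                center=c,
                depth=0,
            )
        )
    return subs


def _subnetwork_degrees(sub: Subnetwork) -> dict[int, int]:
    deg = {v: 0 for v in sub.vertex_ids}
    for a, b in sub.internal_edges:
        deg[a] += 1
        deg[b] += 1
    return deg


def _hop_matrix(sub: Subnetwork) -> dict[int, dict[int, float]]:
    """All-pairs hop distances within the induced subgraph."""
    nbrs: dict[int, list[int]] = {v: [] for v in sub.vertex_ids}
    for a, b in sub.internal_edges:
        nbrs[a].append(b)
        nbrs[b].append(a)
    for v in nbrs:
        nbrs[v].sort()
    out: dict[int, dict[int, float]] = {}
    for s in sub.vertex_ids:
        dist = {v: np.inf for v in sub.vertex_ids}
        dist[s] = 0.0
        q = deque([s])
        while q:
            u = q.popleft()
            for w in nbrs[u]:
                if np.isinf(dist[w]):
                    dist[w] = dist[u] + 1.0
                    q.append(w)
        out[s] = dist
    return out


def choose_split_seeds(sub: Subnetwork) -> tuple[int, int] | None:
    """Highest-degree seed pair with hop distance > 2, or None.

    Among all vertex pairs whose hop distance within the induced
    subgraph exceeds 2 (disconnected pairs qualify), the pair whose
    sorted-descending degree pair is lexicographically largest wins;
    remaining ties go to the smallest (min id, max id) pair.  The
    returned pair is ordered higher-degree first (ties: smaller id
    first), which also fixes the preferred side in the subsequent BFS.
    """
    if sub.size < MIN_SPLIT_SIZE:
        return None
    deg = _subnetwork_degrees(sub)
    hops = _hop_matrix(sub)
    best_key: tuple | None = None
    best_pair: tuple[int, int] | None = None
    verts = sub.vertex_ids
    for i, x in enumerate(verts):
        for y in verts[i + 1 :]:
            if hops[x][y] <= 2:
                continue
            dpair = tuple(sorted((deg[x], deg[y]), reverse=True))
            key = (dpair, (-x, -y))  # maximize degrees, then smallest ids
            if best_key is None or key > best_key:
                best_key = key
                best_pair = (x, y)
    if best_pair is None:
        return None
    x, y = best_pair
    if (deg[y], -y) > (deg[x], -x):
        x, y = y, x
    return (x, y)


def bipartition_bfs(sub: Subnetwork, u: int, v: int) -> tuple[Subnetwork, Subnetwork]:
    """Two-seed multi-source BFS split of a subnetwork.

    Each vertex joins the seed whose BFS front reaches it first; equal
    distances and vertices unreachable from both seeds go to u's side.
    """
    if u == v or u not in sub.vertex_ids or v not in sub.vertex_ids:
        raise ValueError("seeds must be two distinct members of the subnetwork")
    hops = _hop_matrix(sub)
    du, dv = hops[u], hops[v]
    left, right = [], []
    for w in sub.vertex_ids:
        if dv[w] < du[w]:
            right.append(w)
        else:  # closer to u, tie, or unreachable from both
            left.append(w)
    vs_l, vs_r = tuple(left), tuple(right)
    set_l, set_r = set(vs_l), set(vs_r)
    edges_l = frozenset(e for e in sub.internal_edges if e[0] in set_l and e[1] in set_l)
    edges_r = frozenset(e for e in sub.internal_edges if e[0] in set_r and e[1] in set_r)
    return (
        Subnetwork(vertex_ids=vs_l, internal_edges=edges_l, center=u, depth=sub.depth + 1),
        Subnetwork(vertex_ids=vs_r, internal_edges=edges_r, center=v, depth=sub.depth + 1),
    )


def average_degree(sub: Subnetwork) -> float:
    """Topological connection strength 2|E| / |V| of a subnetwork."""
    if sub.size == 0:
        raise ValueError("empty subnetwork")
    return 2.0 * len(sub.internal_edges) / sub.size


def recursive_partition(
    fc: FCMatrix,
    t: float = DEFAULT_THRESHOLD,
    d_max: int = DEFAULT_D_MAX,
    n_centers: int | None = None,
) -> tuple[Hypergraph, PartitionTree]:
    """Full granularity-adaptive decomposition of one FC matrix.

    Pipeline: threshold -> centre selection -> shortest-path assignment
    (depth 0) -> recursive two-seed BFS bipartition.  A split is kept
    only when the children's summed average degree strictly exceeds the
    parent's; leaves are further forced by small size (<= 3 vertices),
    the depth cap, or absence of a hop>2 seed pair.  Leaves become the
    hyperedges of the local view, ordered by smallest member id.
    """
    if d_max < 1:
        raise ValueError("d_max must be at least 1")
    n = fc.n_rois
    adj = threshold_adjacency(fc, t)
    if n < MIN_SPLIT_SIZE:
        warnings.warn(
            f"only {n} ROIs: local view degenerates to a single hyperedge",
            RuntimeWarning,
            stacklevel=2,
        )
        whole = Subnetwork(
            vertex_ids=tuple(range(n)),
            internal_edges=_induced_edges(adj, tuple(range(n))),
            center=0,
        )
        node = _TreeNode(subnetwork=whole, stop_reason="size")
        tree = PartitionTree(roots=[node], centers=[0], threshold=float(t), d_max=d_max)
        hg = build_incidence(n, [whole.vertex_ids], provenance="local")
        return hg, tree

    centers = select_centers(adj, n_centers)
    initial = assign_to_centers(adj, centers, fc=fc)

    def grow(sub: Subnetwork) -> _TreeNode:
        node = _TreeNode(subnetwork=sub)
        if sub.size <= MIN_SPLIT_SIZE - 1:
            node.stop_reason = "size"
            return node
        if sub.depth >= d_max:
            node.stop_reason = "depth"
            return node
        seeds = choose_split_seeds(sub)
        if seeds is None:
            node.stop_reason = "no_seed_pair"
            return node
        node.seeds = seeds
        g_l, g_r = bipartition_bfs(sub, *seeds)
        if average_degree(g_l) + average_degree(g_r) > average_degree(sub):
            node.children = [grow(g_l), grow(g_r)]
        else:
            node.stop_reason = "strength"
        return node

    roots = [grow(s) for s in initial]
    tree = PartitionTree(roots=roots, centers=centers, threshold=float(t), d_max=d_max)
    leaves = tree.leaf_subnetworks()
    hg = build_incidence(n, [s.vertex_ids for s in leaves], provenance="local")
    return hg, tree
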