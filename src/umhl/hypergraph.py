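"""Incidence-matrix hypergraphs.

A hypergraph on a fixed vertex set V is stored as an ordered list of
hyperedges (vertex-id sets) plus optional per-(edge, vertex) weights
w_e(v).  The |V| x |E| incidence matrix has entry (v, e) equal to
w_e(v) when v belongs to e and 0 otherwise.  Because the vertex set is
shared across views, incidence matrices of different constructions can
be fused by simple column concatenation.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Hypergraph",
    "build_incidence",
    "vertex_degrees",
    "hyperedge_degrees",
    "concat_hypergraphs",
    "save_hypergraph",
    "load_hypergraph",
]

PROVENANCE_TAGS = ("prior", "local", "global", "fused", "custom")


@dataclass
class Hypergraph:
    """Vertex set + ordered hyperedge list with incidence-matrix view.

    ``weights`` maps ``(edge_index, vertex_id)`` to w_e(v); missing
    entries default to 1 (the only case the source constructions use).
    """

    n_vertices: int
    hyperedges: list[tuple[int, ...]]
    weights: dict[tuple[int, int], float] = field(default_factory=dict)
    provenance: str = "custom"

    def __post_init__(self) -> None:
        if self.n_vertices < 0:
            raise ValueError("n_vertices must be non-negative")
        if self.provenance not in PROVENANCE_TAGS:
            raise ValueError(
                f"provenance must be one of {PROVENANCE_TAGS}, got {self.provenance!r}"
            )
        edges: list[tuple[int, ...]] = []
        for j, e in enumerate(self.hyperedges):
            members = tuple(sorted(set(int(v) for v in e)))
            if not members:
                raise ValueError(f"hyperedge {j} is empty")
            if members[0] < 0 or members[-1] >= self.n_vertices:
                raise ValueError(
                    f"hyperedge {j} has out-of-range vertex ids {members}"
                )
            edges.append(members)
        self.hyperedges = edges
        for (j, v), w in self.weights.items():
            if j < 0 or j >= len(edges) or v not in edges[j]:
                raise ValueError(f"weight refers to absent membership ({j}, {v})")
            if not np.isfinite(w):
                raise ValueError("vertex-in-edge weights must be finite")

    @property
    def n_edges(self) -> int:
        return len(self.hyperedges)

    def incidence(self) -> np.ndarray:
        """Dense |V| x |E| incidence matrix H with H(v,e) = w_e(v)."""
        h = np.zeros((self.n_vertices, self.n_edges))
        for j, e in enumerate(self.hyperedges):
            for v in e:
                h[v, j] = self.weights.get((j, v), 1.0)
        return h

    def membership(self) -> np.ndarray:
        """Binary membership pattern (weights ignored)."""
        h = np.zeros((self.n_vertices, self.n_edges))
        for j, e in enumerate(self.hyperedges):
            h[list(e), j] = 1.0
        return h


def build_incidence(
    n_vertices: int,
    hyperedges: Iterable[Iterable[int]],
    weights: Mapping[tuple[int, int], float] | None = None,
    provenance: str = "custom",
) -> Hypergraph:
    """Construct a hypergraph (validating members) from hyperedge sets."""
    return Hypergraph(
        n_vertices=int(n_vertices),
        hyperedges=[tuple(e) for e in hyperedges],
        weights=dict(weights) if weights else {},
        provenance=provenance,
    )


def vertex_degrees(hg: Hypergraph) -> np.ndarray:
    """Number of hyperedges each vertex belongs to (binary row sums)."""
    d = np.zeros(hg.n_vertices)
    for e in hg.hyperedges:
        d[list(e)] += 1.0
    return d


def hyperedge_degrees(hg: Hypergraph) -> np.ndarray:
    """Size of each hyperedge (binary column sums)."""
    return np.array([float(len(e)) for e in hg.hyperedges])


def concat_hypergraphs(hgs: Sequence[Hypergraph]) -> Hypergraph:
    """Fuse hypergraphs over the same vertex set by stacking columns."""
    if not hgs:
        raise ValueError("need at least one hypergraph to concatenate")
    n = hgs[0].n_vertices
    for hg in hgs:
        if hg.n_vertices != n:
            raise ValueError(
                f"vertex counts differ: {hg.n_vertices} vs {n}"
            )
    edges: list[tuple[int, ...]] = []
    weights: dict[tuple[int, int], float] = {}
    for hg in hgs:
        offset = len(edges)
        edges.extend(hg.hyperedges)
        for (j, v), w in hg.weights.items():
            weights[(j + offset, v)] = w
    return Hypergraph(n_vertices=n, hyperedges=edges, weights=weights, provenance="fused")


def save_hypergraph(hg: Hypergraph, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    """Export incidence as TSV (rows = vertices) plus a JSON sidecar.

    The sidecar records provenance and explicit member lists so the
    hypergraph round-trips exactly even when weights are non-unit.
    """
    tsv_path = Path(tsv_path)
    cols = [f"e{j}" for j in range(hg.n_edges)]
    idx = [f"v{i}" for i in range(hg.n_vertices)]
    pd.DataFrame(hg.incidence(), index=idx, columns=cols).to_csv(
        tsv_path, sep="\t", float_format="%.17g"
    )
    if json_path is None:
        json_path = tsv_path.with_suffix(".json")
    sidecar = {
        "n_vertices": hg.n_vertices,
        "provenance": hg.provenance,
        "hyperedges": [
            {"id": j, "members": list(e)} for j, e in enumerate(hg.hyperedges)
        ],
        "weights": [
            {"edge": j, "vertex": v, "weight": w} for (j, v), w in sorted(hg.weights.items())
        ],
    }
    Path(json_path).write_text(json.dumps(sidecar, indent=1), encoding="utf-8")


def load_hypergraph(json_path: str | Path) -> Hypergraph:
    """Rebuild a hypergraph from its JSON sidecar."""
    data = json.loads(Path(json_path).read_text(encoding="utf-8"))
    return Hypergraph(
        n_vertices=int(data["n_vertices"]),
        hyperedges=[tuple(e["members"]) for e in data["hyperedges"]],
        weights={(int(w["edge"]), int(w["vertex"])): float(w["weight"]) for w in data.get("weights", [])},
        provenance=data.get("provenance", "custom"),
    )
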