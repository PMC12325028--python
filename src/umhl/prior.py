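"""Knowledge-driven hypergraph: one hyperedge per functional subnetwork.

A parcellation assigns every ROI to exactly one predefined functional
brain subnetwork (the canonical scheme has eight such subnetworks).
Each subnetwork becomes a hyperedge connecting all of its ROIs, so the
resulting hyperedges are pairwise disjoint and cover the vertex set.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .hypergraph import Hypergraph, build_incidence

__all__ = ["Parcellation", "build_prior_hypergraph", "load_parcellation", "save_parcellation"]


@dataclass
class Parcellation:
    """ROI -> subnetwork labelling (a partition of the ROI set).

    ``labels[i]`` is the subnetwork of ``roi_ids[i]``; subnetwork order
    follows first appearance in the ROI ordering.
    """

    roi_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.roi_ids = [str(r) for r in self.roi_ids]
        self.labels = [str(l) for l in self.labels]
        if len(self.roi_ids) != len(self.labels):
            raise ValueError("roi_ids and labels must have equal length")
        if len(set(self.roi_ids)) != len(self.roi_ids):
            dupes = sorted({r for r in self.roi_ids if self.roi_ids.count(r) > 1})
            raise ValueError(f"duplicate ROI ids in parcellation: {dupes[:5]}")
        if not self.roi_ids:
            raise ValueError("parcellation is empty")

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    @property
    def subnet_names(self) -> list[str]:
        """Subnetwork names in order of first appearance."""
        seen: list[str] = []
        for l in self.labels:
            if l not in seen:
                seen.append(l)
        return seen

    @property
    def n_subnets(self) -> int:
        return len(self.subnet_names)

    def members(self, subnet: str) -> list[int]:
        return [i for i, l in enumerate(self.labels) if l == subnet]


def build_prior_hypergraph(parcellation: Parcellation) -> Hypergraph:
    """One hyperedge per subnetwork, ordered by first label appearance."""
    edges = [parcellation.members(s) for s in parcellation.subnet_names]
    return build_incidence(parcellation.n_rois, edges, provenance="prior")


def load_parcellation(path: str | Path) -> Parcellation:
    """Read a TSV with columns ``roi_id`` and ``subnetwork``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"roi_id", "subnetwork"} - set(df.columns)
    if missing:
        raise ValueError(f"parcellation file {path} lacks columns {sorted(missing)}")
    if df["roi_id"].isna().any() or df["subnetwork"].isna().any():
        raise ValueError(f"parcellation file {path} has missing entries")
    return Parcellation(roi_ids=df["roi_id"].tolist(), labels=df["subnetwork"].tolist())


def save_parcellation(parc: Parcellation, path: str | Path) -> None:
    pd.DataFrame({"roi_id": parc.roi_ids, "subnetwork": parc.labels}).to_csv(
        path, sep="\t", index=False
    )
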