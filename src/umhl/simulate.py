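"""Synthetic functional-connectivity cohorts with planted class effects.

Each subject's ROI signals are drawn from a block-structured Gaussian:
ROIs inside the same functional subnetwork correlate at
``within_corr``, ROIs in different subnetworks at ``between_corr``.
For the patient class, ``effect_size`` is added to the within-block
correlation of ``n_affected`` designated subnetworks, so the two
classes differ only by stronger coupling inside known subnetworks —
the kind of localized high-order alteration the classifier is meant to
pick up.  White observation noise (``noise_sd``) and the finite number
of timepoints (``t_points``) give every empirical FC matrix realistic
sampling variability around its population target.

Defaults mirror a CC200-style setting: 200 ROIs in 8 near-equal
subnetworks, 40 subjects per class, 150 timepoints, a 0.25 correlation
shift in 2 affected subnetworks over a 0.30 within / 0.05 between
baseline, and mild observation noise (sd 0.1 against unit signal
variance).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fc import BoldTimeSeries, FCMatrix, compute_fc, load_matrix, save_matrix
from .prior import Parcellation, save_parcellation

__all__ = [
    "SimSpec",
    "CohortDataset",
    "make_parcellation",
    "target_correlation",
    "simulate_subject",
    "make_dataset",
    "load_dataset",
]


@dataclass
class SimSpec:
    """Generator settings for one synthetic cohort."""

    n_rois: int = 200
    n_subnets: int = 8
    n_per_class: int = 40
    effect_size: float = 0.25
    n_affected: int = 2
    within_corr: float = 0.30
    between_corr: float = 0.05
    noise_sd: float = 0.10
    t_points: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < self.n_subnets or self.n_subnets < 1:
            raise ValueError("need n_rois >= n_subnets >= 1")
        if self.n_per_class < 1 or self.t_points < 2:
            raise ValueError("need n_per_class >= 1 and t_points >= 2")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ValueError("effect_size and noise_sd must be non-negative")
        if not 0 <= self.n_affected <= self.n_subnets:
            raise ValueError("n_affected must lie in [0, n_subnets]")
        hi = self.within_corr + self.effect_size
        for r in (self.within_corr, self.between_corr, hi):
            if not -1.0 < r < 1.0:
                raise ValueError(f"correlation target {r} outside (-1, 1)")


@dataclass
class CohortDataset:
    """In-memory cohort: per-subject FC + labels + simulation truth."""

    subjects: list[FCMatrix]
    labels: np.ndarray  # 0 = control, 1 = patient
    parcellation: Parcellation
    affected_subnets: list[str]
    subject_ids: list[str]
    spec: SimSpec | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.subjects) == len(self.labels) == len(self.subject_ids)):
            raise ValueError("subjects, labels and ids must align")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def make_parcellation(spec: SimSpec) -> Parcellation:
    """Contiguous near-equal subnetwork blocks (larger blocks first)."""
    base, extra = divmod(spec.n_rois, spec.n_subnets)
    sizes = [base + (1 if i < extra else 0) for i in range(spec.n_subnets)]
    labels: list[str] = []
    for i, sz in enumerate(sizes):
        labels.extend([f"subnet{i}"] * sz)
    return Parcellation(roi_ids=[f"roi{i}" for i in range(spec.n_rois)], labels=labels)


def _nearest_psd(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped PSD repair, rescaled back to unit diagonal."""
    w, v = np.linalg.eigh(corr)
    if w.min() >= eps:
        return corr
    w = np.clip(w, eps, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def target_correlation(spec: SimSpec, parc: Parcellation, patient: bool) -> np.ndarray:
    """Population correlation matrix of the signal part for one class."""
    n = spec.n_rois
    corr = np.full((n, n), spec.between_corr)
    affected = set(_affected_subnets(spec, parc))
    for name in parc.subnet_names:
        idx = parc.members(name)
        r = spec.within_corr
        if patient and name in affected:
            r = spec.within_corr + spec.effect_size
        corr[np.ix_(idx, idx)] = r
    np.fill_diagonal(corr, 1.0)
    return _nearest_psd(corr)


def _affected_subnets(spec: SimSpec, parc: Parcellation) -> list[str]:
    return parc.subnet_names[: spec.n_affected]


def simulate_subject(spec: SimSpec, label: int, seed: int | np.random.SeedSequence) -> FCMatrix:
    """Draw one subject's signals and return the empirical FC matrix."""
    parc = make_parcellation(spec)
    corr = target_correlation(spec, parc, patient=bool(label))
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr)
    signals = rng.standard_normal((spec.t_points, spec.n_rois)) @ chol.T
    if spec.noise_sd > 0:
        signals = signals + spec.noise_sd * rng.standard_normal(signals.shape)
    bold = BoldTimeSeries(values=signals.T, roi_ids=parc.roi_ids)
    return compute_fc(bold)


def make_dataset(spec: SimSpec, out_dir: str | Path | None = None) -> CohortDataset:
    """Simulate the full two-class cohort; optionally write it to disk.

    The on-disk layout is exactly what the pipeline consumes: one CSV
    matrix per subject, a parcellation TSV, a manifest TSV
    (subject_id, fc_path, label) and a ground-truth JSON naming the
    affected subnetworks.  Outputs are reproducible from the seed.
    """
    parc = make_parcellation(spec)
    root = np.random.SeedSequence(spec.seed)
    n_total = 2 * spec.n_per_class
    children = root.spawn(n_total)
    subjects: list[FCMatrix] = []
    labels: list[int] = []
    ids: list[str] = []
    # controls first, then patients, matching the manifest ordering
    order = [0] * spec.n_per_class + [1] * spec.n_per_class
    for i, label in enumerate(order):
        subjects.append(simulate_subject(spec, label, children[i]))
        labels.append(label)
        ids.append(f"sub{i:03d}")
    ds = CohortDataset(
        subjects=subjects,
        labels=np.array(labels),
        parcellation=parc,
        affected_subnets=_affected_subnets(spec, parc),
        subject_ids=ids,
        spec=spec,
    )
    if out_dir is not None:
        _write_dataset(ds, Path(out_dir))
    return ds


def _write_dataset(ds: CohortDataset, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    mat_dir = out_dir / "matrices"
    mat_dir.mkdir(exist_ok=True)
    rows = []
    for sid, fc, label in zip(ds.subject_ids, ds.subjects, ds.labels):
        path = mat_dir / f"{sid}.csv"
        save_matrix(fc, path)
        rows.append({"subject_id": sid, "fc_path": str(path.relative_to(out_dir)), "label": int(label)})
    pd.DataFrame(rows).to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    save_parcellation(ds.parcellation, out_dir / "parcellation.tsv")
    truth = {
        "affected_subnets": ds.affected_subnets,
        "spec": {k: getattr(ds.spec, k) for k in SimSpec.__dataclass_fields__} if ds.spec else None,
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=1), encoding="utf-8")


def load_dataset(manifest_path: str | Path, parcellation: Parcellation | None = None) -> CohortDataset:
    """Rebuild a cohort from a manifest TSV written by :func:`make_dataset`.

    ``fc_path`` entries are resolved relative to the manifest's folder.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"no such manifest: {manifest_path}")
    df = pd.read_csv(manifest_path, sep="\t")
    missing = {"subject_id", "fc_path", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns {sorted(missing)}")
    base = manifest_path.parent
    subjects = [load_matrix(base / p) for p in df["fc_path"]]
    if parcellation is None:
        parc_path = base / "parcellation.tsv"
        if parc_path.exists():
            from .prior import load_parcellation

            parcellation = load_parcellation(parc_path)
        else:
            raise ValueError("no parcellation supplied and none found next to the manifest")
    truth_path = base / "ground_truth.json"
    affected: list[str] = []
    if truth_path.exists():
        affected = json.loads(truth_path.read_text(encoding="utf-8")).get("affected_subnets", [])
    return CohortDataset(
        subjects=subjects,
        labels=df["label"].to_numpy(dtype=int),
        parcellation=parcellation,
        affected_subnets=affected,
        subject_ids=[str(s) for s in df["subject_id"]],
        spec=None,
    )
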