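"""Functional-connectivity matrices and node features.

A functional-connectivity (FC) matrix is the N x N matrix of Pearson
correlations between the BOLD time series of N regions of interest
(ROIs).  Row ``i`` of the FC matrix doubles as the feature vector of
node ``i`` in every hypergraph view built downstream.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BoldTimeSeries",
    "FCMatrix",
    "FormatError",
    "compute_fc",
    "load_matrix",
    "save_matrix",
    "fisher_z",
]

#: maximum asymmetry tolerated before a supplied matrix is rejected
ASYMMETRY_TOL = 1e-6
#: asymmetry below this is considered exact (numerical round-off)
SYMMETRY_CHECK_TOL = 1e-8


class FormatError(ValueError):
    """Raised when an on-disk matrix does not parse as a valid FC matrix."""


def _default_ids(n: int) -> list[str]:
    return [f"roi{i}" for i in range(n)]


@dataclass
class BoldTimeSeries:
    """Per-subject ROI x time BOLD signal block.

    Parameters
    ----------
    values
        ``(n_rois, n_timepoints)`` array of signal values.
    roi_ids
        Ordered, unique ROI identifiers; defaults to ``roi0..roi{N-1}``.
    """

    values: np.ndarray
    roi_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("BOLD values must be a 2-D (ROI x time) array")
        n, t = self.values.shape
        if t < 2:
            raise ValueError(f"need at least 2 timepoints, got {t}")
        if not np.isfinite(self.values).all():
            raise ValueError("BOLD values contain non-finite entries")
        if self.roi_ids is None:
            self.roi_ids = _default_ids(n)
        self.roi_ids = list(self.roi_ids)
        if len(self.roi_ids) != n:
            raise ValueError("roi_ids length does not match number of rows")
        if len(set(self.roi_ids)) != n:
            raise ValueError("roi_ids must be unique")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class FCMatrix:
    """N x N symmetric Pearson-correlation matrix with unit diagonal.

    Values lie in [-1, 1]; small asymmetries (up to 1e-6) in supplied
    matrices are repaired by averaging with the transpose, anything
    larger is rejected.
    """

    values: np.ndarray
    roi_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        n = v.shape[0]
        if n < 3:
            raise ValueError(f"FC matrix needs at least 3 ROIs, got {n}")
        if not np.isfinite(v).all():
            raise ValueError("FC matrix contains non-finite entries")
        asym = np.abs(v - v.T).max()
        if asym > ASYMMETRY_TOL:
            raise ValueError(f"FC matrix asymmetric beyond tolerance ({asym:.2e})")
        if asym > 0:
            v = (v + v.T) / 2.0
        diag_err = np.abs(np.diag(v) - 1.0).max()
        if diag_err > ASYMMETRY_TOL:
            raise ValueError(f"FC diagonal deviates from 1 by {diag_err:.2e}")
        np.fill_diagonal(v, 1.0)
        if v.min() < -1.0 - 1e-9 or v.max() > 1.0 + 1e-9:
            raise ValueError("FC entries must lie in [-1, 1]")
        self.values = np.clip(v, -1.0, 1.0)
        if self.roi_ids is None:
            self.roi_ids = _default_ids(n)
        self.roi_ids = list(self.roi_ids)
        if len(self.roi_ids) != n or len(set(self.roi_ids)) != n:
            raise ValueError("roi_ids must be unique and match matrix size")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def features(self) -> np.ndarray:
        """Node-feature matrix: row i is node i's feature vector."""
        return self.values


def compute_fc(bold: BoldTimeSeries) -> FCMatrix:
    """Pearson-correlation FC matrix of a BOLD block.

    Zero-variance ROIs have undefined correlations; their off-diagonal
    entries are set to 0 (diagonal stays 1) and a warning is emitted so
    the node set stays fixed for the hypergraph constructions.
    """
    x = bold.values
    sd = x.std(axis=1)
    flat = sd == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    c = np.atleast_2d(np.asarray(c, dtype=float))
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} ROI(s) have zero variance; their correlations are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        c[flat, :] = 0.0
        c[:, flat] = 0.0
    c = np.clip(c, -1.0, 1.0)
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    return FCMatrix(values=c, roi_ids=bold.roi_ids)


def fisher_z(fc: FCMatrix, clip: float = 0.999999) -> np.ndarray:
    """Fisher r-to-z transform of the off-diagonal FC entries.

    Returns a plain feature array (not an :class:`FCMatrix`, whose
    entries are bounded); the diagonal is kept at 1 so self-connectivity
    stays on a comparable scale.
    """
    z = np.arctanh(np.clip(fc.values, -clip, clip))
    np.fill_diagonal(z, 1.0)
    return z


def _sniff_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def save_matrix(m: FCMatrix, path: str | Path) -> None:
    """Write an FC matrix as CSV/TSV with a header row of ROI ids."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.DataFrame(m.values, index=m.roi_ids, columns=m.roi_ids)
    df.to_csv(path, sep=sep, float_format="%.17g")


def load_matrix(path: str | Path) -> FCMatrix:
    """Read a CSV/TSV numeric grid as an FC matrix.

    Accepts either a plain square numeric grid or one with a first
    header row (and optionally first column) of ROI ids.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such matrix file: {path}")
    sep = _sniff_delimiter(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    tokens = [t for t in first.strip().split(sep) if t != ""]

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_is_number(t) for t in tokens)
    try:
        if has_header:
            df = pd.read_csv(path, sep=sep, header=0, index_col=0)
            roi_ids: Sequence[str] | None = [str(c) for c in df.columns]
        else:
            df = pd.read_csv(path, sep=sep, header=None)
            roi_ids = None
        values = df.to_numpy(dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"could not parse numeric grid from {path}: {exc}") from exc
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise FormatError(
            f"matrix in {path} is not square (shape {values.shape})"
        )
    try:
        return FCMatrix(values=values, roi_ids=list(roi_ids) if roi_ids else None)
    except ValueError as exc:
        raise FormatError(f"invalid FC matrix in {path}: {exc}") from exc
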