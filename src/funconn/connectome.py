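"""Association matrices and density-thresholded binary graphs.

A subject's connectome is the matrix of pairwise Pearson correlations
between ROI time series.  Binary graphs are derived by keeping the top-k
strongest correlations so that every subject's graph has the same edge
density — comparisons across subjects then contrast topology, not mean
connectivity strength.  A sweep of densities (default 0.10 to 0.50 in
steps of 0.05) avoids committing to a single threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .prep import RoiTimeSeries

__all__ = [
    "AssociationMatrix",
    "BinaryGraph",
    "DensitySweep",
    "correlation_matrix",
    "binarize_at_density",
    "binarize_at_threshold",
    "group_mean_association",
]


@dataclass
class AssociationMatrix:
    """Symmetric ROI x ROI Pearson correlation matrix for one subject."""

    values: np.ndarray
    roi_labels: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("association matrix must be square")
        if v.shape[0] != len(self.roi_labels):
            raise ValueError("label count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("association matrix must be symmetric")
        v = (v + v.T) / 2.0
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and (off.min() < -1 - 1e-9 or off.max() > 1 + 1e-9):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")
        np.fill_diagonal(v, 1.0)
        self.values = v

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.roi_labels,
                          columns=self.roi_labels)
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 subject_id: str = "") -> "AssociationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.columns),
                   subject_id or Path(path).stem)


@dataclass
class BinaryGraph:
    """Undirected, unweighted adjacency at a fixed edge density."""

    adjacency: np.ndarray
    density: float
    roi_labels: list[str]

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric (undirected graph)")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        if a.shape[0] != len(self.roi_labels):
            raise ValueError("label count does not match adjacency size")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)

    def to_networkx(self):
        import networkx as nx

        g = nx.from_numpy_array(self.adjacency.astype(int))
        return g

    def edge_list(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(i.tolist(), j.tolist()))

    def to_edge_tsv(self, path: str | Path) -> None:
        rows = [(self.roi_labels[i], self.roi_labels[j])
                for i, j in self.edge_list()]
        pd.DataFrame(rows, columns=["node_a", "node_b"]).to_csv(
            path, sep="\t", index=False)


@dataclass(frozen=True)
class DensitySweep:
    """Ordered set of edge densities for the threshold sweep."""

    densities: tuple[float, ...] = (
        0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50)

    def __post_init__(self) -> None:
        d = tuple(float(x) for x in self.densities)
        if len(d) == 0:
            raise ValueError("density sweep must be non-empty")
        if any(not (0 < x <= 1) for x in d):
            raise ValueError("densities must lie in (0, 1]")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("densities must be strictly increasing")
        object.__setattr__(self, "densities", d)

    def __iter__(self) -> Iterator[float]:
        return iter(self.densities)

    def __len__(self) -> int:
        return len(self.densities)


def correlation_matrix(series: RoiTimeSeries) -> AssociationMatrix:
    """Pairwise Pearson correlation of all ROI columns."""
    if series.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for correlation")
    sd = series.data.std(axis=0)
    if np.any(sd == 0):
        bad = [series.roi_labels[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant ROI column(s): {bad}")
    r = np.corrcoef(series.data, rowvar=False)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return AssociationMatrix(r, list(series.roi_labels), series.subject_id)


def _ranked_pairs(assoc: AssociationMatrix,
                  negatives: str = "exclude") -> tuple[np.ndarray, np.ndarray,
                                                       np.ndarray]:
    """Off-diagonal pairs ranked strongest-first, with deterministic ties.

    Ranking is by signed correlation by default (strong negatives are
    never selected at moderate densities); ``negatives="absolute"`` ranks
    by magnitude instead.  Ties are broken by lexicographic node pair so
    results are platform-independent.
    """
    n = assoc.n_rois
    ii, jj = np.triu_indices(n, k=1)
    vals = assoc.values[ii, jj]
    key = np.abs(vals) if negatives == "absolute" else vals
    order = np.lexsort((jj, ii, -key))
    return ii[order], jj[order], vals[order]


def binarize_at_density(assoc: AssociationMatrix, d: float,
                        negatives: str = "exclude") -> BinaryGraph:
    """Keep the top ceil(d * n(n-1)/2) strongest pairs as edges."""
    if not 0 < d <= 1:
        raise ValueError("density must lie in (0, 1]")
    if negatives not in ("exclude", "absolute"):
        raise ValueError(f"unknown negatives mode {negatives!r}")
    n = assoc.n_rois
    m_total = n * (n - 1) // 2
    k = math.ceil(d * m_total)
    if k < 1:
        raise ValueError(f"density {d} keeps zero edges for n={n}")
    ii, jj, _ = _ranked_pairs(assoc, negatives)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[ii[:k], jj[:k]] = 1
    adj |= adj.T
    return BinaryGraph(adj, k / m_total, list(assoc.roi_labels))


def binarize_at_threshold(assoc: AssociationMatrix,
                          r_threshold: float) -> BinaryGraph:
    """Alternative reading of the sweep: absolute correlation cutoffs.

    Keeps every pair whose correlation is >= ``r_threshold``.
    """
    n = assoc.n_rois
    m_total = n * (n - 1) // 2
    mask = np.triu(assoc.values >= r_threshold, k=1)
    adj = (mask | mask.T).astype(np.int8)
    return BinaryGraph(adj, int(mask.sum()) / m_total, list(assoc.roi_labels))


def group_mean_association(
    subjects: Sequence[AssociationMatrix], subject_id: str = "group_mean"
) -> AssociationMatrix:
    """Entrywise mean after Fisher z-transform, back-transformed.

    Averaging correlations through atanh/tanh avoids the downward bias of
    naive averaging near |r| = 1.  All inputs must share the same ROI
    labels in the same order.
    """
    if len(subjects) == 0:
        raise ValueError("need at least one association matrix")
    ref = subjects[0].roi_labels
    for s in subjects[1:]:
        if s.roi_labels != ref:
            diff = sorted(set(s.roi_labels) ^ set(ref))
            raise ValueError(f"ROI label mismatch across subjects: {diff}")
    clip = 1.0 - 1e-12
    z = np.mean(
        [np.arctanh(np.clip(s.values, -clip, clip)) for s in subjects], axis=0
    )
    r = np.tanh(z)
    np.fill_diagonal(r, 1.0)
    return AssociationMatrix(r, list(ref), subject_id)
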