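"""Connectome construction: streamline endpoints -> weighted adjacency.

A streamline contributes to edge (i, j) iff its first endpoint lies in region
i and its last endpoint in region j (i != j), by nearest-voxel label lookup.
Two edge-weighting strategies are provided:

* length-adjusted:  w_ij = 1/2 * sum_m 1/l_m over the N_ij streamlines,
  which corrects the distal bias of seed-count-proportional streamline counts;
* volume-adjusted:  w_ij = 2 N_ij / (V_i + V_j),
  which corrects for end-node volume (and hence head size).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .tracking import StreamlineSet

__all__ = [
    "Parcellation",
    "Connectome",
    "assign_edges",
    "weight_length_adjusted",
    "weight_volume_adjusted",
]


@dataclass
class Parcellation:
    """Integer label volume (0 = background, 1..n regions) with geometry."""

    labels: np.ndarray
    affine: Optional[np.ndarray] = None
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.affine is None:
            self.affine = np.diag([self.voxel_size] * 3 + [1.0])
        else:
            self.affine = np.asarray(self.affine, dtype=float)
        labs = np.unique(self.labels)
        labs = labs[labs > 0]
        if len(labs) == 0:
            raise ValueError("parcellation contains no positive labels")
        expected = np.arange(1, labs.max() + 1)
        if not np.array_equal(labs, expected):
            raise ValueError("labels 1..n must all be present")

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())

    @property
    def node_volumes(self) -> np.ndarray:
        """Region volumes V_i in mm^3 (voxel count x voxel volume)."""
        counts = np.bincount(self.labels.ravel(), minlength=self.n_regions + 1)[1:]
        return counts * float(self.voxel_size) ** 3

    def label_at(self, pts_mm: np.ndarray) -> np.ndarray:
        """Nearest-voxel label lookup for world-mm points (0 outside)."""
        inv = np.linalg.inv(self.affine)
        pts = np.atleast_2d(np.asarray(pts_mm, dtype=float))
        vox = np.rint(pts @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        out = np.zeros(len(vox), dtype=np.int32)
        shape = np.array(self.labels.shape)
        ok = np.all((vox >= 0) & (vox < shape), axis=1)
        if ok.any():
            v = vox[ok]
            out[ok] = self.labels[v[:, 0], v[:, 1], v[:, 2]]
        return out if np.asarray(pts_mm).ndim == 2 else out[:1]


@dataclass
class Connectome:
    """Per-subject connectome: counts, per-edge streamline lengths, weights.

    ``lengths[(i, j)]`` (i < j) is the list of lengths (mm) of the N_ij
    streamlines joining i and j; absent for synthetic subjects.
    """

    counts: np.ndarray
    node_volumes: Optional[np.ndarray] = None
    lengths: Optional[dict] = None
    weights: Optional[np.ndarray] = None
    strategy: str = "none"
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = self.counts.shape[0]
        if self.counts.shape != (n, n):
            raise ValueError("count matrix must be square")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("count matrix must be symmetric")
        if np.any(np.diag(self.counts) != 0):
            raise ValueError("count matrix must have a zero diagonal")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")

    @classmethod
    def from_weights(cls, W: np.ndarray, strategy: str = "synthetic",
                     subject_id: str = "",
                     node_volumes: Optional[np.ndarray] = None) -> "Connectome":
        """Wrap a ready weight matrix (counts = edge indicators)."""
        W = np.asarray(W, dtype=float)
        counts = (W > 0).astype(np.int64)
        np.fill_diagonal(counts, 0)
        return cls(counts=counts, weights=W, strategy=strategy,
                   subject_id=subject_id, node_volumes=node_volumes)

    @property
    def n_nodes(self) -> int:
        return self.counts.shape[0]

    @property
    def adjacency(self) -> np.ndarray:
        """Unweighted adjacency a_ij = [N_ij > 0]."""
        return (self.counts > 0).astype(np.int8)

    def density(self) -> float:
        n = self.n_nodes
        return float(np.count_nonzero(np.triu(self.counts, 1) > 0)
                     / (n * (n - 1) / 2))


def assign_edges(tracks: StreamlineSet, parc: Parcellation) -> Connectome:
    """Count streamlines per node pair by endpoint region membership.

    Endpoints in background (label 0) or both in the same region contribute
    nothing; each traced streamline counts at most once per pair.
    """
    n = parc.n_regions
    counts = np.zeros((n, n), dtype=np.int64)
    lengths: dict = {}
    if len(tracks):
        starts = np.array([s.points[0] for s in tracks])
        ends = np.array([s.points[-1] for s in tracks])
        lab_s = parc.label_at(starts)
        lab_e = parc.label_at(ends)
        for sl, a, b in zip(tracks, lab_s, lab_e):
            if a == 0 or b == 0 or a == b:
                continue
            i, j = int(min(a, b)) - 1, int(max(a, b)) - 1
            counts[i, j] += 1
            counts[j, i] += 1
            lengths.setdefault((i, j), []).append(sl.length)
    return Connectome(counts=counts, node_volumes=parc.node_volumes,
                      lengths=lengths, strategy="none")


def weight_length_adjusted(conn: Connectome) -> Connectome:
    """Length-adjusted weights: w_ij = 1/2 * sum over the N_ij streamlines of
    the reciprocal streamline length (mm^-1)."""
    if conn.lengths is None:
        raise ValueError("connectome has no recorded streamline lengths")
    n = conn.n_nodes
    W = np.zeros((n, n))
    for (i, j), ls in conn.lengths.items():
        ls = np.asarray(ls, dtype=float)
        if np.any(ls <= 0):
            raise ValueError(f"non-positive streamline length on edge ({i},{j})")
        if len(ls) != conn.counts[i, j]:
            raise ValueError("length list size disagrees with streamline count")
        W[i, j] = W[j, i] = 0.5 * np.sum(1.0 / ls)
    return Connectome(counts=conn.counts, node_volumes=conn.node_volumes,
                      lengths=conn.lengths, weights=W,
                      strategy="length_adjusted", subject_id=conn.subject_id)


def weight_volume_adjusted(conn: Connectome) -> Connectome:
    """Volume-adjusted weights: w_ij = 2 N_ij / (V_i + V_j) (mm^-3)."""
    if conn.node_volumes is None:
        raise ValueError("connectome has no node volumes")
    V = np.asarray(conn.node_volumes, dtype=float)
    pair_vol = V[:, None] + V[None, :]
    if np.any((pair_vol <= 0) & (conn.counts > 0)):
        raise ValueError("zero end-node volume sum on a populated edge")
    with np.errstate(divide="ignore", invalid="ignore"):
        W = 2.0 * conn.counts / pair_vol
    W[~np.isfinite(W)] = 0.0
    np.fill_diagonal(W, 0.0)
    return Connectome(counts=conn.counts, node_volumes=conn.node_volumes,
                      lengths=conn.lengths, weights=W,
                      strategy="volume_adjusted", subject_id=conn.subject_id)
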