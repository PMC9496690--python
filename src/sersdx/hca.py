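"""Agglomerative hierarchical clustering of averaged sample fingerprints.

Treats each normalized fingerprint as a point whose coordinates are the
intensities on the shared wavenumber grid (each wavenumber one dimension,
peak height the value).  Samples are merged bottom-up under a chosen
linkage; in the blinded-replicates experiment, cutting the dendrogram at
the number of true samples should put each sample's replicate mappings in
one cluster ("full concordance").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .spectra_io import Spectrum

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "ClusterAssignment",
    "compute_distance_matrix",
    "agglomerate",
    "cut_tree",
    "replicate_concordance",
    "LINKAGES",
]

LINKAGES = ("complete", "single", "average")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal, plus sample ids."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite distance")
        if np.any(d < 0) or not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
            raise ValueError("matrix must be symmetric, nonnegative, zero-diagonal")
        object.__setattr__(self, "d", d)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge history over ``ids``.

    ``merges`` follows the scipy linkage convention: row k merges clusters
    ``a`` and ``b`` (indices < n refer to leaves, n+k to the cluster formed
    at step k) at the given height.
    """

    ids: tuple[str, ...]
    merges: np.ndarray  # (n-1, 4) linkage matrix
    linkage: str

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat clustering: sample id -> cluster index, with k clusters in use."""

    assignment: dict[str, int]
    k: int

    def __post_init__(self):
        if len(set(self.assignment.values())) != self.k:
            raise ValueError("assignment does not use exactly k distinct clusters")


def compute_distance_matrix(
    fingerprints: Sequence[Spectrum],
    peak_centers: Sequence[float] | None = None,
) -> DistanceMatrix:
    """Euclidean distances between fingerprint intensity vectors.

    By default the full grid is used.  Passing ``peak_centers`` switches to
    the peak-height-vector variant: only the intensities at the grid points
    nearest those centers enter the distance.
    """
    if not fingerprints:
        raise ValueError("no fingerprints")
    grid = fingerprints[0].wavenumbers
    for fp in fingerprints[1:]:
        if fp.wavenumbers.shape != grid.shape or not np.allclose(fp.wavenumbers, grid):
            raise ValueError("fingerprints are not on one grid")
    X = np.stack([fp.intensities for fp in fingerprints])
    if peak_centers is not None:
        idx = [int(np.argmin(np.abs(grid - c))) for c in peak_centers]
        X = X[:, idx]
    ids = tuple(
        str(fp.meta.get("sample_id", f"fp{k}")) for k, fp in enumerate(fingerprints)
    )
    diff = X[:, None, :] - X[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(ids, d)


def agglomerate(dist: DistanceMatrix, linkage: str = "complete") -> Dendrogram:
    """Standard agglomerative merge sequence under the chosen linkage."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if len(dist) < 2:
        raise ValueError("need at least two samples to cluster")
    Z = hierarchy.linkage(squareform(dist.d, checks=False), method=linkage)
    return Dendrogram(dist.ids, Z, linkage)


def cut_tree(dend: Dendrogram, k: int) -> ClusterAssignment:
    """Flat clustering from suppressing the last k-1 merges."""
    n = len(dend.ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    labels = hierarchy.cut_tree(dend.merges, n_clusters=k).ravel()
    return ClusterAssignment(dict(zip(dend.ids, (int(c) for c in labels))), k)


def replicate_concordance(
    assign: ClusterAssignment, truth: Mapping[str, str]
) -> float:
    """Agreement between clusters and true replicate groups.

    Returns 1.0 iff the two partitions of the ids are identical; otherwise
    the adjusted Rand index (chance-corrected, ~0 for random assignment).
    """
    if set(assign.assignment) != set(truth):
        raise ValueError("assignment and truth must cover the same ids")
    ids = sorted(assign.assignment)
    a = [assign.assignment[i] for i in ids]
    t = [truth[i] for i in ids]
    part_a = {}
    part_t = {}
    for i, ca, ct in zip(ids, a, t):
        part_a.setdefault(ca, set()).add(i)
        part_t.setdefault(ct, set()).add(i)
    if set(frozenset(s) for s in part_a.values()) == set(frozenset(s) for s in part_t.values()):
        return 1.0
    t_codes = {lab: j for j, lab in enumerate(dict.fromkeys(t))}
    return float(adjusted_rand_score([t_codes[x] for x in t], a))
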