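"""Adaptive clustering of docking poses.

Docking engines emit tens to hundreds of candidate poses per ligand;
the most probable binding mode is taken as the most populated cluster
of mutually similar poses.  Clustering quality is judged by two metrics
computed on the pose-RMSD matrix:

* the Davies–Bouldin index (DBI) — lower means tighter, better
  separated clusters — evaluated on cluster *medoids* so only the
  distance matrix is needed; and
* the percentage of variance explained, ``100·(1 − SSR/SST)``, whose
  plateau against the cluster count marks the elbow.

``cluster_adaptive`` cuts an average-linkage dendrogram at each
candidate cluster count and picks the first DBI local minimum whose
percentage-of-variance gain has plateaued.  Pose RMSD is computed
without superposition: all poses of one docking run share the receptor
frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "pose_rmsd_matrix",
    "ClusterSolution",
    "dbi",
    "pvariance",
    "cluster_adaptive",
    "representative_cluster",
]


def pose_rmsd_matrix(poses: Sequence) -> np.ndarray:
    """Pairwise in-frame RMSD matrix (Å) of poses with matching atoms."""
    coords = np.array([p.coordinates() for p in poses], dtype=float)
    n = coords.shape[0]
    diff = coords[:, None, :, :] - coords[None, :, :, :]
    mat = np.sqrt(np.mean(np.sum(diff * diff, axis=3), axis=2))
    mat[np.arange(n), np.arange(n)] = 0.0
    return mat


def _check_matrix(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(dist < 0):
        raise ValueError("distances must be non-negative")
    return dist


def _dense_labels(assignment: Sequence[int]) -> np.ndarray:
    """Relabel clusters to dense 0..k−1 by order of first occurrence."""
    labels = np.asarray(assignment)
    mapping: Dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _medoid(dist: np.ndarray, members: np.ndarray) -> int:
    """Index (into the full matrix) of the member minimising total distance."""
    sub = dist[np.ix_(members, members)]
    return int(members[np.argmin(sub.sum(axis=1))])


def dbi(dist: np.ndarray, assignment: Sequence[int]) -> float:
    """Davies–Bouldin index of a partition, from the distance matrix alone.

    ``s_i`` is the mean distance of cluster members to the cluster
    medoid and ``d_ij`` the medoid–medoid distance; the index is the
    mean over clusters of ``max_{j≠i} (s_i + s_j)/d_ij``.
    """
    dist = _check_matrix(dist)
    labels = _dense_labels(assignment)
    k = labels.max() + 1
    if k < 2:
        raise ValueError("DBI requires at least 2 clusters")
    medoids = []
    scatter = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        m = _medoid(dist, members)
        medoids.append(m)
        scatter.append(float(dist[members, m].mean()))
    ratios = np.zeros(k)
    for i in range(k):
        worst = 0.0
        for j in range(k):
            if i == j:
                continue
            d_ij = dist[medoids[i], medoids[j]]
            if d_ij == 0.0:
                raise ValueError(
                    f"coincident medoids for distinct clusters {i} and {j}")
            worst = max(worst, (scatter[i] + scatter[j]) / d_ij)
        ratios[i] = worst
    return float(ratios.mean())


def pvariance(dist: np.ndarray, assignment: Sequence[int]) -> float:
    """Percentage of variance explained by a partition.

    ``100·(1 − SSR/SST)`` with SSR the sum of squared member–medoid
    distances within clusters and SST the sum of squared distances to
    the global medoid.  Returns 100 when all poses coincide (SST = 0).
    """
    dist = _check_matrix(dist)
    labels = _dense_labels(assignment)
    n = dist.shape[0]
    all_idx = np.arange(n)
    g = _medoid(dist, all_idx)
    sst = float(np.sum(dist[:, g] ** 2))
    if sst == 0.0:
        return 100.0
    ssr = 0.0
    for c in range(labels.max() + 1):
        members = np.flatnonzero(labels == c)
        m = _medoid(dist, members)
        ssr += float(np.sum(dist[members, m] ** 2))
    return 100.0 * (1.0 - ssr / sst)


@dataclass
class ClusterSolution:
    """A partition of a pose set with its quality metrics."""

    k: int
    assignment: np.ndarray           # dense labels 0..k−1
    populations: np.ndarray          # per-cluster member counts
    dbi: Optional[float]             # None for the trivial k=1 partition
    pvariance: float
    per_cluster_min_energy: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return int(self.populations.sum())


def _solution(dist: np.ndarray, labels: np.ndarray,
              energies: Optional[Sequence[float]]) -> ClusterSolution:
    labels = _dense_labels(labels)
    k = int(labels.max() + 1)
    populations = np.bincount(labels, minlength=k)
    sol_dbi = dbi(dist, labels) if k >= 2 else None
    sol_pv = pvariance(dist, labels)
    per_min = None
    if energies is not None:
        energies = np.asarray(energies, dtype=float)
        per_min = np.array([energies[labels == c].min() for c in range(k)])
    return ClusterSolution(k=k, assignment=labels, populations=populations,
                           dbi=sol_dbi, pvariance=sol_pv,
                           per_cluster_min_energy=per_min)


def cluster_adaptive(dist: np.ndarray,
                     k_range: Optional[Tuple[int, int]] = None,
                     energies: Optional[Sequence[float]] = None,
                     pvariance_plateau: float = 5.0,
                     dbi_accept: float = 1.0,
                     pvariance_accept: float = 90.0) -> ClusterSolution:
    """Cluster poses with automatic selection of the cluster count.

    An average-linkage dendrogram of the pose-RMSD matrix is cut at
    every ``k`` in ``k_range`` (default ``[2, min(20, n−1)]``).  A cut
    is *acceptable* when both metrics reach acceptable values: DBI at
    most ``dbi_accept`` and percentage of variance at least
    ``pvariance_accept``.  Cuts containing singleton clusters are never
    candidates (a singleton's medoid scatter is identically zero, which
    deflates the DBI artificially).  The selected ``k`` is the first acceptable
    local minimum of the DBI whose percentage-of-variance gain from
    ``k`` to ``k+1`` is below ``pvariance_plateau`` points (falling
    back to the acceptable cut with the lowest DBI).  If no cut is
    acceptable the pose set is judged unimodal and the trivial
    one-cluster partition is returned.  Deterministic for a fixed
    matrix.
    """
    dist = _check_matrix(dist)
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need at least 2 poses to cluster")
    k_lo, k_hi = k_range if k_range is not None else (2, min(20, n - 1))
    k_lo = max(2, k_lo)
    k_hi = min(k_hi, n - 1)
    if k_hi < k_lo:
        k_lo = k_hi = min(2, n - 1) if n > 2 else 2
        k_hi = max(k_hi, k_lo)
    z = linkage(squareform(dist, checks=False), method="average")

    def cut(k: int) -> np.ndarray:
        return _dense_labels(fcluster(z, t=k, criterion="maxclust"))

    ks = list(range(k_lo, min(k_hi, n - 1) + 1))
    labels_by_k = {k: cut(k) for k in ks}
    dbi_by_k = {}
    pv_by_k = {}
    for k in ks:
        labels = labels_by_k[k]
        actual = labels.max() + 1
        populations = np.bincount(labels, minlength=actual)
        if actual < 2 or populations.min() < 2:
            # singleton clusters have zero medoid scatter, which deflates
            # the DBI artificially: such cuts are not usable candidates
            dbi_by_k[k] = np.inf
        else:
            try:
                dbi_by_k[k] = dbi(dist, labels)
            except ValueError:
                # coincident medoids at this cut: unusable candidate
                dbi_by_k[k] = np.inf
        pv_by_k[k] = pvariance(dist, labels)
    # percentage of variance one step past each candidate, for the plateau test
    pv_next = {}
    for k in ks:
        nxt = k + 1
        if nxt in pv_by_k:
            pv_next[k] = pv_by_k[nxt]
        elif nxt <= n:
            pv_next[k] = pvariance(dist, cut(nxt))
        else:
            pv_next[k] = 100.0

    def acceptable(k: int) -> bool:
        return (dbi_by_k[k] <= dbi_accept
                and pv_by_k[k] >= pvariance_accept)

    selected = None
    for k in ks:
        left = dbi_by_k.get(k - 1, np.inf)
        right = dbi_by_k.get(k + 1, np.inf)
        is_local_min = dbi_by_k[k] <= left and dbi_by_k[k] <= right
        plateaued = (pv_next[k] - pv_by_k[k]) < pvariance_plateau
        if is_local_min and plateaued and acceptable(k):
            selected = k
            break
    if selected is None:
        candidates = [k for k in ks if acceptable(k)]
        if candidates:
            selected = min(candidates, key=lambda k: (dbi_by_k[k], k))
        else:
            # no acceptable split: unimodal pose cloud, one cluster
            return _solution(dist, np.zeros(n, dtype=int), energies)
    return _solution(dist, labels_by_k[selected], energies)


def representative_cluster(sol: ClusterSolution,
                           energies: Optional[Sequence[float]] = None,
                           min_population: float = 0.25):
    """Most populated cluster and its lowest energy, or ``None``.

    Returns ``(cluster_id, min_energy)`` when the largest cluster holds
    at least ``min_population`` of all poses (inclusive gate, the 25 %
    screening rule); population ties break toward the lower minimum
    energy, then the lower cluster id.  Returns ``None`` (rejection)
    when the gate fails.
    """
    if energies is not None:
        energies = np.asarray(energies, dtype=float)
        if len(energies) != sol.n:
            raise ValueError("energies must align with poses")
        per_min = np.array([energies[sol.assignment == c].min()
                            for c in range(sol.k)])
    elif sol.per_cluster_min_energy is not None:
        per_min = np.asarray(sol.per_cluster_min_energy, dtype=float)
    else:
        raise ValueError("per-pose or per-cluster energies are required")
    order = sorted(range(sol.k),
                   key=lambda c: (-sol.populations[c], per_min[c], c))
    best = order[0]
    if sol.populations[best] / sol.n < min_population:
        return None
    return best, float(per_min[best])
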