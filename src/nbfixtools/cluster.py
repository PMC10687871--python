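"""Density-peak clustering (Rodriguez-Laio) of conformational ensembles.

Works on any precomputed pairwise distance matrix (typically eRMSD
between trajectory frames).  Each point i gets a local density rho_i
(number of neighbors within d_c, or a Gaussian-kernel sum) and a
separation delta_i, the distance to the nearest point of higher
density; the global density maximum receives the largest pairwise
distance.  Cluster centers stand out as points where both rho and
delta are large; the remaining points are assigned to the cluster of
their nearest higher-density neighbor, descending density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ClusterAssignment", "cluster_density_peaks", "dc_percentile"]


@dataclass
class ClusterAssignment:
    labels: np.ndarray        # per-frame cluster id (0..k-1)
    centers: np.ndarray       # frame indices of the k centers
    populations: np.ndarray   # per-cluster population, percent
    rho: np.ndarray
    delta: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


def dc_percentile(dist: np.ndarray, percentile: float = 2.0) -> float:
    """Common heuristic for the cutoff d_c: a low percentile of the
    off-diagonal pairwise distance distribution."""
    iu = np.triu_indices(dist.shape[0], k=1)
    if iu[0].size == 0:
        return 1.0
    return float(np.percentile(dist[iu], percentile))


def _validate(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(dist < 0) or not np.allclose(np.diag(dist), 0):
        raise ValueError("distance matrix must be non-negative with zero diagonal")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    return dist


def cluster_density_peaks(
    dist: np.ndarray,
    d_c: float | None = None,
    n_clusters: int | None = None,
    kernel: str = "cutoff",
) -> ClusterAssignment:
    """Cluster frames by the density-peak decision rule.

    With ``n_clusters=None`` the number of centers is chosen
    automatically from the largest gap in the sorted rho*delta products
    (both factors max-normalized); pass an integer to force k.
    """
    dist = _validate(dist)
    n = dist.shape[0]
    if n == 1:
        return ClusterAssignment(
            labels=np.zeros(1, int),
            centers=np.array([0]),
            populations=np.array([100.0]),
            rho=np.array([1.0]),
            delta=np.array([0.0]),
        )
    if d_c is None:
        # aim for a couple of neighbors per point even at small n
        d_c = dc_percentile(dist, max(2.0, 200.0 / n))
    if d_c <= 0:
        d_c = float(np.mean(dist)) or 1.0
    if kernel == "cutoff":
        rho = (dist < d_c).sum(axis=1).astype(float) - 1.0  # exclude self
    elif kernel == "gaussian":
        rho = np.exp(-((dist / d_c) ** 2)).sum(axis=1) - 1.0
    else:
        raise ValueError(f"unknown kernel {kernel!r}")

    order = np.argsort(-rho, kind="stable")
    delta = np.empty(n)
    nearest_higher = np.full(n, -1)
    delta[order[0]] = float(dist.max())
    for pos in range(1, n):
        i = order[pos]
        higher = order[:pos]
        j = higher[np.argmin(dist[i, higher])]
        delta[i] = dist[i, j]
        nearest_higher[i] = j

    gamma = (rho / max(rho.max(), 1e-12)) * (delta / max(delta.max(), 1e-12))
    if n_clusters is None:
        # decision graph: centers separate from the bulk by an
        # anomalously large delta (at least half the largest separation)
        # while sitting in a dense region (low-rho stragglers excluded)
        n_clusters = max(
            1, int(np.sum((delta >= 0.6 * delta.max()) & (rho >= rho.mean())))
        )
    centers = np.argsort(-gamma, kind="stable")[:n_clusters]

    labels = np.full(n, -1)
    for c_id, c in enumerate(centers):
        labels[c] = c_id
    for i in order:  # descending density: parents assigned first
        if labels[i] < 0:
            labels[i] = labels[nearest_higher[i]]

    pops = np.array([100.0 * np.sum(labels == c) / n for c in range(n_clusters)])
    return ClusterAssignment(
        labels=labels,
        centers=np.asarray(centers),
        populations=pops,
        rho=rho,
        delta=delta,
    )
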