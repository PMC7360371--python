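"""Cluster identification and cluster-level order parameters.

Clusters are connected components of occupied sites under the von Neumann
adjacency with periodic wrap, labeled with the Hoshen-Kopelman scheme
(union-find with path compression in a single raster sweep).  From the
labeling we derive the order parameters used to classify the assembly state:

* ``S_clus`` — cluster size, reported as a particle count or as a fraction
  of ``N_tot``;
* ``L_clus`` — size of the single largest cluster as a fraction of
  ``N_tot`` (``L_clus -> 1`` signals a system-spanning macrophase, many
  coexisting clusters with ``S_clus << N_tot`` a microphase);
* ``phi_clus / phi_lattice`` — intra-cluster density relative to the bulk,
  computed from the 2D radius of gyration of the member sites
  (``phi_clus = S / (pi R_g^2)``); >> 1 for dense droplets, -> 1 for a
  system-spanning network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lattice import DIRECTIONS, LatticeState

__all__ = [
    "ClusterLabeling",
    "ClusterDensityResult",
    "label_clusters",
    "largest_cluster_fraction",
    "cluster_size_distribution",
    "cluster_density",
    "cluster_densities",
]

#: minimum member count for a well-defined gyration-disk density
MIN_DENSITY_SIZE = 4


@dataclass
class ClusterLabeling:
    """Partition of particles into adjacency-connected clusters.

    ``labels[p]`` is the cluster index of particle ``p``.  Labels are
    canonical: sorted by descending size, ties broken by the smallest
    member id, so identical partitions always get identical labels.
    """

    labels: np.ndarray          # (N,) int64, particle id -> cluster index
    sizes: np.ndarray           # (n_clusters,) int64
    n_clusters: int

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def _find(parent: np.ndarray, i: int) -> int:
    root = i
    while parent[root] != root:
        root = parent[root]
    while parent[i] != root:        # path compression
        parent[i], i = root, parent[i]
    return root


def label_clusters(state: LatticeState) -> ClusterLabeling:
    """Hoshen-Kopelman labeling of occupied sites (periodic von Neumann)."""
    n = state.n_particles
    parent = np.arange(n, dtype=np.int64)
    L = state.L
    for p in range(n):
        r, c = state.positions[p]
        # scanning S and E once covers each adjacent pair exactly once
        for dr, dc in ((1, 0), (0, 1)):
            q = state.grid[(r + dr) % L, (c + dc) % L]
            if q >= 0:
                rp, rq = _find(parent, p), _find(parent, int(q))
                if rp != rq:
                    parent[max(rp, rq)] = min(rp, rq)
    roots = np.array([_find(parent, p) for p in range(n)], dtype=np.int64)
    uniq, inverse, counts = np.unique(roots, return_inverse=True, return_counts=True)
    # canonical order: descending size, ties by smallest member id (= root)
    order = np.lexsort((uniq, -counts))
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return ClusterLabeling(
        labels=rank[inverse], sizes=counts[order], n_clusters=len(uniq)
    )


def largest_cluster_fraction(labeling: ClusterLabeling, n_tot: int) -> float:
    """``L_clus``: largest cluster size as a fraction of ``n_tot``."""
    if n_tot <= 0:
        raise ValueError("n_tot must be positive")
    if labeling.n_clusters == 0:
        return 0.0
    return float(labeling.sizes.max()) / n_tot


def cluster_size_distribution(
    trajectories,
    t_window: tuple[float, float],
    n_bins: int = 20,
    bin_edges: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled normalized histogram of ``S_clus / N_tot`` over snapshots.

    Every cluster in every snapshot whose time falls inside ``t_window``
    (inclusive) contributes one count.  Returns ``(edges, probability)``
    with probabilities summing to 1.  Default binning: ``n_bins`` equal
    bins on (0, 1].
    """
    lo, hi = t_window
    fractions: list[float] = []
    for traj in trajectories:
        for t, snap in zip(traj.snapshot_times, traj.snapshots):
            if lo <= t <= hi:
                lab = label_clusters(snap)
                fractions.extend(lab.sizes / snap.n_particles)
    if not fractions:
        raise ValueError(f"no snapshots inside the time window {t_window}")
    if bin_edges is None:
        bin_edges = np.linspace(0.0, 1.0, n_bins + 1)
    edges = np.asarray(bin_edges, dtype=float)
    # right-inclusive bins (lo, hi], so S/N = 1 lands in the last bin and a
    # fraction sitting exactly on an edge belongs to the bin it closes
    idx = np.searchsorted(edges, np.asarray(fractions), side="left") - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1).astype(float)
    return edges, counts / counts.sum()


@dataclass
class ClusterDensityResult:
    """Gyration-disk density of one cluster."""

    size: int
    rg2: float                  # squared 2D radius of gyration (lattice units)
    phi_clus: float             # S / (pi * rg2)
    ratio: float                # phi_clus / phi_lattice
    percolating: bool           # spans >= L/2 in either axis after unwrapping


def _unwrap_members(state: LatticeState, members: np.ndarray) -> np.ndarray:
    """Unwrap a cluster across the periodic seam by BFS minimal-image offsets."""
    L = state.L
    pos = {int(p): None for p in members}
    start = int(members[0])
    pos[start] = np.array(state.positions[start], dtype=np.int64)
    queue = [start]
    member_set = set(int(p) for p in members)
    while queue:
        p = queue.pop()
        rp = pos[p]
        r, c = state.positions[p]
        for d in range(4):
            dr, dc = DIRECTIONS[d]
            q = int(state.grid[(r + dr) % L, (c + dc) % L])
            if q in member_set and pos[q] is None:
                pos[q] = rp + np.array([dr, dc])
                queue.append(q)
    return np.array([pos[int(p)] for p in members], dtype=np.float64)


def cluster_density(
    state: LatticeState,
    labeling: ClusterLabeling,
    label: int,
    phi_lattice: float | None = None,
) -> ClusterDensityResult:
    """Normalized intra-cluster density ``phi_clus / phi_lattice``.

    The cluster is first unwrapped across periodic boundaries; the density
    is ``S / (pi R_g^2)`` with ``R_g`` the 2D radius of gyration of the
    member sites (lattice constant 1).  Undefined (NaN fields) for clusters
    smaller than 4 sites; clusters spanning at least ``L/2`` along either
    axis are flagged percolating and should be excluded from droplet
    density statistics.
    """
    members = labeling.members(label)
    size = len(members)
    if phi_lattice is None:
        phi_lattice = state.n_particles / state.L**2
    if size < MIN_DENSITY_SIZE:
        return ClusterDensityResult(size, math.nan, math.nan, math.nan, False)
    coords = _unwrap_members(state, members)
    span = coords.max(axis=0) - coords.min(axis=0)
    percolating = bool((span >= state.L / 2).any())
    centroid = coords.mean(axis=0)
    rg2 = float(((coords - centroid) ** 2).sum(axis=1).mean())
    phi_clus = size / (math.pi * rg2)
    return ClusterDensityResult(size, rg2, phi_clus, phi_clus / phi_lattice, percolating)


def cluster_densities(
    state: LatticeState, labeling: ClusterLabeling
) -> dict[int, ClusterDensityResult]:
    """Density result for every cluster with at least 4 members."""
    return {
        lbl: cluster_density(state, labeling, lbl)
        for lbl in range(labeling.n_clusters)
        if labeling.sizes[lbl] >= MIN_DENSITY_SIZE
    }
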