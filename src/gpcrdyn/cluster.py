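"""RMSD-cutoff clustering of trajectory snapshots.

Greedy most-neighbors clustering: frames are first superposed once onto
frame 0 using a fit region; pairwise C-alpha RMSDs over a (possibly
different) measure region are thresholded at the cutoff; the frame with the
most neighbors becomes the centroid of the first cluster, its neighborhood
is removed, and the procedure repeats. Cluster labels are 1-based in order
of decreasing size. A mutual pairwise-superposition variant is available
for small frame counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .essential import apply_transform, kabsch_superpose
from .structures import Trajectory, concatenate, select

__all__ = ["ClusterAssignment", "rmsd_cluster", "occupancy"]


@dataclass
class ClusterAssignment:
    """Per-frame cluster labels (1-based, by decreasing cluster size)."""

    labels: np.ndarray
    centroid_frames: np.ndarray
    cutoff: float
    fit_region: str
    measure_region: str
    source_names: np.ndarray | None = None
    source_frames: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0


def _pairwise_rmsd_single_fit(traj: Trajectory, fit_region: str,
                              measure_region: str) -> np.ndarray:
    """All-vs-all RMSD over the measure region after one alignment pass of
    every frame onto frame 0 using the fit region."""
    fit_idx = select(traj, fit_region, "CA")
    measure_idx = select(traj, measure_region, "CA")
    ref = traj.frames[0]
    n = traj.n_frames
    coords = np.empty((n, measure_idx.size, 3))
    for t in range(n):
        rot, trans, _ = kabsch_superpose(traj.frames[t], ref, fit_idx)
        coords[t] = apply_transform(traj.frames[t][measure_idx], rot, trans)
    flat = coords.reshape(n, -1)
    sq = np.sum(flat**2, axis=1)
    gram = flat @ flat.T
    d2 = (sq[:, None] + sq[None, :] - 2.0 * gram) / measure_idx.size
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.maximum(d2, 0.0))


def _pairwise_rmsd_mutual(traj: Trajectory, fit_region: str,
                          measure_region: str) -> np.ndarray:
    """All-vs-all RMSD with a fresh superposition for every frame pair
    (O(n^2) Kabsch fits; intended for small n)."""
    fit_idx = select(traj, fit_region, "CA")
    measure_idx = select(traj, measure_region, "CA")
    n = traj.n_frames
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rot, trans, _ = kabsch_superpose(traj.frames[j], traj.frames[i], fit_idx)
            moved = apply_transform(traj.frames[j][measure_idx], rot, trans)
            diff = moved - traj.frames[i][measure_idx]
            out[i, j] = out[j, i] = np.sqrt(np.mean(np.sum(diff * diff, axis=1)))
    return out


def _greedy_clusters(neighbors: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Greedy most-neighbors assignment from a boolean adjacency matrix
    (diagonal True). Ties go to the lowest frame index."""
    n = neighbors.shape[0]
    labels = np.zeros(n, dtype=int)
    active = np.ones(n, dtype=bool)
    counts = neighbors.sum(axis=1)
    centroids: list[int] = []
    cluster = 0
    while active.any():
        cluster += 1
        masked = np.where(active, counts, -1)
        center = int(np.argmax(masked))  # argmax takes the first (lowest) index
        members = neighbors[center] & active
        labels[members] = cluster
        centroids.append(center)
        counts = counts - (neighbors[:, members].sum(axis=1))
        active &= ~members
    return labels, centroids


def rmsd_cluster(trajs: Trajectory | list[Trajectory], fit_region: str,
                 measure_region: str, cutoff: float,
                 mutual_fit: bool = False,
                 names: list[str] | None = None) -> ClusterAssignment:
    """Cluster snapshots of one trajectory (or several, concatenated, with
    frame provenance preserved) at an RMSD cutoff (A).

    Every frame ends up labeled; each member's RMSD to its cluster centroid
    frame is at most the cutoff. Determinism: ties on neighbor count are
    broken by the lowest frame index.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    source_names = source_frames = None
    if isinstance(trajs, (list, tuple)):
        traj, source_names, source_frames = concatenate(list(trajs), names)
    else:
        traj = trajs
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    pairwise = (_pairwise_rmsd_mutual if mutual_fit
                else _pairwise_rmsd_single_fit)(traj, fit_region, measure_region)
    neighbors = pairwise <= cutoff
    labels, centroids = _greedy_clusters(neighbors)
    # relabel by decreasing cluster size (ties: earlier centroid first)
    sizes = np.bincount(labels)[1:]
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(len(order) + 1, dtype=int)
    relabel[order + 1] = np.arange(1, len(order) + 1)
    labels = relabel[labels]
    centroid_frames = np.array(centroids)[order]
    return ClusterAssignment(
        labels, centroid_frames, cutoff, fit_region, measure_region,
        source_names, source_frames,
        {"mutual_fit": mutual_fit, "n_frames": traj.n_frames},
    )


def occupancy(assignment: ClusterAssignment) -> np.ndarray:
    """Fraction of frames in each cluster, by label order; sums to 1."""
    counts = np.bincount(assignment.labels)[1:]
    return counts / counts.sum()
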