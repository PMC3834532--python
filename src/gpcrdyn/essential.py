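"""Essential dynamics: superposition, coordinate PCA and reconstruction.

Frames are least-squares superposed (proper rotations only) onto a
reference frame using a fit region's C-alpha atoms; PCA then diagonalizes
the covariance of the aligned, mean-centered C-alpha coordinates. Low-index
principal modes carry the dominant collective motions; projecting frames
onto a subset of modes and adding the mean back gives a reduced-dimensional
reconstruction of the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import Structure, Trajectory, select

__all__ = [
    "PCAResult",
    "kabsch_superpose",
    "apply_transform",
    "align_trajectory",
    "pca",
    "reconstruct",
]


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray,
                     fit_indices: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation/translation of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` with the convention
    ``aligned = mobile @ rotation.T + translation``; the RMSD is over the
    fit atoms. Improper rotations (reflections) are never produced.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if fit_indices is None:
        fit_indices = np.arange(mobile.shape[0])
    fit_indices = np.asarray(fit_indices, dtype=int)
    if fit_indices.size < 3:
        raise ValueError("at least 3 fit atoms required")
    mob = mobile[fit_indices]
    tgt = target[fit_indices]
    mob_c = mob - mob.mean(axis=0)
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise ValueError("fit atoms are collinear; superposition is degenerate")
    tgt_c = tgt - tgt.mean(axis=0)
    rot, _ = Rotation.align_vectors(tgt_c, mob_c)
    matrix = rot.as_matrix()
    translation = tgt.mean(axis=0) - mob.mean(axis=0) @ matrix.T
    diff = mob @ matrix.T + translation - tgt
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return matrix, translation, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ rotation.T + translation


def align_trajectory(traj: Trajectory, reference_frame: int = 0,
                     fit_region: str = "ALL",
                     reference: Structure | None = None) -> Trajectory:
    """Superpose every frame onto a reference using the fit region's
    C-alpha atoms; the transform is applied to all atoms.

    The reference is frame ``reference_frame`` unless an explicit reference
    structure (sharing the atom table) is given.
    """
    fit_idx = select(traj, fit_region, "CA")
    if reference is not None:
        ref_coords = reference.coords
        if ref_coords.shape != traj.frames[0].shape:
            raise ValueError("reference atom table does not match the trajectory")
    else:
        ref_coords = traj.frames[reference_frame]
    aligned = np.empty_like(traj.frames)
    for t in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(traj.frames[t], ref_coords, fit_idx)
        aligned[t] = apply_transform(traj.frames[t], rot, trans)
    return traj.with_frames(aligned)


@dataclass
class PCAResult:
    """PCA of aligned C-alpha coordinates.

    ``eigenvectors`` has modes as columns (3m x n_modes), descending
    eigenvalue (variance, A^2) order; ``projections`` are per-frame scores
    (n_frames x n_modes, A). ``atom_indices`` are the trajectory atoms the
    3m components refer to; ``fit_indices``/``reference_frame`` record the
    alignment convention (the alignment reference is typically the initial
    frame while centering uses the trajectory mean).
    """

    mean_coords: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray        # for the retained modes
    projections: np.ndarray
    atom_indices: np.ndarray
    full_eigenvalues: np.ndarray | None = None  # complete spectrum
    fit_indices: np.ndarray | None = None
    reference_frame: int = 0

    def __post_init__(self):
        if self.full_eigenvalues is None:
            self.full_eigenvalues = self.eigenvalues

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def variance_fractions(self) -> np.ndarray:
        """lambda_i / sum(all lambda) for the retained modes."""
        total = self.full_eigenvalues.sum()
        if total <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total

    @property
    def total_variance(self) -> float:
        return float(self.full_eigenvalues.sum())


def _fix_sign_columns(vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    flips = np.ones(vectors.shape[1])
    for j in range(vectors.shape[1]):
        col = vectors[:, j]
        if np.any(col) and col[np.argmax(np.abs(col))] < 0:
            flips[j] = -1.0
    return vectors * flips, flips


def pca(traj: Trajectory, atom_indices: np.ndarray | None = None,
        n_modes: int | None = None,
        frame_range: tuple[int, int] | None = None) -> PCAResult:
    """PCA of the (already aligned) trajectory's selected atoms.

    ``frame_range`` (start, stop — stop exclusive) restricts the analysis,
    e.g. to drop an equilibration stage. If more modes are requested than
    the data support, the available number is returned.
    """
    if atom_indices is None:
        atom_indices = select(traj, "ALL", "CA")
    atom_indices = np.asarray(atom_indices, dtype=int)
    frames = traj.frames
    if frame_range is not None:
        frames = frames[frame_range[0]:frame_range[1]]
    n = frames.shape[0]
    if n < 2:
        raise ValueError("PCA requires more than one frame")
    X = frames[:, atom_indices, :].reshape(n, -1)
    mean = X.mean(axis=0)
    centered = X - mean
    # SVD of the centered data: right singular vectors are the PCA modes
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = svals**2 / (n - 1)
    max_modes = int(np.sum(svals > 1e-12 * max(svals[0], 1.0)))
    if n_modes is None:
        n_modes = max_modes
    n_modes = min(n_modes, max_modes)
    vectors, flips = _fix_sign_columns(vt[:n_modes].T)
    projections = centered @ vectors
    return PCAResult(
        mean_coords=mean,
        eigenvectors=vectors,
        eigenvalues=eigenvalues[:n_modes],
        projections=projections,
        atom_indices=atom_indices,
        full_eigenvalues=eigenvalues,
    )


def reconstruct(result: PCAResult, mode_indices, traj: Trajectory) -> Trajectory:
    """Rebuild the trajectory from a subset of principal modes (0-based
    indices): frame_t = mean + sum_{i in K} projection_i(t) * p_i.

    Atoms outside the PCA selection are frozen at their mean position over
    the analyzed frames. The output shares the input's atom table.
    """
    mode_indices = np.asarray(mode_indices, dtype=int)
    if mode_indices.size == 0:
        raise ValueError("at least one mode index required")
    if mode_indices.min() < 0 or mode_indices.max() >= result.n_modes:
        raise IndexError(
            f"mode index out of range 0..{result.n_modes - 1}"
        )
    n = result.projections.shape[0]
    if n != traj.n_frames:
        raise ValueError("PCA frame count does not match the trajectory")
    flat = (result.mean_coords
            + result.projections[:, mode_indices] @ result.eigenvectors[:, mode_indices].T)
    frames = np.array([traj.frames.mean(axis=0)] * n)
    frames[:, result.atom_indices, :] = flat.reshape(n, -1, 3)
    return traj.with_frames(frames)
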