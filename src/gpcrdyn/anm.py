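"""Anisotropic network model: Hessian assembly and normal modes.

For nodes i, j within the cutoff, the 3x3 off-diagonal super-element is

    H_ij = -(gamma_ij / r_ij^2) * (r_ij (x) r_ij),

with the diagonal block the negative sum of the row's off-diagonal blocks,
so rigid translations (and rotations) are zero modes. ``gamma_ij`` depends
on the node types of the pair (protein/membrane). Modes are eigenvectors of
the Hessian with rigid-body modes removed; a connected 3-D network has
exactly six of those.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .membrane import Network

__all__ = ["ModeSet", "build_hessian", "solve_modes", "restrict_modes"]


class DisconnectedNetworkError(ValueError):
    """More near-zero modes than the six rigid-body modes of a connected network."""


@dataclass
class ModeSet:
    """Orthonormal displacement modes, ascending eigenvalue order.

    ``vectors`` has shape (3*n_nodes, n_modes) (modes as columns);
    ``node_map`` records the node order the components refer to (residue
    index for protein nodes, lattice index offset by node count for membrane
    nodes, or plain positions for restricted sets). ``degenerate`` flags
    modes whose restriction had (near-)zero norm.
    """

    vectors: np.ndarray
    eigenvalues: np.ndarray
    node_map: np.ndarray
    n_zero_modes_removed: int = 0
    degenerate: np.ndarray | None = None

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.vectors.shape[1] != len(self.eigenvalues):
            raise ValueError("one eigenvalue per mode required")
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.eigenvalues), dtype=bool)

    @property
    def n_modes(self) -> int:
        return self.vectors.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.vectors.shape[0] // 3


def _fix_sign(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign: largest-magnitude component of each column positive."""
    vectors = vectors.copy()
    for j in range(vectors.shape[1]):
        col = vectors[:, j]
        if np.any(col) and col[np.argmax(np.abs(col))] < 0:
            vectors[:, j] = -col
    return vectors


def build_hessian(network: Network) -> np.ndarray:
    """Assemble the dense 3N x 3N ANM Hessian of a typed network."""
    coords = network.coords
    types = network.node_types
    n = network.n_nodes
    if network.cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pairs = network.spring_pairs()
    hessian = np.zeros((3 * n, 3 * n))
    for i, j in pairs:
        rij = coords[j] - coords[i]
        d2 = float(rij @ rij)
        if d2 < 1e-12:
            raise ValueError(f"coincident nodes {i} and {j} within cutoff")
        gamma = network.gamma(types[i], types[j])
        block = -(gamma / d2) * np.outer(rij, rij)
        si, sj = 3 * i, 3 * j
        hessian[si:si + 3, sj:sj + 3] += block
        hessian[sj:sj + 3, si:si + 3] += block
        hessian[si:si + 3, si:si + 3] -= block
        hessian[sj:sj + 3, sj:sj + 3] -= block
    return hessian


def solve_modes(hessian: np.ndarray, n_modes: int = 20,
                zero_tol: float = 1e-8,
                node_map: np.ndarray | None = None) -> ModeSet:
    """Lowest ``n_modes`` non-rigid normal modes of a (symmetric PSD)
    Hessian. Modes with eigenvalue below ``zero_tol`` relative to the
    largest eigenvalue are treated as rigid-body modes and removed; more
    than six of them means the network is disconnected."""
    hessian = np.asarray(hessian, dtype=float)
    if hessian.ndim != 2 or hessian.shape[0] != hessian.shape[1]:
        raise ValueError("hessian must be square")
    if not np.allclose(hessian, hessian.T, atol=1e-8):
        raise ValueError("hessian must be symmetric")
    dim = hessian.shape[0]
    lam_max = float(eigh(hessian, subset_by_index=[dim - 1, dim - 1],
                         eigvals_only=True)[0])
    if lam_max <= 0:
        raise ValueError("hessian has no positive eigenvalues")
    n_low = min(dim, n_modes + 6)
    eigvals, eigvecs = eigh(hessian, subset_by_index=[0, n_low - 1])
    threshold = zero_tol * lam_max
    zero_mask = eigvals < threshold
    n_zero = int(zero_mask.sum())
    if n_zero > 6:
        raise DisconnectedNetworkError(
            f"{n_zero} near-zero modes found (six expected): network disconnected"
        )
    keep = ~zero_mask
    vectors = _fix_sign(eigvecs[:, keep][:, :n_modes])
    eigenvalues = eigvals[keep][:n_modes]
    if node_map is None:
        node_map = np.arange(dim // 3)
    return ModeSet(vectors, eigenvalues, np.asarray(node_map), n_zero)


def restrict_modes(modes: ModeSet, node_indices: np.ndarray,
                   zero_norm_tol: float = 1e-12) -> ModeSet:
    """Restrict every mode to the components of ``node_indices`` (indices
    into the mode's node order) and renormalize to unit length.

    A mode with (near-)zero norm on the region cannot be renormalized; it is
    kept as a zero vector and flagged in ``degenerate``."""
    node_indices = np.asarray(node_indices, dtype=int)
    if node_indices.size == 0:
        raise ValueError("empty node selection")
    if node_indices.min() < 0 or node_indices.max() >= modes.n_nodes:
        raise IndexError("node index outside the mode set's node order")
    comp = (3 * node_indices[:, None] + np.arange(3)).ravel()
    sub = modes.vectors[comp, :]
    norms = np.linalg.norm(sub, axis=0)
    degenerate = norms < zero_norm_tol
    safe = np.where(degenerate, 1.0, norms)
    restricted = sub / safe
    restricted[:, degenerate] = 0.0
    return ModeSet(
        restricted,
        modes.eigenvalues.copy(),
        modes.node_map[node_indices],
        modes.n_zero_modes_removed,
        degenerate | modes.degenerate,
    )
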