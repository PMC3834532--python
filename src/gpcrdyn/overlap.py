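"""Subspace overlap between PCA and ANM mode sets.

Single-mode overlaps are absolute inner products O_ij = |p_i . u_j| of
normalized eigenvectors. Agreement between the leading k-dimensional
subspaces is the average overlap (RMSIP),

    O_ave = sqrt( (1/k) * sum_{i<=k} sum_{j<=k} (p_i . u_j)^2 ),

which is 1 exactly when the two k-subspaces coincide and 0 when they are
orthogonal; k = 10 is the conventional choice for collective subspaces.
Region-restricted variants (e.g. a loop plus the adjacent helix end)
restrict both vector sets to the region's components and renormalize before
taking inner products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anm import ModeSet, restrict_modes
from .essential import PCAResult

__all__ = ["OverlapMatrix", "overlap_matrix", "average_overlap", "region_overlap"]

DEFAULT_K = 10


@dataclass
class OverlapMatrix:
    """|p_i . u_j| for all mode pairs; NaN marks pairs where a restricted
    vector had zero norm (overlap undefined)."""

    values: np.ndarray
    row_labels: np.ndarray
    col_labels: np.ndarray
    k: int = DEFAULT_K

    def __post_init__(self):
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1.0 + 1e-9):
            raise ValueError("overlap entries must lie in [0, 1]")


def _as_columns(modes) -> np.ndarray:
    """Mode vectors as unit-norm columns from a ModeSet, PCAResult or array
    (accepts (dim, m) columns or (m, dim) rows)."""
    if isinstance(modes, ModeSet):
        return modes.vectors
    if isinstance(modes, PCAResult):
        return modes.eigenvectors
    arr = np.asarray(modes, dtype=float)
    if arr.ndim != 2:
        raise ValueError("mode set must be 2-D")
    if arr.shape[0] < arr.shape[1]:
        arr = arr.T
    return arr


def overlap_matrix(P, U) -> OverlapMatrix:
    """Absolute inner products between two mode sets of equal dimension."""
    p = _as_columns(P)
    u = _as_columns(U)
    if p.shape[0] != u.shape[0]:
        raise ValueError(
            f"mode dimensions differ ({p.shape[0]} vs {u.shape[0]}); restrict "
            "both sets to a common node selection first (restrict_modes)"
        )
    values = np.abs(p.T @ u)
    p_zero = np.linalg.norm(p, axis=0) < 1e-12
    u_zero = np.linalg.norm(u, axis=0) < 1e-12
    if p_zero.any():
        values[p_zero, :] = np.nan
    if u_zero.any():
        values[:, u_zero] = np.nan
    return OverlapMatrix(
        values,
        np.arange(1, p.shape[1] + 1),
        np.arange(1, u.shape[1] + 1),
    )


def average_overlap(P, U, k: int = DEFAULT_K, literal: bool = False) -> float:
    """Average overlap (RMSIP) over the first k modes of each set.

    ``literal=True`` computes the variant with 1/k outside the square root,
    sqrt(sum (p_i . u_j)^2) / k, which caps identical subspaces at
    1/sqrt(k) instead of 1.
    """
    p = _as_columns(P)
    u = _as_columns(U)
    if k < 1:
        raise ValueError("k must be at least 1")
    if p.shape[1] < k or u.shape[1] < k:
        raise ValueError(
            f"both mode sets need at least k={k} modes "
            f"(have {p.shape[1]} and {u.shape[1]})"
        )
    matrix = overlap_matrix(p[:, :k], u[:, :k]).values
    if np.isnan(matrix).any():
        raise ValueError("overlap undefined: zero-norm mode among the first k")
    total = float(np.sum(matrix**2))
    if literal:
        return np.sqrt(total) / k
    return float(np.sqrt(total / k))


def region_overlap(P, U, node_indices: np.ndarray, k: int = DEFAULT_K) -> OverlapMatrix:
    """Overlap matrix after restricting both mode sets to the components of
    ``node_indices`` (indices into each set's node order) and renormalizing.
    Modes with zero norm on the region yield NaN rows/columns."""
    node_indices = np.asarray(node_indices, dtype=int)
    if node_indices.size == 0:
        raise ValueError("empty region")
    restricted = []
    for modes in (P, U):
        cols = _as_columns(modes)
        ms = modes if isinstance(modes, ModeSet) else ModeSet(
            cols, np.zeros(cols.shape[1]), np.arange(cols.shape[0] // 3)
        )
        restricted.append(restrict_modes(ms, node_indices))
    out = overlap_matrix(restricted[0], restricted[1])
    out.k = k
    return out
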