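"""Coarse-grained membrane slab and typed protein+membrane network.

The membrane is a slab of spheres on an FCC lattice (diameter 80 A,
thickness 33 A by default) clipped to a cylinder around the z axis. The
protein's C-alpha nodes are embedded after centering its transmembrane
region at the slab center with the principal axis along z; membrane nodes
clashing with the protein are removed. Springs connect node pairs within a
cutoff (11 A default) with force constants by contact type:
protein-protein 1.0, protein-membrane 2.0, membrane-membrane 4.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structures import Structure, select

__all__ = [
    "Node",
    "Network",
    "DEFAULT_GAMMAS",
    "build_fcc_slab",
    "embed",
]

logger = logging.getLogger(__name__)

PROTEIN = "protein"
MEMBRANE = "membrane"

#: force constants by unordered contact type
DEFAULT_GAMMAS: dict[tuple[str, str], float] = {
    (PROTEIN, PROTEIN): 1.0,
    (PROTEIN, MEMBRANE): 2.0,
    (MEMBRANE, MEMBRANE): 4.0,
}
DEFAULT_CUTOFF = 11.0  # A


@dataclass(frozen=True)
class Node:
    """One network node: a protein C-alpha or a membrane sphere."""

    coords: tuple[float, float, float]
    node_type: str  # PROTEIN or MEMBRANE
    source: int     # residue_index for protein, lattice index for membrane


@dataclass
class Network:
    """Typed node set with spring topology parameters."""

    nodes: list[Node]
    cutoff: float = DEFAULT_CUTOFF
    gamma_map: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_GAMMAS)
    )

    @property
    def coords(self) -> np.ndarray:
        return np.array([n.coords for n in self.nodes], dtype=float)

    @property
    def node_types(self) -> np.ndarray:
        return np.array([n.node_type for n in self.nodes])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def protein_indices(self) -> np.ndarray:
        return np.array(
            [i for i, n in enumerate(self.nodes) if n.node_type == PROTEIN], dtype=int
        )

    def gamma(self, type_a: str, type_b: str) -> float:
        key = (type_a, type_b)
        if key in self.gamma_map:
            return self.gamma_map[key]
        return self.gamma_map[(type_b, type_a)]

    def spring_pairs(self) -> np.ndarray:
        """(n_springs, 2) unique node index pairs (i < j) within cutoff."""
        tree = cKDTree(self.coords)
        pairs = tree.query_pairs(self.cutoff, output_type="ndarray")
        return pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]

    def is_connected(self) -> bool:
        pairs = self.spring_pairs()
        n = self.n_nodes
        if n == 0:
            return False
        data = np.ones(len(pairs))
        adj = csr_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        n_comp, _ = connected_components(adj, directed=False)
        return n_comp == 1


def build_fcc_slab(diameter: float = 80.0, thickness: float = 33.0,
                   nn_spacing: float = 8.0) -> list[Node]:
    """Membrane spheres on an FCC lattice clipped to a cylinder (axis z) of
    the given diameter and a slab of the given thickness, centered at the
    origin. Nearest-neighbor distance is ``nn_spacing`` exactly
    (conventional cubic cell a = nn_spacing * sqrt(2))."""
    if diameter <= 0 or thickness <= 0 or nn_spacing <= 0:
        raise ValueError("diameter, thickness and nn_spacing must be positive")
    if nn_spacing >= diameter:
        raise ValueError(
            f"nn_spacing {nn_spacing} A must be smaller than the slab "
            f"diameter {diameter} A"
        )
    half = nn_spacing / np.sqrt(2.0)  # a/2: FCC sites are even-parity multiples
    radius = diameter / 2.0
    zmax = thickness / 2.0
    imax = int(np.floor(radius / half))
    kmax = int(np.floor(zmax / half))
    rng_i = np.arange(-imax, imax + 1)
    rng_k = np.arange(-kmax, kmax + 1)
    ii, jj, kk = np.meshgrid(rng_i, rng_i, rng_k, indexing="ij")
    parity = (ii + jj + kk) % 2 == 0
    x, y, z = ii * half, jj * half, kk * half
    inside = parity & (x**2 + y**2 <= radius**2 + 1e-9) & (np.abs(z) <= zmax + 1e-9)
    pts = np.stack([x[inside], y[inside], z[inside]], axis=1)
    return [
        Node(tuple(p), MEMBRANE, lattice_index)
        for lattice_index, p in enumerate(pts)
    ]


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """Unit eigenvector of largest covariance eigenvalue, z-positive."""
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, -1]
    if axis[2] < 0:
        axis = -axis
    return axis


def orient_protein(protein: Structure, z_center_region: str = "TMEMB",
                   tilt_deg: float = 0.0) -> Structure:
    """Translate/rotate the protein so the named region's C-alpha centroid
    sits at the origin and its principal axis lies along z (optionally tilted
    by ``tilt_deg`` about the x axis)."""
    idx = select(protein, z_center_region, "CA")
    coords = protein.coords
    region = coords[idx]
    centroid = region.mean(axis=0)
    axis = _principal_axis(region)
    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [axis])
    oriented = rot.apply(coords - centroid)
    if tilt_deg:
        oriented = Rotation.from_euler("x", tilt_deg, degrees=True).apply(oriented)
    return protein.with_coords(oriented)


def embed(protein: Structure, slab: list[Node], clash_radius: float = 4.0,
          z_center_region: str = "TMEMB", cutoff: float = DEFAULT_CUTOFF,
          gamma_map: dict[tuple[str, str], float] | None = None,
          orient: bool = True, tilt_deg: float = 0.0) -> Network:
    """Embed the protein in the membrane slab and return the typed network.

    Protein nodes are the C-alpha atoms. Membrane nodes within
    ``clash_radius`` of any protein node are removed. Raises if the
    resulting network is not a single connected component at ``cutoff``.
    """
    if orient:
        protein = orient_protein(protein, z_center_region, tilt_deg)
    ca_idx = select(protein, "ALL", "CA")
    coords = protein.coords[ca_idx]
    protein_nodes = [
        Node(tuple(coords[k]), PROTEIN, protein.atoms[i].residue_index)
        for k, i in enumerate(ca_idx)
    ]
    slab_coords = np.array([n.coords for n in slab], dtype=float)
    keep = np.ones(len(slab), dtype=bool)
    if len(slab) and len(coords):
        tree = cKDTree(coords)
        dmin, _ = tree.query(slab_coords, k=1)
        keep = dmin > clash_radius
    removed = int((~keep).sum())
    logger.info("embed: removed %d of %d membrane nodes within %.1f A of the protein",
                removed, len(slab), clash_radius)
    nodes = protein_nodes + [n for n, k in zip(slab, keep) if k]
    network = Network(nodes, cutoff, dict(gamma_map or DEFAULT_GAMMAS))
    if not network.is_connected():
        raise ValueError(
            "embedded network is not a single connected component at cutoff "
            f"{cutoff} A; decrease lattice spacing or increase the cutoff"
        )
    return network
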