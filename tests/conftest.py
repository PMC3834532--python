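"""Shared fixtures: toy structures and the (expensive) membrane-embedded
network with its normal modes, built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from gpcrdyn.anm import build_hessian, restrict_modes, solve_modes
from gpcrdyn.membrane import build_fcc_slab, embed
from gpcrdyn.structures import AtomRecord, Structure, Trajectory
from gpcrdyn.synthetic import SyntheticSpec, make_bundle


@pytest.fixture(scope="session")
def bundle() -> Structure:
    """The default 330-residue 7-helix bundle with a 32-residue loop."""
    return make_bundle(SyntheticSpec())


@pytest.fixture(scope="session")
def membrane_system(bundle):
    """Membrane-embedded network with its 20 slowest modes and their
    protein-restricted versions (shared: the eigensolve is the slow part)."""
    network = embed(bundle, build_fcc_slab())
    hessian = build_hessian(network)
    modes = solve_modes(hessian, n_modes=20)
    protein_modes = restrict_modes(modes, network.protein_indices())
    return {"network": network, "hessian": hessian, "modes": modes,
            "protein_modes": protein_modes}


def make_toy_structure(n_residues: int = 10, spacing: float = 3.8,
                       regions: dict | None = None) -> Structure:
    """Non-collinear CA-only chain with optional regions."""
    rng = np.random.default_rng(42)
    coords = np.cumsum(
        spacing * _unit_rows(rng.normal(size=(n_residues, 3))), axis=0
    )
    atoms = [
        AtomRecord(i + 1, "ALA", "CA", "A", tuple(coords[i]))
        for i in range(n_residues)
    ]
    return Structure(atoms, regions or {})


def _unit_rows(x: np.ndarray) -> np.ndarray:
    return x / np.linalg.norm(x, axis=1, keepdims=True)


def make_static_trajectory(structure: Structure, n_frames: int = 5) -> Trajectory:
    frames = np.repeat(structure.coords[None], n_frames, axis=0)
    times = 0.2 * np.arange(n_frames)
    return Trajectory(list(structure.atoms), frames, times, dict(structure.regions))
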