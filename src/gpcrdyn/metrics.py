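"""Per-frame trajectory observables.

Region-fitted RMSD profiles (the fit region used for superposition and the
measured region may differ, e.g. loop RMSD after core-region alignment),
windowed per-residue RMSF about the window's average structure, atom-pair
distance profiles, center-of-mass axis offsets between regions, ionic-lock
style minimum side-chain distances, and signed side-chain dihedrals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .essential import apply_transform, kabsch_superpose
from .structures import Structure, Trajectory, atom_index, select

__all__ = [
    "Profile",
    "RMSFTable",
    "rmsd_profile",
    "rmsf",
    "distance_profile",
    "com_offset_profile",
    "ionic_lock_profile",
    "dihedral_profile",
]


@dataclass
class Profile:
    """A per-frame scalar series with its metric descriptor."""

    times: np.ndarray
    values: np.ndarray
    kind: str
    units: str = "A"
    descriptor: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")


@dataclass
class RMSFTable:
    """Per-residue RMSF (A) about the average structure of a time window."""

    residue_indices: np.ndarray
    values: np.ndarray
    window: tuple[float, float]
    fit_region: str


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    diff = a - b
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def rmsd_profile(traj: Trajectory, reference: Structure | int,
                 fit_region: str = "ALL", measure_region: str = "ALL") -> Profile:
    """Per-frame C-alpha RMSD over ``measure_region`` after superposing each
    frame onto the reference using ``fit_region`` atoms only.

    The reference is a frame index or a Structure sharing the atom table
    (e.g. an alternative, inactive- or active-state conformation).
    """
    fit_idx = select(traj, fit_region, "CA")
    measure_idx = select(traj, measure_region, "CA")
    if isinstance(reference, Structure):
        ref = reference.coords
        if ref.shape != traj.frames[0].shape:
            raise ValueError("reference atom table does not match the trajectory")
    else:
        ref = traj.frames[int(reference)]
    values = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(traj.frames[t], ref, fit_idx)
        moved = apply_transform(traj.frames[t][measure_idx], rot, trans)
        values[t] = _rmsd(moved, ref[measure_idx])
    return Profile(traj.times, values, "rmsd", "A",
                   {"fit_region": fit_region, "measure_region": measure_region})


def rmsf(traj: Trajectory, fit_region: str = "ALL",
         window: tuple[float, float] | None = None) -> RMSFTable:
    """Per-residue C-alpha RMSF over a time window (ns, inclusive).

    Frames in the window are superposed onto the first window frame using
    ``fit_region``; fluctuations are about the window's average structure:
    RMSF_i = sqrt(<|x_i - <x_i>|^2>).
    """
    if window is None:
        window = (float(traj.times[0]), float(traj.times[-1]))
    mask = (traj.times >= window[0]) & (traj.times <= window[1])
    if not mask.any():
        raise ValueError(f"no frames in time window {window}")
    fit_idx = select(traj, fit_region, "CA")
    ca_idx = select(traj, "ALL", "CA")
    frames = traj.frames[mask]
    ref = frames[0]
    aligned = np.empty((frames.shape[0], ca_idx.size, 3))
    for t in range(frames.shape[0]):
        rot, trans, _ = kabsch_superpose(frames[t], ref, fit_idx)
        aligned[t] = apply_transform(frames[t][ca_idx], rot, trans)
    mean = aligned.mean(axis=0)
    values = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
    residues = np.array([traj.atom_table[i].residue_index for i in ca_idx])
    return RMSFTable(residues, values, window, fit_region)


def distance_profile(traj: Trajectory, atom_a: tuple[int, str],
                     atom_b: tuple[int, str]) -> Profile:
    """Euclidean distance between two named atoms, per frame.

    Computed on raw coordinates — invariant under any per-frame rigid
    motion, so no superposition is involved.
    """
    ia = atom_index(traj, *atom_a)
    ib = atom_index(traj, *atom_b)
    diff = traj.frames[:, ia, :] - traj.frames[:, ib, :]
    values = np.linalg.norm(diff, axis=1)
    return Profile(traj.times, values, "distance", "A",
                   {"atom_a": atom_a, "atom_b": atom_b})


def com_offset_profile(traj: Trajectory, region_a: str, region_b: str,
                       axis: str = "x") -> Profile:
    """Per-frame difference along one axis between the C-alpha centroids of
    two regions (COM_axis(a) - COM_axis(b)).

    Axis offsets are only meaningful in a common laboratory frame: align the
    trajectory (e.g. on the core region to its initial frame) first.
    """
    try:
        col = {"x": 0, "y": 1, "z": 2}[axis]
    except KeyError:
        raise ValueError(f"axis must be x, y or z, got {axis!r}") from None
    ia = select(traj, region_a, "CA")
    ib = select(traj, region_b, "CA")
    values = (traj.frames[:, ia, col].mean(axis=1)
              - traj.frames[:, ib, col].mean(axis=1))
    return Profile(traj.times, values, "com_offset", "A",
                   {"region_a": region_a, "region_b": region_b, "axis": axis})


def ionic_lock_profile(traj: Trajectory, donor_residue: int, acceptor_residue: int,
                       donor_atoms: tuple[str, ...] = ("NH1", "NH2", "NE"),
                       acceptor_atoms: tuple[str, ...] = ("OE1", "OE2"),
                       ) -> tuple[Profile, Profile]:
    """Salt-bridge distance: per-frame minimum over all donor-nitrogen /
    acceptor-oxygen pairs (guanidinium x carboxylate by default), plus the
    companion C-alpha-C-alpha backbone distance of the two residues."""
    d_idx = [atom_index(traj, donor_residue, a) for a in donor_atoms]
    a_idx = [atom_index(traj, acceptor_residue, a) for a in acceptor_atoms]
    diffs = (traj.frames[:, d_idx, None, :] - traj.frames[:, None, a_idx, :])
    dists = np.linalg.norm(diffs, axis=3)
    values = dists.reshape(traj.n_frames, -1).min(axis=1)
    lock = Profile(traj.times, values, "ionic_lock", "A",
                   {"donor": donor_residue, "acceptor": acceptor_residue,
                    "donor_atoms": donor_atoms, "acceptor_atoms": acceptor_atoms})
    backbone = distance_profile(traj, (donor_residue, "CA"), (acceptor_residue, "CA"))
    return lock, backbone


def dihedral_profile(traj: Trajectory, residue: int,
                     atom_names: tuple[str, str, str, str]) -> Profile:
    """Standard signed dihedral (degrees, in (-180, 180]) over four named
    atoms of one residue, per frame; 0 is cis, 180 is trans."""
    if len(atom_names) != 4:
        raise ValueError("exactly four atom names required")
    idx = [atom_index(traj, residue, a) for a in atom_names]
    p = traj.frames[:, idx, :]
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    # sign convention: positive when det(b1, b2, b3) > 0 (IUPAC)
    m1 = np.cross(b2 / np.linalg.norm(b2, axis=1, keepdims=True), n1)
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(m1 * n2, axis=1)
    angles = np.degrees(np.arctan2(y, x))
    angles[angles <= -180.0] += 360.0
    return Profile(traj.times, angles, "dihedral", "deg",
                   {"residue": residue, "atoms": atom_names})
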