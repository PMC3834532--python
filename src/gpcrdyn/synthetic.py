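"""Synthetic receptor bundles and trajectories with known ground truth.

The generator stands in for undeposited MD data: an idealized 7-helix
transmembrane bundle with a long flexible intracellular loop, and
trajectories built from planted orthonormal collective modes with prescribed
variances, an optional two-state (or multi-state) mean shift at a prescribed
frame, isotropic per-atom Gaussian noise, and per-frame rigid-body jitter:

    x_t = x_ref + s(t) * state_shift + sum_k a_k(t) * mode_k + eps_t,

with a_k(t) ~ N(0, variance_k) and s(t) a step function. Every analysis
stage (alignment, PCA, mode overlap, metrics, clustering) can therefore be
checked against the planted truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .structures import AtomRecord, Structure, Trajectory, resolve_regions

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "DEFAULT_HELIX_LAYOUT",
    "DEFAULT_LOOP_RANGE",
    "default_region_config",
    "make_bundle",
    "make_trajectory",
    "default_planted_modes",
    "default_state_shift",
]

# Ideal C-alpha trace geometry
_HELIX_RISE = 1.5          # A per residue along the axis
_HELIX_TWIST = np.deg2rad(100.0)
_HELIX_RADIUS = 2.3        # A, C-alpha distance from helix axis
_CA_SPACING = 3.8          # A, consecutive C-alpha distance
_BUNDLE_RADIUS = 12.0      # A, helix axes sit on this circle

#: 7 transmembrane helices; the flexible loop (ICL3 stand-in) spans 231-262
#: and the helix that follows it contains the 267-282 intracellular segment,
#: so the receptor's published residue numbering applies verbatim.
DEFAULT_HELIX_LAYOUT: tuple[tuple[int, int], ...] = (
    (8, 41), (50, 83), (92, 125), (134, 167), (201, 230), (263, 292), (300, 329),
)
DEFAULT_LOOP_RANGE: tuple[int, int] = (231, 262)
DEFAULT_N_RESIDUES = 330


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic system and trajectory.

    ``transition_frame``/``state_shift`` may be a single value (two-state
    trajectory) or equal-length lists (multi-state: each shift is added to
    the mean from its frame onward).
    """

    n_residues: int = DEFAULT_N_RESIDUES
    helix_layout: tuple[tuple[int, int], ...] = DEFAULT_HELIX_LAYOUT
    loop_range: tuple[int, int] = DEFAULT_LOOP_RANGE
    planted_modes: np.ndarray | None = None      # (n_modes, 3*n_atoms)
    mode_variances: np.ndarray | None = None     # A^2, nonincreasing
    transition_frame: int | list[int] | None = None
    state_shift: np.ndarray | list[np.ndarray] | None = None  # (3*n_atoms,) A
    noise_sd: float = 0.3                        # A, isotropic per coordinate
    rigid_jitter: tuple[float, float] = (0.0, 0.0)  # max rotation deg, max translation A
    n_frames: int = 1000
    frame_interval: float = 0.2                  # ns between frames
    seed: int = 0

    def __post_init__(self):
        for start, end in self.helix_layout:
            if not (1 <= start <= end <= self.n_residues):
                raise ValueError(f"helix range ({start}, {end}) outside 1..{self.n_residues}")
        spans = sorted(self.helix_layout)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping helix ranges ({s1},{e1}) and ({s2},{e2})")
        if self.mode_variances is not None:
            v = np.asarray(self.mode_variances, dtype=float)
            if np.any(v <= 0) or np.any(np.diff(v) > 0):
                raise ValueError("mode variances must be positive and nonincreasing")
        for f in self._transition_events():
            if not 0 <= f < self.n_frames:
                raise ValueError(f"transition_frame {f} outside 0..{self.n_frames - 1}")

    def _transition_events(self) -> list[int]:
        if self.transition_frame is None:
            return []
        if isinstance(self.transition_frame, (list, tuple)):
            return [int(f) for f in self.transition_frame]
        return [int(self.transition_frame)]

    def _shift_vectors(self) -> list[np.ndarray]:
        if self.state_shift is None:
            return []
        if isinstance(self.state_shift, (list, tuple)):
            return [np.asarray(s, dtype=float) for s in self.state_shift]
        return [np.asarray(self.state_shift, dtype=float)]


@dataclass
class GroundTruth:
    """The spec plus the noise-free coordinates before rigid jitter."""

    spec: SyntheticSpec
    noise_free: np.ndarray   # (n_frames, 3*n_atoms), A
    state_labels: np.ndarray  # (n_frames,), 0 before the first transition

    def to_json(self, path: str | Path) -> None:
        spec = self.spec
        payload = {
            "seed": spec.seed,
            "n_residues": spec.n_residues,
            "n_frames": spec.n_frames,
            "noise_sd": spec.noise_sd,
            "rigid_jitter": list(spec.rigid_jitter),
            "helix_layout": [list(h) for h in spec.helix_layout],
            "loop_range": list(spec.loop_range),
            "transition_frames": spec._transition_events(),
            "mode_variances": (
                None if spec.mode_variances is None
                else np.asarray(spec.mode_variances, dtype=float).tolist()
            ),
            "planted_modes": (
                None if spec.planted_modes is None
                else np.asarray(spec.planted_modes, dtype=float).tolist()
            ),
            "state_shifts": [s.tolist() for s in spec._shift_vectors()],
            "state_labels": self.state_labels.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def default_region_config(
    helix_layout: tuple[tuple[int, int], ...] = DEFAULT_HELIX_LAYOUT,
    loop_range: tuple[int, int] = DEFAULT_LOOP_RANGE,
    extra: dict[str, object] | None = None,
) -> dict[str, object]:
    """Raw region config for a bundle: TM1..TM7, TMEMB, ICL3, CORE, and
    (for the default layout) TM6_lower, ICL2 and ECL2."""
    config: dict[str, object] = {}
    for i, (start, end) in enumerate(helix_layout, start=1):
        config[f"TM{i}"] = [start, end]
    config["TMEMB"] = " + ".join(f"TM{i}" for i in range(1, len(helix_layout) + 1))
    config["ICL3"] = list(loop_range)
    config["CORE"] = "ALL - ICL3"
    if helix_layout == DEFAULT_HELIX_LAYOUT:
        config.setdefault("TM6_lower", [267, 282])
        config.setdefault("ICL2", [126, 133])
        config.setdefault("ECL2", [168, 200])
        config.setdefault("INTRA", "ICL3 + TM6_lower")
    if extra:
        config.update(extra)
    return config


# ---------------------------------------------------------------------------
# Geometry


def _arc_points(a: np.ndarray, b: np.ndarray, n_interior: int,
                bulge_dir: np.ndarray, spacing: float = _CA_SPACING) -> np.ndarray:
    """Interior points of a circular arc from a to b such that all
    ``n_interior + 1`` consecutive chords have length ``spacing`` exactly."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if n_interior == 0:
        return np.empty((0, 3))
    m = n_interior + 1          # number of chords
    d = float(np.linalg.norm(b - a))
    if d >= m * spacing * (1 - 1e-9):
        if d > m * spacing * (1 + 1e-9):
            raise ValueError(
                f"gap of {d:.2f} A cannot be bridged by {m} steps of {spacing} A"
            )
        ts = np.arange(1, m)[:, None] / m
        return a + ts * (b - a)

    def chord_gap(rho: float) -> float:
        theta = 2.0 * m * np.arcsin(spacing / (2.0 * rho))
        return 2.0 * rho * np.sin(theta / 2.0) - d

    rho_min = spacing / (2.0 * np.sin(np.pi / m))  # arc closes into a full circle
    rho = brentq(chord_gap, rho_min * (1 + 1e-12), 1e7, xtol=1e-10)
    theta = 2.0 * m * np.arcsin(spacing / (2.0 * rho))

    u = (b - a) / d
    w = bulge_dir - np.dot(bulge_dir, u) * u
    if np.linalg.norm(w) < 1e-8:  # bulge parallel to the chord: pick any normal
        w = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(w) < 1e-8:
            w = np.cross(u, [1.0, 0.0, 0.0])
    w /= np.linalg.norm(w)
    center = (a + b) / 2.0 - rho * np.cos(theta / 2.0) * w
    phis = -theta / 2.0 + theta * np.arange(1, m) / m
    points = center + rho * (np.sin(phis)[:, None] * u + np.cos(phis)[:, None] * w)
    # Small out-of-plane wiggle: a strictly planar chain is a zero-energy
    # mechanism for a distance-based elastic network, so break planarity.
    # Offsets are normal to the arc plane, so each chord grows from
    # ``spacing`` to at most sqrt(spacing^2 + max|delta|^2) ~ spacing + 0.08 A.
    normal = np.cross(u, w)
    j = np.arange(m + 1)
    offsets = 0.45 * np.sin(np.pi * j / m) * np.sin(2.1 * j + 0.8)
    return points + offsets[1:m, None] * normal


def _tail_points(base: np.ndarray, tangent: np.ndarray, n: int) -> np.ndarray:
    """``n`` points of a compact coil leaving ``base`` along ``tangent``.

    A straight (or gently bent) tail touches only its +-1/+-2 sequence
    neighbors — two springs per three degrees of freedom — and is therefore
    a floppy mechanism in a distance-based network. A tight coil brings
    nodes on adjacent turns within the interaction cutoff, which rigidifies
    the tail. Consecutive spacing stays in the ideal C-alpha band.
    """
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, tangent)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u1 = np.cross(tangent, ref)
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(tangent, u1)
    axial, radius, turn = 1.9, 2.1, np.deg2rad(100.0)
    k = np.arange(1, n + 1)
    pts = (base
           + axial * k[:, None] * tangent
           + radius * (np.cos(turn * k) - 1.0)[:, None] * u1
           + radius * np.sin(turn * k)[:, None] * u2)
    return pts


def _loop_points(a: np.ndarray, b: np.ndarray, n_interior: int,
                 bulge_dir: np.ndarray) -> np.ndarray:
    """Interior points of a compact loop from a to b with all consecutive
    C-alpha distances in the ideal band.

    Short gaps use a single tight arc. Long gaps are laid out as a
    serpentine of tight sub-arcs through meandering waypoints, so that loop
    residues pick up cross-strand contacts within the elastic-network
    cutoff instead of dangling as an underconstrained filament.
    """
    n_seg = max(1, int(round((n_interior + 1) / 8)))
    if n_seg == 1 or n_interior < 2 * n_seg:
        return _arc_points(a, b, n_interior, bulge_dir)
    chord = b - a
    d = np.linalg.norm(chord)
    u = chord / d
    w = bulge_dir - np.dot(bulge_dir, u) * u
    w /= np.linalg.norm(w)
    side = np.cross(u, w)
    total_len = _CA_SPACING * (n_interior + 1)
    amp = min(8.0, 0.12 * total_len)
    # m-1 waypoints are themselves residues; remaining residues split evenly
    n_way = n_seg - 1
    per_seg = np.full(n_seg, (n_interior - n_way) // n_seg)
    per_seg[: (n_interior - n_way) % n_seg] += 1
    frac = np.arange(1, n_seg) / n_seg
    waypoints = (a + frac[:, None] * chord
                 + amp * np.sin(np.pi * frac)[:, None] * w
                 + 0.8 * amp * (np.sin(np.pi * frac) * (-1.0) ** np.arange(1, n_seg))[:, None] * side)
    anchors = [a, *waypoints, b]
    points: list[np.ndarray] = []
    for i in range(n_seg):
        seg_bulge = (np.cos(1.1 * i) * w + np.sin(1.1 * i) * side)
        points.append(_arc_points(anchors[i], anchors[i + 1], per_seg[i], seg_bulge))
        if i < n_seg - 1:
            points.append(waypoints[i][None, :])
    return np.concatenate(points, axis=0)


# Side-chain pseudo-atom distances from the C-alpha (A)
_SIDECHAIN_LENGTH = {
    "CB": 1.53, "CG": 2.5, "CG1": 2.5, "CG2": 2.6, "OG": 2.4, "OG1": 2.4,
    "CD": 3.6, "SD": 3.6, "NE": 4.1, "CZ": 4.7, "OE1": 4.3, "OE2": 4.7,
    "OD1": 3.4, "OD2": 3.6, "NH1": 5.3, "NH2": 5.5, "NZ": 5.0,
}


def make_bundle(spec: SyntheticSpec,
                sidechain_map: dict[int, tuple[str, list[str]]] | None = None,
                region_config: dict[str, object] | None = None) -> Structure:
    """Build the idealized C-alpha bundle for ``spec``.

    Helices (rise 1.5 A/residue, 100 deg twist, radius 2.3 A) stand on a
    circle of radius 12 A with axes parallel to z, alternating up/down so
    that consecutive helices connect on opposite membrane faces; connecting
    loops are circular arcs with exact 3.8 A C-alpha spacing. The loop
    standing in for ICL3 dangles below the intracellular face.

    ``sidechain_map`` optionally adds named side-chain pseudo-atoms
    (residue_index -> (residue_name, [atom names])) at deterministic offsets
    from the C-alpha, for distance/dihedral/ionic-lock metrics.
    """
    helices = sorted(spec.helix_layout)
    n_hel = len(helices)
    coords = np.full((spec.n_residues, 3), np.nan)

    axis_angle = 2.0 * np.pi * np.arange(n_hel) / n_hel
    axes = _BUNDLE_RADIUS * np.stack(
        [np.cos(axis_angle), np.sin(axis_angle), np.zeros(n_hel)], axis=1
    )
    for h, (start, end) in enumerate(helices):
        n_res = end - start + 1
        direction = -1.0 if h % 2 == 0 else 1.0   # odd TMs run top -> bottom
        j = np.arange(n_res)
        z = direction * (j - (n_res - 1) / 2.0) * _HELIX_RISE
        phase = axis_angle[h] + j * _HELIX_TWIST
        coords[start - 1:end] = axes[h] + np.stack(
            [_HELIX_RADIUS * np.cos(phase), _HELIX_RADIUS * np.sin(phase), z],
            axis=1,
        )

    # connecting loops: arc bulging outward and away from the membrane face
    for h in range(n_hel - 1):
        end_prev, start_next = helices[h][1], helices[h + 1][0]
        n_loop = start_next - end_prev - 1
        if n_loop == 0:
            continue
        a, b = coords[end_prev - 1], coords[start_next - 1]
        mid = (a + b) / 2.0
        radial = mid * np.array([1.0, 1.0, 0.0])
        radial = radial / max(np.linalg.norm(radial), 1e-9)
        z_sign = np.sign(mid[2]) if abs(mid[2]) > 1e-9 else 1.0
        bulge = 0.6 * radial + np.array([0.0, 0.0, z_sign])
        bulge /= np.linalg.norm(bulge)
        coords[end_prev:start_next - 1] = _loop_points(a, b, n_loop, bulge)

    # terminal tails: gently helical continuation (a straight tail would be
    # a collinear chain — a zero-energy mechanism for the elastic network)
    first, last = helices[0][0], helices[-1][1]
    if first > 1:
        tangent = coords[first - 1] - coords[first]
        tangent /= np.linalg.norm(tangent)
        coords[:first - 1] = _tail_points(coords[first - 1], tangent, first - 1)[::-1]
    if last < spec.n_residues:
        tangent = coords[last - 1] - coords[last - 2]
        tangent /= np.linalg.norm(tangent)
        coords[last:] = _tail_points(coords[last - 1], tangent, spec.n_residues - last)

    if np.any(np.isnan(coords)):
        raise RuntimeError("bundle construction left unplaced residues")

    sidechain_map = sidechain_map or {}
    atoms: list[AtomRecord] = []
    for res in range(1, spec.n_residues + 1):
        ca = coords[res - 1]
        res_name, extra_atoms = sidechain_map.get(res, ("ALA", []))
        atoms.append(AtomRecord(res, res_name, "CA", "A", tuple(ca)))
        radial = ca * np.array([1.0, 1.0, 0.0])
        nrm = np.linalg.norm(radial)
        radial = radial / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        tangential = np.cross([0.0, 0.0, 1.0], radial)
        for k, name in enumerate(extra_atoms):
            length = _SIDECHAIN_LENGTH.get(name, 2.0 + 0.5 * k)
            ang = 0.6 * k
            offset = length * (np.cos(ang) * radial + np.sin(ang) * tangential)
            offset[2] += 0.45 * k - 0.9
            atoms.append(AtomRecord(res, res_name, name, "A", tuple(ca + offset)))

    if region_config is None:
        region_config = default_region_config(tuple(helices), spec.loop_range)
    regions = resolve_regions(region_config, set(range(1, spec.n_residues + 1)))
    return Structure(atoms, regions)


# ---------------------------------------------------------------------------
# Planted modes / shifts


def _loop_ca_indices(structure: Structure, loop_range: tuple[int, int]) -> np.ndarray:
    lo, hi = loop_range
    return np.array(
        [i for i, a in enumerate(structure.atoms)
         if a.atom_name == "CA" and lo <= a.residue_index <= hi],
        dtype=int,
    )


def default_planted_modes(structure: Structure, n_modes: int = 3,
                          loop_range: tuple[int, int] = DEFAULT_LOOP_RANGE) -> np.ndarray:
    """Orthonormal modes localized on the flexible loop: sinusoidal shapes of
    increasing wavenumber along the loop, cycling Cartesian directions, then
    orthonormalized. Deterministic."""
    idx = _loop_ca_indices(structure, loop_range)
    if idx.size == 0:
        raise ValueError("loop range selects no CA atoms")
    n_atoms = structure.n_atoms
    raw = np.zeros((n_modes, 3 * n_atoms))
    j = np.arange(1, idx.size + 1)
    for k in range(n_modes):
        shape = np.sin((k + 1) * np.pi * j / (idx.size + 1))
        raw[k, 3 * idx + (k % 3)] = shape
    q, _ = np.linalg.qr(raw.T)
    modes = q.T[:n_modes]
    # sign convention: largest-magnitude component positive
    for v in modes:
        if v[np.argmax(np.abs(v))] < 0:
            v *= -1
    return modes


def default_state_shift(structure: Structure, norm: float = 10.0,
                        loop_range: tuple[int, int] = DEFAULT_LOOP_RANGE,
                        helix_range: tuple[int, int] = (267, 282)) -> np.ndarray:
    """Mean shift emulating the loop packing under the receptor core coupled
    with an inward motion of the adjacent helix end: loop and lower-helix
    C-alphas move toward the bundle axis, with a smooth envelope, scaled to
    the requested 3N-norm (A)."""
    n_atoms = structure.n_atoms
    shift = np.zeros((n_atoms, 3))
    coords = structure.coords
    for (lo, hi), weight in ((loop_range, 1.0), (helix_range, 0.4)):
        idx = _loop_ca_indices(structure, (lo, hi))
        if idx.size == 0:
            continue
        j = np.arange(1, idx.size + 1)
        envelope = weight * np.sin(np.pi * j / (idx.size + 1))
        inward = -coords[idx] * [1.0, 1.0, 0.0]
        norms = np.linalg.norm(inward, axis=1, keepdims=True)
        inward = np.divide(inward, norms, out=np.zeros_like(inward), where=norms > 1e-9)
        shift[idx] += envelope[:, None] * inward
    flat = shift.ravel()
    total = np.linalg.norm(flat)
    if total < 1e-12:
        raise ValueError("state shift is identically zero")
    return flat * (norm / total)


# ---------------------------------------------------------------------------
# Trajectory generation


def make_trajectory(structure: Structure, spec: SyntheticSpec
                    ) -> tuple[Trajectory, GroundTruth]:
    """Sample a trajectory around ``structure`` per the planted model.

    Draw order from the single seeded generator is fixed (mode amplitudes,
    then noise, then per-frame jitter), so output is bit-reproducible from
    (spec, seed).
    """
    n_atoms = structure.n_atoms
    dim = 3 * n_atoms
    x0 = structure.coords.ravel()
    rng = np.random.default_rng(spec.seed)

    modes = spec.planted_modes
    variances = spec.mode_variances
    if (modes is None) != (variances is None):
        raise ValueError("planted_modes and mode_variances must be given together")
    if modes is not None:
        modes = np.atleast_2d(np.asarray(modes, dtype=float))
        variances = np.asarray(variances, dtype=float)
        if modes.shape[1] != dim:
            raise ValueError(
                f"planted modes have dimension {modes.shape[1]}, expected {dim}"
            )
        if len(variances) != len(modes):
            raise ValueError("one variance per planted mode required")
        gram = modes @ modes.T
        if not np.allclose(gram, np.eye(len(modes)), atol=1e-7):
            raise ValueError("planted modes must be mutually orthonormal")

    events = spec._transition_events()
    shifts = spec._shift_vectors()
    if len(events) != len(shifts):
        raise ValueError("transition_frame and state_shift counts differ")
    for s in shifts:
        if s.shape != (dim,):
            raise ValueError(f"state shift has shape {s.shape}, expected ({dim},)")

    n = spec.n_frames
    mean = np.tile(x0, (n, 1))
    labels = np.zeros(n, dtype=int)
    for frame, shift in sorted(zip(events, shifts)):
        mean[frame:] += shift
        labels[frame:] += 1

    noise_free = mean
    if modes is not None:
        amplitudes = rng.normal(0.0, np.sqrt(variances), size=(n, len(variances)))
        noise_free = noise_free + amplitudes @ modes

    frames = noise_free.copy()
    if spec.noise_sd > 0:
        frames += rng.normal(0.0, spec.noise_sd, size=(n, dim))

    frames = frames.reshape(n, n_atoms, 3)
    max_deg, max_trans = spec.rigid_jitter
    if max_deg > 0 or max_trans > 0:
        for t in range(n):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = np.deg2rad(rng.uniform(0.0, max_deg))
            rot = Rotation.from_rotvec(angle * axis)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            translation = rng.uniform(0.0, max_trans) * direction
            centroid = frames[t].mean(axis=0)
            frames[t] = rot.apply(frames[t] - centroid) + centroid + translation

    times = spec.frame_interval * np.arange(n)
    traj = Trajectory(list(structure.atoms), frames, times, dict(structure.regions))
    return traj, GroundTruth(spec, noise_free, labels)
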