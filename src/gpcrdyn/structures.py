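"""Structures, trajectories, named residue regions and atom selection.

Coordinates are C-alpha level (plus selected side-chain atoms) in Angstrom,
residue numbering is author/PDB numbering (1-based, inclusive ranges).
Structures and trajectories are read and written as fixed-width PDB text
(multi-model PDB for trajectories) through biotite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "PDBParseError",
    "RegionError",
    "load_region_config",
    "resolve_regions",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "select",
    "concatenate",
]

#: default sampling interval of trajectory frames when the file carries no
#: time information (ns); matches recording one snapshot every 200 ps.
DEFAULT_FRAME_INTERVAL_NS = 0.2


class PDBParseError(ValueError):
    """Raised for malformed or inconsistent PDB input."""


class RegionError(KeyError):
    """Raised for unknown regions or residues lacking a requested atom."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus position (Angstrom)."""

    residue_index: int
    residue_name: str
    atom_name: str
    chain_id: str
    coords: tuple[float, float, float]

    def __post_init__(self):
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for {self}")


def _check_unique(atoms: list[AtomRecord]) -> None:
    keys = [(a.chain_id, a.residue_index, a.atom_name) for a in atoms]
    if len(set(keys)) != len(keys):
        seen, dup = set(), None
        for k in keys:
            if k in seen:
                dup = k
                break
            seen.add(k)
        raise ValueError(f"duplicate atom (chain, residue, atom) = {dup}")


@dataclass
class Structure:
    """An ordered atom table with coordinates and named residue regions.

    ``regions`` maps a region name to the set of residue indices it covers.
    The pseudo-region ``"ALL"`` (every residue present) is always available
    through :func:`select` and need not be stored.
    """

    atoms: list[AtomRecord]
    regions: dict[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self):
        _check_unique(self.atoms)
        ca_residues = {a.residue_index for a in self.atoms if a.atom_name == "CA"}
        for name, residues in self.regions.items():
            missing = set(residues) - ca_residues
            if missing:
                raise RegionError(
                    f"region {name!r} names residues without a CA atom: "
                    f"{sorted(missing)[:5]}"
                )

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Angstrom."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float).reshape(len(self.atoms), 3)
        atoms = [
            AtomRecord(a.residue_index, a.residue_name, a.atom_name, a.chain_id,
                       tuple(xyz))
            for a, xyz in zip(self.atoms, coords)
        ]
        return Structure(atoms, dict(self.regions))


@dataclass
class Trajectory:
    """Ordered frames sharing one atom table, with per-frame times in ns."""

    atom_table: list[AtomRecord]
    frames: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    times: np.ndarray  # (n_frames,), ns
    regions: dict[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.atom_table):
            raise ValueError(
                f"frames shape {self.frames.shape} does not match the "
                f"{len(self.atom_table)}-atom table"
            )
        if self.times.shape != (self.frames.shape[0],):
            raise ValueError("times length must equal number of frames")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame_structure(self, index: int) -> Structure:
        """Materialize one frame as a Structure (shares the regions)."""
        base = Structure(list(self.atom_table), dict(self.regions))
        return base.with_coords(self.frames[index])

    def with_frames(self, frames: np.ndarray, times: np.ndarray | None = None) -> "Trajectory":
        return Trajectory(
            list(self.atom_table),
            frames,
            self.times if times is None else times,
            dict(self.regions),
        )


# ---------------------------------------------------------------------------
# Region configuration


def load_region_config(path: str | Path) -> dict[str, object]:
    """Read a YAML region config: name -> [start, end] range, list of ranges,
    explicit residue list, or an expression ``"ALL - <region>"`` /
    ``"<a> + <b>"`` combining previously defined regions."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"region config {path} must be a mapping")
    return raw


def resolve_regions(raw: dict[str, object], all_residues: set[int]) -> dict[str, frozenset[int]]:
    """Expand a raw region config into explicit residue sets.

    Ranges are inclusive on both ends. ``ALL`` refers to every residue in the
    structure; set arithmetic (``+`` union, ``-`` difference) over region
    names is evaluated after all literal regions.
    """
    regions: dict[str, frozenset[int]] = {}
    deferred: dict[str, str] = {}
    for name, value in raw.items():
        if isinstance(value, str):
            deferred[name] = value
        else:
            regions[name] = frozenset(_expand_literal(name, value))
    env = dict(regions)
    env["ALL"] = frozenset(all_residues)
    for name, expr in deferred.items():
        regions[name] = _eval_region_expr(name, expr, env)
        env[name] = regions[name]
    return regions


def _expand_literal(name: str, value) -> set[int]:
    if (isinstance(value, (list, tuple)) and len(value) == 2
            and all(isinstance(v, int) for v in value)):
        lo, hi = value
        return set(range(lo, hi + 1))
    if isinstance(value, (list, tuple)):
        out: set[int] = set()
        for item in value:
            if isinstance(item, int):
                out.add(item)
            elif isinstance(item, (list, tuple)) and len(item) == 2:
                out.update(range(item[0], item[1] + 1))
            else:
                raise ValueError(f"region {name!r}: cannot parse {item!r}")
        return out
    raise ValueError(f"region {name!r}: cannot parse {value!r}")


def _eval_region_expr(name: str, expr: str, env: dict[str, frozenset[int]]) -> frozenset[int]:
    tokens = expr.replace("+", " + ").replace("-", " - ").split()
    if not tokens:
        raise ValueError(f"region {name!r}: empty expression")
    result, op = frozenset(), "+"
    for tok in tokens:
        if tok in "+-":
            op = tok
            continue
        if tok not in env:
            raise RegionError(f"region {name!r}: unknown region {tok!r} in expression")
        result = result | env[tok] if op == "+" else result - env[tok]
    return result


# ---------------------------------------------------------------------------
# PDB input / output


def _scan_pdb_text(path: Path) -> list[int]:
    """Pre-scan PDB text: validate coordinate fields (reporting the line
    number on failure) and return the atom count of each MODEL."""
    counts: list[int] = []
    current = 0
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if in_model:
                    counts.append(current)
                in_model, current = True, 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model, current = False, 0
            elif rec in ("ATOM", "HETATM"):
                current += 1
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fieldtxt = line[lo:hi]
                    try:
                        float(fieldtxt)
                    except ValueError:
                        raise PDBParseError(
                            f"{path}, line {lineno}: malformed coordinate "
                            f"field {fieldtxt!r}"
                        ) from None
    if in_model or (not counts and current):
        counts.append(current)
    return counts


def _atom_array_to_records(arr: struc.AtomArray) -> list[AtomRecord]:
    return [
        AtomRecord(
            int(arr.res_id[i]),
            str(arr.res_name[i]),
            str(arr.atom_name[i]),
            str(arr.chain_id[i]) or "A",
            tuple(np.asarray(arr.coord[i], dtype=float)),
        )
        for i in range(arr.array_length())
    ]


def _require_ca(atoms: list[AtomRecord], path) -> None:
    by_res: dict[int, set[str]] = {}
    for a in atoms:
        by_res.setdefault(a.residue_index, set()).add(a.atom_name)
    for res, names in by_res.items():
        if "CA" not in names:
            raise PDBParseError(f"{path}: residue {res} has no CA atom")


def read_structure(path: str | Path, model_index: int = 1,
                   region_config: dict[str, object] | None = None) -> Structure:
    """Read one MODEL of a PDB file (1-based ``model_index``).

    Every residue must carry a CA atom. ``region_config`` (as from
    :func:`load_region_config`) attaches named regions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _scan_pdb_text(path)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if not 1 <= model_index <= n_models:
        raise PDBParseError(
            f"{path}: requested MODEL {model_index} but file has {n_models}"
        )
    arr = pdb.get_structure(model=model_index)
    atoms = _atom_array_to_records(arr)
    _require_ca(atoms, path)
    regions = {}
    if region_config is not None:
        regions = resolve_regions(region_config, {a.residue_index for a in atoms})
    return Structure(atoms, regions)


def read_trajectory(path: str | Path,
                    region_config: dict[str, object] | None = None,
                    times: np.ndarray | None = None,
                    frame_interval: float = DEFAULT_FRAME_INTERVAL_NS,
                    t0: float = 0.0) -> Trajectory:
    """Read a multi-model PDB as a trajectory.

    PDB files carry no time axis; frame times default to
    ``t0 + i * frame_interval`` (ns) unless ``times`` is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    counts = _scan_pdb_text(path)
    if len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts) if c != counts[0])
        raise PDBParseError(
            f"{path}: MODEL {bad + 1} has {counts[bad]} atoms, "
            f"expected {counts[0]}"
        )
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()  # AtomArrayStack
    arr0 = stack[0]
    atoms = _atom_array_to_records(arr0)
    _require_ca(atoms, path)
    frames = np.asarray(stack.coord, dtype=float)
    if times is None:
        times = t0 + frame_interval * np.arange(frames.shape[0])
    regions = {}
    if region_config is not None:
        regions = resolve_regions(region_config, {a.residue_index for a in atoms})
    return Trajectory(atoms, frames, np.asarray(times, dtype=float), regions)


_ELEMENT_FROM_NAME = {"C": "C", "N": "N", "O": "O", "S": "S", "M": "C"}


def _records_to_atom_array(atoms: list[AtomRecord], coords: np.ndarray) -> struc.AtomArray:
    n = len(atoms)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32).reshape(n, 3)
    arr.res_id = np.array([a.residue_index for a in atoms])
    arr.res_name = np.array([a.residue_name for a in atoms])
    arr.atom_name = np.array([a.atom_name for a in atoms])
    arr.chain_id = np.array([a.chain_id for a in atoms])
    arr.element = np.array(
        [_ELEMENT_FROM_NAME.get(a.atom_name[:1], "C") for a in atoms]
    )
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_structure(structure: Structure, path: str | Path) -> None:
    pdb = PDBFile()
    pdb.set_structure(_records_to_atom_array(structure.atoms, structure.coords))
    pdb.write(str(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    arrays = [_records_to_atom_array(traj.atom_table, f) for f in traj.frames]
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Selection


def select(obj: Structure | Trajectory, region_name: str, atom_name: str = "CA") -> np.ndarray:
    """Indices (into the atom table) of ``atom_name`` atoms of the region,
    sorted by residue index. ``"ALL"`` selects every residue."""
    atoms = obj.atoms if isinstance(obj, Structure) else obj.atom_table
    regions = obj.regions
    all_residues = {a.residue_index for a in atoms}
    if region_name == "ALL":
        residues = all_residues
    elif region_name in regions:
        residues = set(regions[region_name])
    else:
        raise RegionError(
            f"unknown region {region_name!r}; available: "
            f"{sorted(regions) + ['ALL']}"
        )
    hits = {a.residue_index: i for i, a in enumerate(atoms) if a.atom_name == atom_name}
    missing = residues - set(hits)
    if missing:
        raise RegionError(
            f"region {region_name!r}: residues {sorted(missing)[:5]} lack "
            f"atom {atom_name!r}"
        )
    return np.array([hits[r] for r in sorted(residues)], dtype=int)


def atom_index(obj: Structure | Trajectory, residue_index: int, atom_name: str) -> int:
    """Index of one named atom of one residue."""
    atoms = obj.atoms if isinstance(obj, Structure) else obj.atom_table
    for i, a in enumerate(atoms):
        if a.residue_index == residue_index and a.atom_name == atom_name:
            return i
    raise RegionError(f"no atom {atom_name!r} in residue {residue_index}")


def concatenate(trajs: list[Trajectory], names: list[str] | None = None
                ) -> tuple[Trajectory, np.ndarray, np.ndarray]:
    """Concatenate trajectories sharing one atom table.

    Returns (trajectory, source_names, source_frames) recording, for every
    output frame, which input it came from and its local frame index. Times
    are re-spaced to stay strictly increasing, preserving each input's step.
    """
    if not trajs:
        raise ValueError("no trajectories to concatenate")
    ref = trajs[0]
    for i, t in enumerate(trajs[1:], start=2):
        if len(t.atom_table) != len(ref.atom_table):
            raise ValueError(f"trajectory {i} has a different atom count")
    if names is None:
        names = [f"traj{i}" for i in range(1, len(trajs) + 1)]
    frames = np.concatenate([t.frames for t in trajs], axis=0)
    times, offset = [], 0.0
    for t in trajs:
        shifted = t.times - t.times[0] + offset
        times.append(shifted)
        step = np.median(np.diff(t.times)) if t.n_frames > 1 else DEFAULT_FRAME_INTERVAL_NS
        offset = shifted[-1] + step
    source_names = np.concatenate([[n] * t.n_frames for n, t in zip(names, trajs)])
    source_frames = np.concatenate([np.arange(t.n_frames) for t in trajs])
    out = Trajectory(list(ref.atom_table), frames, np.concatenate(times), dict(ref.regions))
    return out, source_names, source_frames
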