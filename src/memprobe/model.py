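"""Coordinate/topology data model, file I/O and periodic-geometry primitives.

The in-memory model is deliberately light: a flat list of :class:`AtomRecord`
(identity, residue, segment, analysis role) plus per-frame coordinate arrays.
Roles — which atoms count as "protein heavy", "lipid tail carbon",
"head group", "ligand" — drive every downstream analysis, so they are assigned
once, by explicit rules, and never inferred silently.

Units are Å and ns throughout; conversions happen only at reporting
boundaries.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

log = logging.getLogger("memprobe")

__all__ = [
    "Role",
    "AtomRecord",
    "Frame",
    "Trajectory",
    "SystemModel",
    "load_structure",
    "load_trajectory",
    "write_structure",
    "classify_atoms",
    "min_image_displacement",
    "min_image_distance",
    "DEFAULT_ROLE_RULES",
    "load_role_rules",
    "ELEMENT_MASSES",
]


class Role(str, Enum):
    PROTEIN_HEAVY = "protein_heavy"
    PROTEIN_HYDROGEN = "protein_hydrogen"
    LIPID_TAIL_CARBON = "lipid_tail_carbon"
    LIPID_HEADGROUP = "lipid_headgroup"
    LIGAND = "ligand"
    OTHER = "other"


# Average atomic masses (amu) for mass-weighted centres of mass.
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "NA": 22.990, "CL": 35.45, "K": 39.098, "MG": 24.305,
    "CA": 40.078, "ZN": 65.38, "F": 18.998,
}
_DEFAULT_MASS = 12.011

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP",
}


@dataclass
class AtomRecord:
    """One atom: identity, residue membership, segment class and analysis role."""

    atom_id: int
    name: str
    element: str
    residue_id: int
    residue_name: str
    segment: str = "other"  # protein | lipid | ligand | solvent | ion | other
    role: Role = Role.OTHER


@dataclass
class Frame:
    """Coordinates (Å) of every atom at one time point, with an orthorhombic box."""

    coordinates: np.ndarray  # (n_atoms, 3) Å
    box: np.ndarray | None = None  # three orthorhombic edge lengths, Å
    time: float = 0.0  # ns

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (n_atoms, 3) array")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if not np.all(self.box > 0):
                raise ValueError("box edges must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.coordinates)

    def copy(self) -> "Frame":
        return Frame(self.coordinates.copy(),
                     None if self.box is None else self.box.copy(),
                     self.time)


@dataclass
class Trajectory:
    """Uniformly spaced frame sequence; dt in ns (default 0.01 ns = 10 ps)."""

    frames: list[Frame]
    dt: float = 0.01

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")
        n = self.frames[0].n_atoms
        for f in self.frames:
            if f.n_atoms != n:
                raise ValueError("inconsistent atom counts across frames")
        times = np.array([f.time for f in self.frames])
        if len(times) > 1:
            spacing = np.diff(times)
            if np.any(spacing <= 0):
                raise ValueError("frame times must be strictly increasing")
            if np.any(np.abs(spacing - self.dt) > 1e-6):
                raise ValueError("frame times must be uniformly spaced at dt")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @classmethod
    def from_coords(cls, coords: np.ndarray, dt: float = 0.01,
                    box: np.ndarray | None = None) -> "Trajectory":
        coords = np.asarray(coords, dtype=float)
        frames = [Frame(c, box=box, time=i * dt) for i, c in enumerate(coords)]
        return cls(frames, dt=dt)

    def coordinate_array(self) -> np.ndarray:
        """Stacked (n_frames, n_atoms, 3) coordinate array."""
        return np.stack([f.coordinates for f in self.frames])


class SystemModel:
    """Atoms plus named atom-id groups ("protein", "PIP3", "POPC", ...)."""

    def __init__(self, atoms: Sequence[AtomRecord],
                 groups: Mapping[str, Iterable[int]] | None = None):
        self.atoms: list[AtomRecord] = list(atoms)
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise ValueError("atom_id values must be unique")
        self._id_to_index = {a.atom_id: i for i, a in enumerate(self.atoms)}
        self.groups: dict[str, set[int]] = {}
        for name, members in (groups or {}).items():
            self.set_group(name, members)

    # -- bookkeeping ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    def index_of(self, atom_id: int) -> int:
        return self._id_to_index[atom_id]

    def indices_of(self, atom_ids: Iterable[int]) -> np.ndarray:
        return np.array([self._id_to_index[i] for i in atom_ids], dtype=int)

    def set_group(self, name: str, atom_ids: Iterable[int]) -> None:
        members = set(int(i) for i in atom_ids)
        missing = members - set(self._id_to_index)
        if missing:
            raise ValueError(f"group {name!r} refers to unknown atom ids {sorted(missing)[:5]}")
        self.groups[name] = members

    def group_indices(self, name: str) -> np.ndarray:
        if name not in self.groups:
            raise KeyError(f"no group named {name!r}")
        return np.sort(self.indices_of(self.groups[name]))

    # -- derived arrays ---------------------------------------------------
    @property
    def names(self) -> np.ndarray:
        return np.array([a.name for a in self.atoms])

    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    @property
    def residue_ids(self) -> np.ndarray:
        return np.array([a.residue_id for a in self.atoms])

    @property
    def residue_names(self) -> np.ndarray:
        return np.array([a.residue_name for a in self.atoms])

    @property
    def roles(self) -> np.ndarray:
        return np.array([a.role.value for a in self.atoms])

    @property
    def segments(self) -> np.ndarray:
        return np.array([a.segment for a in self.atoms])

    @property
    def masses(self) -> np.ndarray:
        return np.array([ELEMENT_MASSES.get(a.element.upper(), _DEFAULT_MASS)
                         for a in self.atoms])

    def role_indices(self, role: Role | str) -> np.ndarray:
        value = role.value if isinstance(role, Role) else str(role)
        return np.flatnonzero(self.roles == value)

    def residues(self) -> list[tuple[int, str]]:
        """(residue_id, residue_name) pairs in order of first appearance."""
        seen: dict[int, str] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_id, a.residue_name)
        return list(seen.items())


# ---------------------------------------------------------------------------
# Role classification
# ---------------------------------------------------------------------------

# Rule table: list of dicts with residue-name patterns, a segment label and
# role → atom-name-pattern lists.  Patterns are full-match regexes.  The POPC
# tail rule labels the sn-1 (C31..C3x) and sn-2 (C21..C2x) acyl carbons
# *distal to the ester carbonyl* (C21/C31 excluded) as tail carbons; the
# pseudo-lipid rule matches the T* beads emitted by the synthetic generators.
DEFAULT_ROLE_RULES: list[dict] = [
    {
        "residues": sorted(_AMINO_ACIDS),
        "segment": "protein",
        "roles": {},  # element split handles heavy vs hydrogen
    },
    {
        "residues": ["POPC", "POPE", "POPG", "DPPC", "DOPC", "DMPC", "LIP"],
        "segment": "lipid",
        "roles": {
            "lipid_tail_carbon": [r"C2([2-9]|1[0-9])", r"C3([2-9]|1[0-9])",
                                  r"T[0-9]+"],
            "lipid_headgroup": [r"N", r"P", r"C1[1-5]", r"O1[1-4]",
                                r"C[123]", r"O[23][12]", r"H[DS]?"],
        },
    },
    {
        "residues": ["PIP3", "PIP2", "IP4", "I4P", "INS", "PI3P"],
        "segment": "ligand",
        "roles": {},
    },
    {
        "residues": ["HOH", "SOL", "WAT", "TIP3", "SPC"],
        "segment": "solvent",
        "roles": {},
    },
    {
        "residues": ["NA", "CL", "K", "MG", "CA", "ZN", "NA+", "CL-"],
        "segment": "ion",
        "roles": {},
    },
]


def load_role_rules(path: str | Path) -> list[dict]:
    """Read a YAML role-rule table (same structure as DEFAULT_ROLE_RULES)."""
    import yaml

    with open(path) as fh:
        rules = yaml.safe_load(fh)
    if not isinstance(rules, list):
        raise ValueError("role-rule file must contain a list of rule blocks")
    return rules


def _compile_rules(rules: list[dict]):
    compiled = []
    for rule in rules:
        residues = {r.upper() for r in rule.get("residues", [])}
        roles = {
            role: [re.compile(p) for p in pats]
            for role, pats in (rule.get("roles") or {}).items()
        }
        compiled.append((residues, rule.get("segment", "other"), roles))
    return compiled


def classify_atoms(system: SystemModel,
                   rules: list[dict] | None = None) -> SystemModel:
    """Assign segment and role to every atom from a (residue, atom-name) rule table.

    Pure function of (residue_name, atom_name, element): re-running with the
    same rules is a no-op.  Unknown residues are labelled role=other with a
    logged warning, never silently misclassified.  The lipid_tail_carbon role
    is only ever placed on carbon atoms.
    """
    compiled = _compile_rules(rules if rules is not None else DEFAULT_ROLE_RULES)
    unknown: set[str] = set()
    for atom in system.atoms:
        resname = atom.residue_name.upper()
        matched = False
        for residues, segment, roles in compiled:
            if resname not in residues:
                continue
            matched = True
            atom.segment = segment
            atom.role = Role.OTHER
            if segment == "protein":
                atom.role = (Role.PROTEIN_HYDROGEN if atom.element.upper() == "H"
                             else Role.PROTEIN_HEAVY)
            elif segment == "ligand":
                atom.role = Role.LIGAND
            for role_name, patterns in roles.items():
                if any(p.fullmatch(atom.name) for p in patterns):
                    role = Role(role_name)
                    if role is Role.LIPID_TAIL_CARBON and atom.element.upper() != "C":
                        continue  # tail-carbon role restricted to carbons
                    atom.role = role
                    break
            break
        if not matched:
            unknown.add(atom.residue_name)
            atom.segment = "other"
            atom.role = Role.OTHER
    if unknown:
        log.warning("no classification rule for residue(s) %s; assigned role=other",
                    ", ".join(sorted(unknown)))
    return system


# ---------------------------------------------------------------------------
# Periodic geometry
# ---------------------------------------------------------------------------

def min_image_displacement(a: np.ndarray, b: np.ndarray,
                           box: np.ndarray | None) -> np.ndarray:
    """Minimum-image displacement b→a under an orthorhombic box (broadcasts)."""
    delta = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if box is not None:
        box = np.asarray(box, dtype=float)
        delta = delta - box * np.round(delta / box)
    return delta


def min_image_distance(a: np.ndarray, b: np.ndarray,
                       box: np.ndarray | None) -> float | np.ndarray:
    """Minimum distance between a and b over all periodic images (Å)."""
    delta = min_image_displacement(a, b, box)
    return np.linalg.norm(delta, axis=-1)


def wrap_coordinates(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into [0, box) per axis."""
    return np.mod(coords, np.asarray(box, dtype=float))


# ---------------------------------------------------------------------------
# File I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _structure_to_system(atoms_struct, rules=None) -> SystemModel:
    import biotite.structure as struc

    records = []
    for i in range(atoms_struct.array_length()):
        element = str(atoms_struct.element[i]).strip()
        records.append(AtomRecord(
            atom_id=i + 1,
            name=str(atoms_struct.atom_name[i]).strip(),
            element=element if element else "C",
            residue_id=int(atoms_struct.res_id[i]),
            residue_name=str(atoms_struct.res_name[i]).strip(),
        ))
    system = SystemModel(records)
    classify_atoms(system, rules)
    return system


def _box_from_struct(atoms_struct) -> np.ndarray | None:
    box = atoms_struct.box
    if box is None:
        return None
    box = np.asarray(box, dtype=float)
    if box.ndim == 3:
        box = box[0]
    off_diag = box - np.diag(np.diag(box))
    if np.any(np.abs(off_diag) > 1e-6):
        raise ValueError("triclinic boxes are unsupported; orthorhombic only")
    edges = np.diag(box)
    if np.all(edges > 0):
        return edges
    return None


def _read_file(path: str | Path, altloc: str = "occupancy", model=None):
    """Return a biotite AtomArray/Stack from a PDB or GRO file."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty structure file")
    suffix = path.suffix.lower()
    try:
        if suffix == ".gro":
            import biotite.structure.io.gro as gro
            f = gro.GROFile.read(str(path))
            return f.get_structure(model=model) if model else f.get_structure()
        import biotite.structure.io.pdb as pdb
        f = pdb.PDBFile.read(str(path))
        if model is not None:
            return f.get_structure(model=model, altloc=altloc)
        return f.get_structure(altloc=altloc)
    except Exception as exc:  # surface the offending line when biotite reports it
        raise ValueError(f"failed to parse {path}: {exc}") from exc


def load_structure(path: str | Path,
                   rules: list[dict] | None = None) -> tuple[SystemModel, Frame]:
    """Read one coordinate file (PDB or GRO) into (SystemModel, Frame).

    Residue numbering is preserved exactly as authored (1FGY runs 261–385 and
    reports name residues like H355 on that numbering).  Alternate locations
    are resolved by highest occupancy.  Roles follow ``classify_atoms``
    defaults unless a rule table is supplied.
    """
    struct = _read_file(path, model=1)
    system = _structure_to_system(struct, rules)
    frame = Frame(np.asarray(struct.coord, dtype=float),
                  box=_box_from_struct(struct))
    return system, frame


def load_trajectory(path: str | Path, dt: float = 0.01,
                    rules: list[dict] | None = None
                    ) -> tuple[SystemModel, Trajectory]:
    """Read a concatenated-model PDB as a trajectory with declared dt (ns)."""
    stack = _read_file(path)
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    system = _structure_to_system(stack[0] if coords.shape[0] > 1 else stack, rules)
    box = _box_from_struct(stack)
    traj = Trajectory.from_coords(coords, dt=dt, box=box)
    return system, traj


def write_structure(path: str | Path, system: SystemModel,
                    frames: Frame | Trajectory | Sequence[Frame],
                    b_factors: np.ndarray | None = None) -> None:
    """Write a PDB (multi-model when several frames are given).

    ``b_factors`` fills the temperature-factor column, used for per-residue
    surface colouring of contact or CSP metrics.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    if isinstance(frames, Frame):
        frame_list = [frames]
    elif isinstance(frames, Trajectory):
        frame_list = list(frames.frames)
    else:
        frame_list = list(frames)

    n = len(system)
    template = struc.AtomArray(n)
    template.atom_name = system.names
    template.res_name = system.residue_names
    template.res_id = system.residue_ids
    template.element = system.elements
    template.chain_id = np.array(["A"] * n)
    template.hetero = np.array([a.segment not in ("protein",) for a in system.atoms])
    template.set_annotation("b_factor",
                            np.zeros(n) if b_factors is None
                            else np.asarray(b_factors, dtype=float))
    template.set_annotation("occupancy", np.ones(n))

    box = frame_list[0].box
    arrays = []
    for f in frame_list:
        arr = template.copy()
        arr.coord = np.asarray(f.coordinates, dtype=float)
        if box is not None:
            arr.box = np.diag(box)
        arrays.append(arr)
    out = arrays[0] if len(arrays) == 1 else struc.stack(arrays)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(out)
    pdb_file.write(str(path))
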