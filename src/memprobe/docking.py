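"""Membrane docking by inositol head-group orientation.

A ligand-bound protein is placed on a planar bilayer by rotating the whole
complex rigidly until the inositol-ring C1→C4 and C3→C5 vectors make target
angles with the membrane plane (e.g. +40° and −17.5° for GRP1-PH on a
PC bilayer), then translating it so the ring phosphate replaces a host
lipid's head group near the centre of the upper leaflet.

Sign convention: positive tilt means the vector points away from the
membrane along the outward normal of the cytoplasmic-facing (upper) leaflet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .model import Frame, Role, SystemModel, min_image_distance

__all__ = [
    "OrientationTarget",
    "MembraneFrame",
    "membrane_frame",
    "vector_tilt",
    "orient_headgroup",
    "superpose_on_lipid",
]


@dataclass
class OrientationTarget:
    """Target tilts (degrees, in [-90, 90]) of the two inositol ring vectors."""

    tilt_c1c4: float = 40.0
    tilt_c3c5: float = -17.5
    normal_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        for t in (self.tilt_c1c4, self.tilt_c3c5):
            if not -90.0 <= t <= 90.0:
                raise ValueError("tilt targets must lie in [-90, 90] degrees")
        self.normal_axis = np.asarray(self.normal_axis, dtype=float)
        n = np.linalg.norm(self.normal_axis)
        if n == 0:
            raise ValueError("normal_axis must be non-zero")
        self.normal_axis = self.normal_axis / n


@dataclass
class MembraneFrame:
    """Planar membrane geometry: leaflet head-group planes and midplane (Å)."""

    leaflet_upper_z: float
    leaflet_lower_z: float
    midplane_z: float
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        if not self.leaflet_lower_z < self.midplane_z < self.leaflet_upper_z:
            raise ValueError("require leaflet_lower_z < midplane_z < leaflet_upper_z")


def membrane_frame(system: SystemModel, frame: Frame) -> MembraneFrame:
    """Locate the two leaflet planes from lipid head-group z coordinates.

    The splitting plane is the mean head-group z; each leaflet plane is the
    mean z of the heads on its side.  The membrane is treated as planar with
    normal +z.
    """
    idx = system.role_indices(Role.LIPID_HEADGROUP)
    if idx.size == 0:
        raise ValueError("no lipid_headgroup atoms in system")
    z = frame.coordinates[idx, 2]
    mid = float(np.mean(z))
    upper = z[z >= mid]
    lower = z[z < mid]
    if upper.size == 0 or lower.size == 0 or np.ptp(z) < 1e-9:
        raise ValueError("single leaflet: head groups do not split about the midplane")
    return MembraneFrame(leaflet_upper_z=float(np.mean(upper)),
                         leaflet_lower_z=float(np.mean(lower)),
                         midplane_z=mid)


def vector_tilt(frame: Frame, atom_a: int, atom_b: int,
                mframe: MembraneFrame | None = None,
                system: SystemModel | None = None,
                normal: np.ndarray | None = None) -> float:
    """Signed angle (degrees) between the a→b atom vector and the membrane plane.

    ``atom_a``/``atom_b`` are atom ids when ``system`` is given, otherwise
    0-based coordinate indices.  Positive = vector points along the outward
    normal; range [-90, 90].
    """
    if system is not None:
        ia, ib = system.index_of(atom_a), system.index_of(atom_b)
    else:
        ia, ib = atom_a, atom_b
    v = frame.coordinates[ib] - frame.coordinates[ia]
    return _tilt_of_vector(v, _resolve_normal(mframe, normal))


def _resolve_normal(mframe: MembraneFrame | None,
                    normal: np.ndarray | None) -> np.ndarray:
    if normal is not None:
        n = np.asarray(normal, dtype=float)
    elif mframe is not None:
        n = np.asarray(mframe.normal, dtype=float)
    else:
        n = np.array([0.0, 0.0, 1.0])
    return n / np.linalg.norm(n)


def _tilt_of_vector(v: np.ndarray, n_hat: np.ndarray) -> float:
    norm = np.linalg.norm(v)
    if norm < 1e-6:
        raise ValueError("zero-length vector has no tilt")
    s = float(np.clip(np.dot(v / norm, n_hat), -1.0, 1.0))
    return float(np.degrees(np.arcsin(s)))


# ---------------------------------------------------------------------------
# Head-group orientation
# ---------------------------------------------------------------------------

def _rotation_angle(R: Rotation) -> float:
    return float(np.linalg.norm(R.as_rotvec()))


def _triad(u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal triad with first axis u and second in span(u, w)."""
    e1 = u / np.linalg.norm(u)
    w_perp = w - np.dot(w, e1) * e1
    n = np.linalg.norm(w_perp)
    if n < 1e-9:
        raise ValueError("ring vectors are collinear; orientation under-determined")
    e2 = w_perp / n
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def _exact_orientations(u: np.ndarray, w: np.ndarray,
                        t1: float, t2: float) -> list[Rotation]:
    """Rotations mapping unit vectors (u, w) onto tilts (t1, t2) about +z.

    Solves for target unit vectors a, b with prescribed z-components and the
    same mutual angle as (u, w); two chirality branches exist, and each
    extends to a one-parameter family under rotation about z.
    """
    cos_g = float(np.clip(np.dot(u, w), -1.0, 1.0))
    s1, s2 = np.sin(np.radians(t1)), np.sin(np.radians(t2))
    c1, c2 = np.cos(np.radians(t1)), np.cos(np.radians(t2))
    a = np.array([c1, 0.0, s1])
    if c1 < 1e-12:
        return []  # first vector along the normal: handled by least squares
    b1 = (cos_g - s1 * s2) / c1
    disc = c2 * c2 - b1 * b1
    if disc < -1e-10:
        return []  # targets not exactly achievable for this ring geometry
    b2 = np.sqrt(max(disc, 0.0))
    sols = []
    for sign in (+1.0, -1.0):
        b = np.array([b1, sign * b2, s2])
        M_src = _triad(u, w)
        M_dst = _triad(a, b)
        sols.append(Rotation.from_matrix(M_dst @ M_src.T))
    return sols


def _least_squares_orientation(u: np.ndarray, w: np.ndarray,
                               t1: float, t2: float) -> Rotation:
    def residuals(rotvec):
        R = Rotation.from_rotvec(rotvec)
        return [np.degrees(np.arcsin(np.clip((R.apply(u))[2], -1, 1))) - t1,
                np.degrees(np.arcsin(np.clip((R.apply(w))[2], -1, 1))) - t2]

    best = None
    for x0 in ([0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.5, -0.5, 0.3]):
        sol = least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    return Rotation.from_rotvec(best.x)


def _minimise_total_rotation(R0: Rotation) -> Rotation:
    """Pick the z-rotation follow-up that minimises the combined rotation angle.

    Any rotation about the membrane normal preserves both tilts, so the
    solution family is Rz(phi)·R0; the minimal-angle member keeps
    already-satisfying inputs at (near-)identity and makes the operation
    idempotent.
    """
    phis = np.linspace(0.0, 2 * np.pi, 721)
    angles = [_rotation_angle(Rotation.from_euler("z", p) * R0) for p in phis]
    i = int(np.argmin(angles))
    # golden-section refine around the grid minimum
    lo, hi = phis[max(i - 1, 0)], phis[min(i + 1, len(phis) - 1)]
    from scipy.optimize import minimize_scalar
    res = minimize_scalar(
        lambda p: _rotation_angle(Rotation.from_euler("z", p) * R0),
        bounds=(lo, hi), method="bounded")
    return Rotation.from_euler("z", float(res.x)) * R0


def orient_headgroup(system: SystemModel, frame: Frame,
                     c1: int, c3: int, c4: int, c5: int,
                     target: OrientationTarget,
                     max_residual_deg: float = 5.0) -> Frame:
    """Rigidly rotate the complex so the ring vectors hit the target tilts.

    The C1→C4 tilt is matched within 0.1° and the C3→C5 tilt within 0.5°
    when the pair is exactly achievable for the ring's internal geometry;
    otherwise the best least-squares orientation is used, and a residual
    above ``max_residual_deg`` raises.  All interatomic distances are
    preserved (pure rotation about the ring centroid).
    """
    idx = {k: system.index_of(v) for k, v in dict(c1=c1, c3=c3, c4=c4, c5=c5).items()}
    coords = frame.coordinates
    v14 = coords[idx["c4"]] - coords[idx["c1"]]
    v35 = coords[idx["c5"]] - coords[idx["c3"]]
    if np.linalg.norm(v14) < 1e-6 or np.linalg.norm(v35) < 1e-6:
        raise ValueError("ring atoms coincide; zero-length orientation vector")
    u = v14 / np.linalg.norm(v14)
    w = v35 / np.linalg.norm(v35)

    candidates = _exact_orientations(u, w, target.tilt_c1c4, target.tilt_c3c5)
    if candidates:
        candidates = [_minimise_total_rotation(R) for R in candidates]
        R = min(candidates, key=_rotation_angle)
    else:
        R = _least_squares_orientation(u, w, target.tilt_c1c4, target.tilt_c3c5)

    n_hat = target.normal_axis
    resid = np.hypot(_tilt_of_vector(R.apply(u), n_hat) - target.tilt_c1c4,
                     _tilt_of_vector(R.apply(w), n_hat) - target.tilt_c3c5)
    if resid > max_residual_deg:
        raise ValueError(
            f"no rotation reaches both tilt targets; residual {resid:.2f} deg")

    pivot = coords[[idx["c1"], idx["c3"], idx["c4"], idx["c5"]]].mean(axis=0)
    new_coords = R.apply(coords - pivot) + pivot
    out = frame.copy()
    out.coordinates = new_coords
    return out


# ---------------------------------------------------------------------------
# Superposition onto a host lipid
# ---------------------------------------------------------------------------

def superpose_on_lipid(complex_system: SystemModel, complex_frame: Frame,
                       bilayer_system: SystemModel, bilayer_frame: Frame,
                       host_lipid: int,
                       anchor_atom: int | None = None,
                       clash_cutoff: float = 1.0
                       ) -> tuple[SystemModel, Frame, list[tuple[int, int, float]]]:
    """Exchange a host lipid's head group for the protein–ligand complex.

    The complex is translated so its anchor phosphate (``anchor_atom`` id in
    the complex; default: first ligand phosphorus) lands on the host lipid's
    head-group phosphate; the host head-group atoms are removed and the two
    systems merged with fresh unique atom ids.  Returns the merged system,
    frame and a steric-clash report of atom-id pairs closer than
    ``clash_cutoff`` Å (complex vs bilayer).
    """
    mframe = membrane_frame(bilayer_system, bilayer_frame)

    host_mask = bilayer_system.residue_ids == host_lipid
    if not host_mask.any():
        raise ValueError(f"no lipid with residue id {host_lipid} in bilayer")
    host_idx = np.flatnonzero(host_mask)
    head_idx = np.array([i for i in host_idx
                         if bilayer_system.atoms[i].role is Role.LIPID_HEADGROUP])
    if head_idx.size == 0:
        raise ValueError("host lipid has no head-group atoms")
    host_z = float(bilayer_frame.coordinates[head_idx, 2].mean())
    if abs(host_z - mframe.leaflet_upper_z) > abs(host_z - mframe.leaflet_lower_z):
        raise ValueError("host lipid is in the lower leaflet; docking targets the upper")

    phos = [i for i in head_idx
            if bilayer_system.atoms[i].element.upper() == "P"
            or bilayer_system.atoms[i].name.upper().startswith("P")]
    host_anchor = phos[0] if phos else head_idx[0]
    target_pos = bilayer_frame.coordinates[host_anchor]

    if anchor_atom is None:
        ligand_p = [a.atom_id for a in complex_system.atoms
                    if a.role is Role.LIGAND and a.element.upper() == "P"]
        if not ligand_p:
            raise ValueError("no ligand phosphorus found; pass anchor_atom explicitly")
        anchor_atom = ligand_p[0]
    shift = target_pos - complex_frame.coordinates[complex_system.index_of(anchor_atom)]
    moved = complex_frame.coordinates + shift

    keep = np.array([i for i in range(len(bilayer_system)) if i not in set(head_idx)])
    merged_atoms: list = []
    merged_coords = []
    next_id = 1
    new_id_of_complex: dict[int, int] = {}
    for j, atom in enumerate(complex_system.atoms):
        rec = _copy_atom(atom, next_id)
        new_id_of_complex[atom.atom_id] = next_id
        merged_atoms.append(rec)
        merged_coords.append(moved[j])
        next_id += 1
    for i in keep:
        merged_atoms.append(_copy_atom(bilayer_system.atoms[i], next_id))
        merged_coords.append(bilayer_frame.coordinates[i])
        next_id += 1

    merged = SystemModel(merged_atoms)
    n_complex = len(complex_system)
    for name, members in complex_system.groups.items():
        merged.set_group(name, [new_id_of_complex[i] for i in members])
    merged.set_group("complex", [a.atom_id for a in merged_atoms[:n_complex]])
    merged.set_group("bilayer", [a.atom_id for a in merged_atoms[n_complex:]])
    coords = np.array(merged_coords)
    out_frame = Frame(coords, box=bilayer_frame.box, time=bilayer_frame.time)

    clashes: list[tuple[int, int, float]] = []
    bil_coords = coords[n_complex:]
    for j in range(n_complex):
        d = min_image_distance(coords[j], bil_coords, out_frame.box)
        for k in np.flatnonzero(d < clash_cutoff):
            clashes.append((merged_atoms[j].atom_id,
                            merged_atoms[n_complex + int(k)].atom_id,
                            float(d[k])))
    return merged, out_frame, clashes


def _copy_atom(atom, new_id: int):
    from .model import AtomRecord

    return AtomRecord(atom_id=new_id, name=atom.name, element=atom.element,
                      residue_id=atom.residue_id, residue_name=atom.residue_name,
                      segment=atom.segment, role=atom.role)
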