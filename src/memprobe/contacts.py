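"""Protein–lipid contact profiling and geometric hydrogen-bond analysis.

Nonpolar membrane penetration is quantified as, per protein residue, the
number of lipid acyl-chain ("tail") carbon atoms lying within a cutoff
(default 4.0 Å, strict ``<``) of any heavy atom of that residue, using
minimum-image distances.  Averaged over a trajectory this gives a
contacts-per-frame profile; dividing by the frame spacing in ps gives the
contacts-per-ps normalisation used for surface colouring on a 0–2 scale.

Hydrogen bonds are called geometrically: donor–acceptor distance ≤ 3.5 Å and
donor–hydrogen–acceptor angle ≥ 150° by default (both configurable; the
criteria are the common community defaults).  Occupancy is the fraction of
frames in which a given donor/acceptor atom pair satisfies the criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import (Frame, Role, SystemModel, Trajectory,
                    min_image_displacement, min_image_distance,
                    wrap_coordinates)

__all__ = [
    "ContactCriteria",
    "ContactProfile",
    "HBondCriteria",
    "HBond",
    "HBondOccupancy",
    "count_contacts_frame",
    "profile_contacts",
    "project_to_surface",
    "detect_hbonds",
    "hbond_occupancy",
    "residues_bonded",
]

# Below this many atoms the O(N^2) path is used directly; above it a periodic
# KD-tree finds candidate pairs.  Both paths return identical counts.
_BRUTE_FORCE_LIMIT = 200


@dataclass
class ContactCriteria:
    cutoff: float = 4.0  # Å, strict <
    lipid_role: Role = Role.LIPID_TAIL_CARBON
    protein_role: Role = Role.PROTEIN_HEAVY
    use_min_image: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class ContactProfile:
    """Per-residue time-averaged nonpolar contact counts."""

    table: pd.DataFrame  # residue_id, residue_name, mean_contacts_per_frame,
    #                      mean_contacts_per_ps, frames_used
    dt_ps: float | None = None

    def per_residue(self, residue_id: int) -> pd.Series:
        return self.table.set_index("residue_id").loc[residue_id]


def _pair_distances(lipid_xyz: np.ndarray, prot_xyz: np.ndarray,
                    box: np.ndarray | None) -> np.ndarray:
    """(n_lipid, n_prot) minimum-image distance matrix."""
    delta = min_image_displacement(lipid_xyz[:, None, :], prot_xyz[None, :, :], box)
    return np.linalg.norm(delta, axis=-1)


def _contact_pairs(lipid_xyz: np.ndarray, prot_xyz: np.ndarray,
                   box: np.ndarray | None, cutoff: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Indices (into lipid_xyz, prot_xyz) of pairs with distance < cutoff."""
    n_total = len(lipid_xyz) + len(prot_xyz)
    if box is None or n_total <= _BRUTE_FORCE_LIMIT:
        d = _pair_distances(lipid_xyz, prot_xyz, box)
        li, pi = np.nonzero(d < cutoff)
        return li, pi
    box = np.asarray(box, dtype=float)
    tree_l = cKDTree(wrap_coordinates(lipid_xyz, box), boxsize=box)
    tree_p = cKDTree(wrap_coordinates(prot_xyz, box), boxsize=box)
    pairs = tree_l.query_ball_tree(tree_p, r=cutoff)
    li, pi = [], []
    for i, neigh in enumerate(pairs):
        for j in neigh:
            # query_ball_tree is inclusive at r; enforce the strict < rule
            if min_image_distance(lipid_xyz[i], prot_xyz[j], box) < cutoff:
                li.append(i)
                pi.append(j)
    return np.array(li, dtype=int), np.array(pi, dtype=int)


def count_contacts_frame(system: SystemModel, frame: Frame,
                         criteria: ContactCriteria | None = None,
                         binary: bool = False) -> dict[int, int]:
    """Per-protein-residue count of (tail carbon, heavy atom) pairs within cutoff.

    A tail carbon near two residues is counted once against each.  With
    ``binary=True`` each (residue, tail carbon) combination counts at most
    once regardless of how many heavy atoms it touches.
    """
    criteria = criteria or ContactCriteria()
    lipid_idx = system.role_indices(criteria.lipid_role)
    if lipid_idx.size == 0:
        raise ValueError("no lipid tails: no atoms with role "
                         f"{criteria.lipid_role.value}")
    prot_idx = system.role_indices(criteria.protein_role)
    residue_ids = system.residue_ids
    counts: dict[int, int] = {int(r): 0 for r in
                              np.unique(residue_ids[prot_idx])}
    if prot_idx.size == 0:
        return counts

    box = frame.box if criteria.use_min_image else None
    li, pi = _contact_pairs(frame.coordinates[lipid_idx],
                            frame.coordinates[prot_idx], box, criteria.cutoff)
    prot_res = residue_ids[prot_idx]
    if binary:
        seen = {(int(lipid_idx[i]), int(prot_res[j])) for i, j in zip(li, pi)}
        for _, res in seen:
            counts[res] += 1
    else:
        for j in pi:
            counts[int(prot_res[j])] += 1
    return counts


def profile_contacts(system: SystemModel, traj: Trajectory,
                     criteria: ContactCriteria | None = None,
                     binary: bool = False) -> ContactProfile:
    """Average per-frame contact counts over a trajectory.

    mean_contacts_per_ps = mean_contacts_per_frame / dt in ps, i.e. the
    per-frame mean re-expressed per picosecond of sampling interval.
    """
    criteria = criteria or ContactCriteria()
    totals: dict[int, float] = {}
    n_frames = len(traj)
    for frame in traj:
        counts = count_contacts_frame(system, frame, criteria, binary=binary)
        for res, c in counts.items():
            totals[res] = totals.get(res, 0.0) + c
    resname_of = {rid: rname for rid, rname in system.residues()}
    dt_ps = traj.dt * 1000.0
    rows = []
    for res in sorted(totals):
        mean = totals[res] / n_frames
        rows.append(dict(residue_id=res, residue_name=resname_of.get(res, "?"),
                         mean_contacts_per_frame=mean,
                         mean_contacts_per_ps=mean / dt_ps,
                         frames_used=n_frames))
    return ContactProfile(pd.DataFrame(rows), dt_ps=dt_ps)


def project_to_surface(profile: ContactProfile,
                       metric: str = "mean_contacts_per_ps",
                       scale_max: float = 2.0) -> pd.DataFrame:
    """Clamp the chosen metric to [0, scale_max] for structure colouring.

    Returns a residue table with a ``surface_value`` column; the values are
    also what gets written into the PDB B-factor column for molecular-surface
    rendering on the 0 (blue) to 2 (red) scale.
    """
    if profile.table.empty:
        raise ValueError("empty contact profile")
    out = profile.table[["residue_id", "residue_name", metric]].copy()
    out["surface_value"] = out[metric].clip(lower=0.0, upper=scale_max)
    return out


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

# Donor/acceptor atom-name rule tables: full-match regexes on atom names.
# Donors are N/O heavy atoms carrying a hydrogen; acceptors are N/O (and
# phosphate O of the ligand).  Hydrogens are associated with their donor
# geometrically (same residue, name starting with H, within 1.2 Å) since
# the model carries no bond list.
DEFAULT_DONOR_PATTERNS = [r"N[A-Z0-9]*", r"O[A-Z0-9]*"]
DEFAULT_ACCEPTOR_PATTERNS = [r"O[A-Z0-9]*", r"N[A-Z0-9]*"]
_H_ATTACH_CUTOFF = 1.2  # Å


@dataclass
class HBondCriteria:
    da_cutoff: float = 3.5  # Å, donor–acceptor, inclusive
    dha_min_angle: float = 150.0  # degrees
    donor_patterns: list[str] = field(default_factory=lambda: list(DEFAULT_DONOR_PATTERNS))
    acceptor_patterns: list[str] = field(default_factory=lambda: list(DEFAULT_ACCEPTOR_PATTERNS))
    heavy_only: bool = False  # distance criterion alone (no hydrogens needed)

    def __post_init__(self) -> None:
        if self.da_cutoff <= 0:
            raise ValueError("da_cutoff must be positive")
        if not 90.0 < self.dha_min_angle <= 180.0:
            raise ValueError("dha_min_angle must lie in (90, 180]")
        if not self.donor_patterns:
            raise ValueError("donor pattern table is empty")


@dataclass(frozen=True)
class HBond:
    donor_atom: int
    hydrogen_atom: int | None
    acceptor_atom: int
    donor_residue: int
    acceptor_residue: int
    distance: float
    angle: float | None  # None in heavy-only mode
    heavy_only: bool = False


@dataclass
class HBondOccupancy:
    donor_atom: int
    acceptor_atom: int
    donor_residue: int
    donor_residue_name: str
    acceptor_residue: int
    acceptor_residue_name: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("occupancy fraction must lie in [0, 1]")


def _match_any(name: str, patterns: list[str]) -> bool:
    import re

    return any(re.fullmatch(p, name) for p in patterns)


def _candidate_atoms(system: SystemModel, group: np.ndarray | None,
                     patterns: list[str], polar_only: bool = True) -> np.ndarray:
    idx = group if group is not None else np.arange(len(system))
    out = []
    for i in idx:
        a = system.atoms[int(i)]
        if a.element.upper() == "H":
            continue
        if polar_only and a.element.upper() not in ("N", "O", "S", "F"):
            continue
        if _match_any(a.name, patterns):
            out.append(int(i))
    return np.array(out, dtype=int)


def _attached_hydrogens(system: SystemModel, frame: Frame,
                        heavy_index: int) -> list[int]:
    a = system.atoms[heavy_index]
    out = []
    for j, b in enumerate(system.atoms):
        if b.residue_id != a.residue_id or not b.name.upper().startswith("H"):
            continue
        if b.element.upper() != "H":
            continue
        d = min_image_distance(frame.coordinates[heavy_index],
                               frame.coordinates[j], frame.box)
        if d <= _H_ATTACH_CUTOFF:
            out.append(j)
    return out


def detect_hbonds(system: SystemModel, frame: Frame,
                  criteria: HBondCriteria | None = None,
                  donor_group: str | None = None,
                  acceptor_group: str | None = None) -> list[HBond]:
    """Geometric hydrogen-bond detection in one frame.

    Standard mode requires an explicit hydrogen: D–A distance ≤ cutoff and
    D–H–A angle ≥ the minimum.  ``heavy_only`` mode applies the distance
    criterion alone and flags each record accordingly (for hydrogen-free
    models).  Donor and acceptor candidates can be restricted to named
    groups.
    """
    criteria = criteria or HBondCriteria()
    d_group = system.group_indices(donor_group) if donor_group else None
    a_group = system.group_indices(acceptor_group) if acceptor_group else None
    donors = _candidate_atoms(system, d_group, criteria.donor_patterns)
    acceptors = _candidate_atoms(system, a_group, criteria.acceptor_patterns)
    if donors.size == 0:
        raise ValueError("no donor atoms match the donor pattern table")

    bonds: list[HBond] = []
    coords = frame.coordinates
    for di in donors:
        d_xyz = coords[di]
        dist = min_image_distance(d_xyz, coords[acceptors], frame.box)
        near = acceptors[np.asarray(dist <= criteria.da_cutoff).nonzero()[0]]
        if near.size == 0:
            continue
        hydrogens = None if criteria.heavy_only else _attached_hydrogens(system, frame, di)
        for ai in near:
            if ai == di or system.atoms[int(ai)].residue_id == system.atoms[int(di)].residue_id:
                continue
            d_val = float(min_image_distance(d_xyz, coords[ai], frame.box))
            if criteria.heavy_only:
                bonds.append(HBond(system.atoms[di].atom_id, None,
                                   system.atoms[int(ai)].atom_id,
                                   system.atoms[di].residue_id,
                                   system.atoms[int(ai)].residue_id,
                                   d_val, None, heavy_only=True))
                continue
            for hi in hydrogens:
                v_hd = min_image_displacement(d_xyz, coords[hi], frame.box)
                v_ha = min_image_displacement(coords[ai], coords[hi], frame.box)
                cosang = np.dot(v_hd, v_ha) / (np.linalg.norm(v_hd) * np.linalg.norm(v_ha))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if angle >= criteria.dha_min_angle:
                    bonds.append(HBond(system.atoms[di].atom_id,
                                       system.atoms[hi].atom_id,
                                       system.atoms[int(ai)].atom_id,
                                       system.atoms[di].residue_id,
                                       system.atoms[int(ai)].residue_id,
                                       d_val, angle))
                    break  # one bond per donor-acceptor pair
    return bonds


def hbond_occupancy(system: SystemModel, traj: Trajectory,
                    criteria: HBondCriteria | None = None,
                    donor_group: str | None = None,
                    acceptor_group: str | None = None) -> list[HBondOccupancy]:
    """Fraction of frames in which each (donor atom, acceptor atom) pair bonds."""
    presence: dict[tuple[int, int], int] = {}
    meta: dict[tuple[int, int], HBond] = {}
    for frame in traj:
        bonds = detect_hbonds(system, frame, criteria, donor_group, acceptor_group)
        for b in bonds:
            key = (b.donor_atom, b.acceptor_atom)
            presence[key] = presence.get(key, 0) + 1
            meta.setdefault(key, b)
    resname_of = {rid: rname for rid, rname in system.residues()}
    n = len(traj)
    out = []
    for key, count in sorted(presence.items()):
        b = meta[key]
        out.append(HBondOccupancy(
            donor_atom=b.donor_atom, acceptor_atom=b.acceptor_atom,
            donor_residue=b.donor_residue,
            donor_residue_name=resname_of.get(b.donor_residue, "?"),
            acceptor_residue=b.acceptor_residue,
            acceptor_residue_name=resname_of.get(b.acceptor_residue, "?"),
            fraction=count / n))
    return out


def residues_bonded(occupancies: list[HBondOccupancy],
                    min_fraction: float = 0.10,
                    partner_residues: set[int] | None = None) -> list[int]:
    """Residues with at least one H-bond pair at occupancy ≥ min_fraction.

    When ``partner_residues`` is given, only bonds whose opposite end lies in
    that residue set are considered (e.g. bonds to the ligand).  Each bond
    contributes the residue at its *other* end.
    """
    hits: set[int] = set()
    for occ in occupancies:
        if occ.fraction < min_fraction:
            continue
        ends = {occ.donor_residue, occ.acceptor_residue}
        if partner_residues is not None:
            touching = ends & set(partner_residues)
            if not touching:
                continue
            hits |= ends - set(partner_residues)
        else:
            hits |= ends
    return sorted(hits)
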