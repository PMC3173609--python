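"""Steered-pull post-processing: spring force, work, energy decomposition.

A stiff harmonic spring (default k = 500 pN/Å) attached to the protein
centre of mass is retracted along +z at constant speed (0.5 Å/ns over 80 ns
or 1.0 Å/ns over 40 ns; 40 Å total either way).  This module does the
bookkeeping around such pulls: instantaneous spring force, cumulative work
by trapezoidal integration over anchor displacement, short-range pairwise
Lennard-Jones / Coulomb interaction energies between named groups (no
long-range reciprocal-space reconstruction — short-range components only),
and classification of lipids dragged out of the bilayer.

Units: pN, Å, ns, kJ/mol.  1 pN·Å = 0.06022 kJ/mol; the Coulomb prefactor
is 1389.35 kJ·Å·mol⁻¹·e⁻² (vacuum permittivity, dielectric configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .docking import MembraneFrame
from .model import Frame, SystemModel, Trajectory, min_image_distance

__all__ = [
    "PN_A_TO_KJ_PER_MOL",
    "COULOMB_PREFACTOR",
    "PullProtocol",
    "PullSeries",
    "EnergyTerms",
    "NonbondedParams",
    "spring_force",
    "accumulate_work",
    "interaction_energy",
    "decompose_pull",
    "detect_extracted_lipids",
]

PN_A_TO_KJ_PER_MOL = 0.06022
COULOMB_PREFACTOR = 1389.35  # kJ·Å/mol per e²


@dataclass
class PullProtocol:
    """Constant-velocity harmonic pull along an axis."""

    k: float = 500.0  # pN/Å
    v: float = 0.5  # Å/ns
    duration: float = 80.0  # ns
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    anchor0: float = 0.0  # Å, anchor position along axis at t=0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("spring constant must be positive")
        self.axis = np.asarray(self.axis, dtype=float)
        self.axis = self.axis / np.linalg.norm(self.axis)

    @property
    def total_distance(self) -> float:
        return self.v * self.duration

    def anchor_at(self, t: float | np.ndarray) -> float | np.ndarray:
        return self.anchor0 + self.v * np.asarray(t, dtype=float)


@dataclass
class PullSeries:
    """Time series of one pull: anchor, group COM, spring force, work."""

    t: np.ndarray  # ns
    anchor_z: np.ndarray  # Å along the pull axis
    com_z: np.ndarray  # Å
    force: np.ndarray  # pN
    protocol: PullProtocol | None = None

    def as_frame(self) -> pd.DataFrame:
        work = _cumulative_work(self.anchor_z, self.force)
        return pd.DataFrame(dict(
            t_ns=self.t, anchor_z=self.anchor_z, com_z=self.com_z,
            force_pN=self.force, work_pN_A=work,
            work_kJ_mol=work * PN_A_TO_KJ_PER_MOL))


@dataclass
class EnergyTerms:
    e_lj: float  # kJ/mol
    e_coul: float  # kJ/mol
    pair: str = ""
    cutoff: float = 10.0  # Å


class NonbondedParams:
    """Per-atom charge (e), LJ sigma (Å) and epsilon (kJ/mol).

    Parameters are keyed by (residue_name, atom_name), with an atom-name-only
    fallback.  Cross terms use the geometric combination rule by convention
    (GROMOS-style), Lorentz-Berthelot selectable.
    """

    def __init__(self, table: Mapping[tuple[str, str] | str, tuple[float, float, float]],
                 combination_rule: str = "geometric"):
        if combination_rule not in ("geometric", "lorentz-berthelot"):
            raise ValueError("combination_rule must be geometric or lorentz-berthelot")
        self.combination_rule = combination_rule
        self.table = dict(table)
        for key, (q, sigma, eps) in self.table.items():
            if sigma <= 0 or eps < 0:
                raise ValueError(f"bad LJ parameters for {key!r}: sigma>0, eps>=0 required")

    def lookup(self, residue_name: str, atom_name: str) -> tuple[float, float, float]:
        key = (residue_name, atom_name)
        if key in self.table:
            return self.table[key]
        if atom_name in self.table:
            return self.table[atom_name]
        raise KeyError(f"no nonbonded parameters for atom {atom_name!r} "
                       f"in residue {residue_name!r}")

    @classmethod
    def from_yaml(cls, path) -> "NonbondedParams":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        table = {}
        for entry in raw.get("atoms", []):
            key = (entry["residue"], entry["name"]) if "residue" in entry else entry["name"]
            table[key] = (float(entry["charge"]), float(entry["sigma"]),
                          float(entry["epsilon"]))
        return cls(table, combination_rule=raw.get("combination_rule", "geometric"))


def spring_force(t: float, com_z: float, protocol: PullProtocol) -> float:
    """Instantaneous spring force F = k·(anchor(t) − com) in pN.

    Positive force pulls the group toward the anchor along the pull axis.
    """
    if not 0.0 <= t <= protocol.duration + 1e-9:
        raise ValueError(f"t={t} outside pull duration [0, {protocol.duration}] ns")
    return float(protocol.k * (protocol.anchor_at(t) - com_z))


def _cumulative_work(anchor: np.ndarray, force: np.ndarray) -> np.ndarray:
    d_anchor = np.diff(anchor)
    mid_force = 0.5 * (force[1:] + force[:-1])
    return np.concatenate(([0.0], np.cumsum(mid_force * d_anchor)))


def accumulate_work(series: PullSeries) -> tuple[float, float]:
    """Trapezoidal work done by the spring over anchor displacement.

    Returns (work in pN·Å, work in kJ/mol).  The anchor must advance
    monotonically (constant-velocity protocol).
    """
    if len(series.t) < 2:
        raise ValueError("need at least two samples to integrate work")
    if np.any(np.diff(series.anchor_z) < -1e-9):
        raise ValueError("anchor displacement must be monotonic")
    w = float(_cumulative_work(series.anchor_z, series.force)[-1])
    return w, w * PN_A_TO_KJ_PER_MOL


# ---------------------------------------------------------------------------
# Pairwise short-range energies
# ---------------------------------------------------------------------------

def _group_params(system: SystemModel, idx: np.ndarray,
                  params: NonbondedParams):
    q = np.empty(len(idx))
    sig = np.empty(len(idx))
    eps = np.empty(len(idx))
    for k, i in enumerate(idx):
        a = system.atoms[int(i)]
        q[k], sig[k], eps[k] = params.lookup(a.residue_name, a.name)
    return q, sig, eps


def interaction_energy(system: SystemModel, frame: Frame,
                       group_a: str, group_b: str,
                       params: NonbondedParams,
                       cutoff: float = 10.0,
                       dielectric: float = 1.0) -> EnergyTerms:
    """Short-range LJ + Coulomb energy between two disjoint groups (kJ/mol).

    Sums over inter-group pairs with minimum-image separation < cutoff:
    E_coul = f·qᵢqⱼ/(ε_r·r), E_lj = 4ε[(σ/r)¹² − (σ/r)⁶].  Both terms vanish
    when every pair exceeds the cutoff.
    """
    ia = system.group_indices(group_a)
    ib = system.group_indices(group_b)
    if np.intersect1d(ia, ib).size:
        raise ValueError(f"groups {group_a!r} and {group_b!r} overlap")
    qa, siga, epsa = _group_params(system, ia, params)
    qb, sigb, epsb = _group_params(system, ib, params)

    xa = frame.coordinates[ia]
    xb = frame.coordinates[ib]
    delta = xa[:, None, :] - xb[None, :, :]
    if frame.box is not None:
        delta -= frame.box * np.round(delta / frame.box)
    r = np.linalg.norm(delta, axis=-1)
    mask = r < cutoff
    if not mask.any():
        return EnergyTerms(0.0, 0.0, pair=f"{group_a}-{group_b}", cutoff=cutoff)
    r = r[mask]
    qq = np.outer(qa, qb)[mask]
    if params.combination_rule == "geometric":
        sig = np.sqrt(np.outer(siga, sigb))[mask]
    else:
        sig = (0.5 * (siga[:, None] + sigb[None, :]))[mask]
    eps = np.sqrt(np.outer(epsa, epsb))[mask]

    e_coul = float(np.sum(COULOMB_PREFACTOR * qq / (dielectric * r)))
    sr6 = (sig / r) ** 6
    e_lj = float(np.sum(4.0 * eps * (sr6 ** 2 - sr6)))
    return EnergyTerms(e_lj=e_lj, e_coul=e_coul,
                       pair=f"{group_a}-{group_b}", cutoff=cutoff)


def decompose_pull(system: SystemModel, traj: Trajectory,
                   params: NonbondedParams,
                   protein_group: str = "protein",
                   ligand_group: str = "PIP3",
                   lipid_group: str = "POPC",
                   cutoff: float = 10.0) -> pd.DataFrame:
    """Per-frame protein–ligand and protein–lipid LJ/Coulomb energy series.

    When a lipid is dragged along with the protein, the protein–lipid terms
    plateau at a nonzero value instead of decaying to zero after detachment
    from the bilayer.
    """
    rows = []
    for i, frame in enumerate(traj):
        e_pl = interaction_energy(system, frame, protein_group, ligand_group,
                                  params, cutoff)
        e_pc = interaction_energy(system, frame, protein_group, lipid_group,
                                  params, cutoff)
        rows.append(dict(t_ns=frame.time,
                         lj_protein_ligand=e_pl.e_lj, coul_protein_ligand=e_pl.e_coul,
                         lj_protein_lipid=e_pc.e_lj, coul_protein_lipid=e_pc.e_coul))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Lipid extraction
# ---------------------------------------------------------------------------

def detect_extracted_lipids(system: SystemModel, frame: Frame,
                            mframe: MembraneFrame,
                            full_thresh: float = 10.0,
                            partial_thresh: float = 4.0) -> dict[int, str]:
    """Classify each lipid by how far its COM sits above the upper leaflet.

    fully_extracted when COM z > leaflet + full_thresh; partially_extracted
    when it lies in (leaflet + partial_thresh, leaflet + full_thresh]; else
    in_bilayer.  Thresholds are heuristics and are reported with results.
    """
    if partial_thresh >= full_thresh:
        raise ValueError("partial_thresh must be below full_thresh")
    masses = system.masses
    segments = system.segments
    residue_ids = system.residue_ids
    out: dict[int, str] = {}
    for res in np.unique(residue_ids[segments == "lipid"]):
        idx = np.flatnonzero((residue_ids == res) & (segments == "lipid"))
        m = masses[idx]
        com_z = float((m * frame.coordinates[idx, 2]).sum() / m.sum())
        height = com_z - mframe.leaflet_upper_z
        if height > full_thresh:
            out[int(res)] = "fully_extracted"
        elif height > partial_thresh:
            out[int(res)] = "partially_extracted"
        else:
            out[int(res)] = "in_bilayer"
    return out
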