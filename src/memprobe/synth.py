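"""Seeded synthetic-data generators with known ground truth.

Every input class the analysis stages consume can be generated here at desk
scale: a planar two-leaflet pseudo-lipid bilayer, a docked protein with
membrane-inserted loop residues, 2D Brownian walks of known diffusion
coefficient, quasi-static harmonic pull traces with a rupture event,
HSQC peak lists with a planted perturbed-residue subset, and linear
Δπ(π₀) monolayer series with known intercept.

Pseudo-lipids are bead chains (one head phosphate bead "P" plus tail-carbon
beads "T1"…"Tn"): the contact, extraction and diffusion analyses need roles
and geometry, not chemistry.  Identical seed ⇒ bit-identical output, and
the ground truth travels with every product.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .model import AtomRecord, Frame, Role, SystemModel, Trajectory, classify_atoms
from .monolayer import PenetrationSeries
from .nmr import PeakList
from .smd import PullProtocol, PullSeries

__all__ = [
    "make_bilayer",
    "make_docked_protein",
    "simulate_brownian_2d",
    "simulate_pull",
    "make_extraction_snapshot",
    "make_peaklists",
    "make_monolayer_series",
]

_TAIL_SPACING = 1.4  # Å between successive tail beads
_AA_NAMES = np.array(["ALA", "ARG", "ASN", "ASP", "GLN", "GLU", "GLY", "HIS",
                      "ILE", "LEU", "LYS", "MET", "PHE", "SER", "THR", "TRP",
                      "TYR", "VAL"])


def make_bilayer(n_per_leaflet: int = 16, area_per_lipid: float = 65.0,
                 tail_carbons: int = 8, seed: int = 0,
                 leaflet_separation: float = 40.0,
                 jitter: float = 0.5) -> tuple[SystemModel, Frame, dict]:
    """Planar two-leaflet slab of pseudo-lipids on a jittered grid.

    Each lipid is one head bead (P) at ±leaflet_separation/2 plus
    ``tail_carbons`` tail beads pointing at the midplane, so the atom count
    is 2·n_per_leaflet·(1 + tail_carbons).  Box x/y edges follow the area
    per lipid; box z is leaflet_separation + 40 Å of headroom.
    """
    if n_per_leaflet < 4:
        raise ValueError("need at least 4 lipids per leaflet")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_per_leaflet)))
    spacing = float(np.sqrt(area_per_lipid))
    box = np.array([side * spacing, side * spacing,
                    leaflet_separation + 40.0])
    half = leaflet_separation / 2.0

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    atom_id = 1
    res_id = 1
    for leaflet_sign in (+1.0, -1.0):
        placed = 0
        for gx in range(side):
            for gy in range(side):
                if placed >= n_per_leaflet:
                    break
                x0 = (gx + 0.5) * spacing + rng.normal(0.0, jitter)
                y0 = (gy + 0.5) * spacing + rng.normal(0.0, jitter)
                z_head = leaflet_sign * half + rng.normal(0.0, jitter)
                atoms.append(AtomRecord(atom_id, "P", "P", res_id, "LIP"))
                coords.append(np.array([x0, y0, z_head]))
                atom_id += 1
                for k in range(1, tail_carbons + 1):
                    z = z_head - leaflet_sign * _TAIL_SPACING * k
                    atoms.append(AtomRecord(atom_id, f"T{k}", "C", res_id, "LIP"))
                    coords.append(np.array([
                        x0 + rng.normal(0.0, 0.2),
                        y0 + rng.normal(0.0, 0.2), z]))
                    atom_id += 1
                res_id += 1
                placed += 1
    system = SystemModel(atoms)
    classify_atoms(system)
    system.set_group("POPC", [a.atom_id for a in atoms])
    system.set_group("membrane", [a.atom_id for a in atoms])
    frame = Frame(np.array(coords), box=box)
    truth = dict(kind="bilayer", seed=seed, n_per_leaflet=n_per_leaflet,
                 tail_carbons=tail_carbons, leaflet_z=half,
                 area_per_lipid=area_per_lipid,
                 n_atoms=len(atoms))
    return system, frame, truth


def make_docked_protein(bilayer: tuple[SystemModel, Frame],
                        n_residues: int = 20,
                        inserted_loop_residues: Sequence[int] = (346, 347, 348),
                        insertion_depth: float = 3.0,
                        seed: int = 0,
                        n_frames: int = 20,
                        jitter_sigma: float = 0.5,
                        first_residue: int = 331
                        ) -> tuple[SystemModel, Trajectory, dict]:
    """Merge a toy protein onto a bilayer with chosen loop residues inserted.

    Residues are 5-heavy-atom clusters (N, CA, C, O, CB).  Loop residues sit
    ``insertion_depth`` Å below the upper head-group plane, laterally over
    lipid positions, so their contact occupancy with tail carbons is high;
    the rest of the chain arcs well above the membrane.  Trajectory frames
    add Gaussian jitter of ``jitter_sigma`` Å to the protein atoms only.
    """
    bil_system, bil_frame, = bilayer
    from .docking import membrane_frame

    mframe = membrane_frame(bil_system, bil_frame)
    if insertion_depth < 0:
        raise ValueError("insertion_depth must be nonnegative")
    if mframe.leaflet_upper_z - insertion_depth <= mframe.midplane_z:
        raise ValueError("insertion_depth reaches past the bilayer midplane")
    residue_ids = list(range(first_residue, first_residue + n_residues))
    loop = set(int(r) for r in inserted_loop_residues)
    if not loop <= set(residue_ids):
        raise ValueError("inserted_loop_residues must be a subset of the chain")

    rng = np.random.default_rng(seed)
    box = bil_frame.box
    # lateral anchor points: centres of the upper-leaflet lipids
    head_idx = bil_system.role_indices(Role.LIPID_HEADGROUP)
    upper_heads = head_idx[bil_frame.coordinates[head_idx, 2] > mframe.midplane_z]
    centre_xy = bil_frame.coordinates[upper_heads, :2].mean(axis=0)

    next_id = max(a.atom_id for a in bil_system.atoms) + 1
    atoms = [  # keep originals first so bilayer indices are unchanged
        AtomRecord(a.atom_id, a.name, a.element, a.residue_id, a.residue_name,
                   a.segment, a.role) for a in bil_system.atoms]
    coords = [c for c in bil_frame.coordinates]
    offsets = np.array([[0.0, 0.0, 0.0], [1.2, 0.0, 0.3], [2.1, 0.9, 0.0],
                        [2.4, 1.9, 0.6], [0.8, 1.1, -0.7]])  # N CA C O CB
    names = ["N", "CA", "C", "O", "CB"]
    protein_ids = []
    for i, res in enumerate(residue_ids):
        if res in loop:
            # below the head-group plane, laterally between lipids
            anchor = upper_heads[rng.integers(len(upper_heads))]
            base = bil_frame.coordinates[anchor].copy()
            base[0] += rng.normal(0.0, 1.0)
            base[1] += rng.normal(0.0, 1.0)
            base[2] = mframe.leaflet_upper_z - insertion_depth
        else:
            theta = 2 * np.pi * i / n_residues
            base = np.array([
                centre_xy[0] + 6.0 * np.cos(theta),
                centre_xy[1] + 6.0 * np.sin(theta),
                mframe.leaflet_upper_z + 6.0 + 4.0 * abs(np.sin(theta))])
        resname = str(_AA_NAMES[rng.integers(len(_AA_NAMES))])
        for name, off in zip(names, offsets):
            atoms.append(AtomRecord(next_id, name, name[0], res, resname))
            coords.append(base + off)
            protein_ids.append(next_id)
            next_id += 1

    system = SystemModel(atoms)
    classify_atoms(system)
    system.set_group("protein", protein_ids)
    lipid_ids = [a.atom_id for a in bil_system.atoms]
    system.set_group("membrane", lipid_ids)
    system.set_group("POPC", lipid_ids)
    system.set_group("loop", [aid for aid in protein_ids
                              if system.atoms[system.index_of(aid)].residue_id in loop])

    base_coords = np.array(coords)
    prot_idx = system.indices_of(protein_ids)
    frames = []
    for fi in range(n_frames):
        c = base_coords.copy()
        c[prot_idx] += rng.normal(0.0, jitter_sigma, size=(len(prot_idx), 3))
        frames.append(Frame(c, box=box, time=fi * 0.01))
    traj = Trajectory(frames, dt=0.01)
    truth = dict(kind="docked_protein", seed=seed,
                 inserted_loop_residues=sorted(loop),
                 insertion_depth=insertion_depth,
                 n_residues=n_residues, n_frames=n_frames,
                 jitter_sigma=jitter_sigma,
                 residue_range=[residue_ids[0], residue_ids[-1]])
    return system, traj, truth


def simulate_brownian_2d(D: float, dt: float = 0.01, n_steps: int = 10_000,
                         n_walkers: int = 100, seed: int = 0
                         ) -> tuple[np.ndarray, dict]:
    """Free 2D Brownian walks: per-axis step variance 2·D·dt (Å², D in Å²/ns).

    Returns positions of shape (n_walkers, n_steps + 1, 2) starting at the
    origin, plus the ground truth.
    """
    if D < 0:
        raise ValueError("D must be nonnegative")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt),
                       size=(n_walkers, n_steps, 2))
    pos = np.concatenate([np.zeros((n_walkers, 1, 2)), np.cumsum(steps, axis=1)],
                         axis=1)
    truth = dict(kind="brownian2d", seed=seed, D_A2_per_ns=D, dt_ns=dt,
                 n_steps=n_steps, n_walkers=n_walkers,
                 D_cm2_per_s=D * 1e-7)
    return pos, truth


def simulate_pull(protocol: PullProtocol | None = None,
                  tether_k: float = 50.0,
                  rupture_force: float = 400.0,
                  dt: float = 0.05,
                  relax_tau: float = 1.0,
                  seed: int = 0) -> tuple[PullSeries, dict]:
    """Quasi-static harmonic pull trace with a rupture event.

    Before rupture the group COM balances the pull spring against a harmonic
    surface tether of stiffness ``tether_k``, so the spring force ramps
    linearly; once it exceeds ``rupture_force`` the tether breaks and the
    COM relaxes exponentially onto the anchor (force → 0).
    """
    if rupture_force <= 0:
        raise ValueError("rupture_force must be positive")
    protocol = protocol or PullProtocol()
    t = np.arange(0.0, protocol.duration + dt / 2, dt)
    anchor = np.asarray(protocol.anchor_at(t), dtype=float)
    z0 = protocol.anchor0
    k, kt = protocol.k, tether_k
    # bound phase: com = (k·anchor + kt·z0)/(k + kt);  F = k·kt/(k+kt)·v·t
    com = (k * anchor + kt * z0) / (k + kt)
    force = k * (anchor - com)
    rupture = np.flatnonzero(force >= rupture_force)
    t_rupture = None
    if rupture.size:
        i0 = int(rupture[0])
        t_rupture = float(t[i0])
        lag0 = anchor[i0] - com[i0]
        decay = lag0 * np.exp(-(t[i0:] - t[i0]) / relax_tau)
        com[i0:] = anchor[i0:] - decay
        force[i0:] = k * decay
    series = PullSeries(t=t, anchor_z=anchor, com_z=com, force=force,
                        protocol=protocol)
    truth = dict(kind="pull", seed=seed, k=k, v=protocol.v,
                 duration=protocol.duration, tether_k=kt,
                 rupture_force=rupture_force, t_rupture=t_rupture,
                 force_ramp_pN_per_ns=k * kt / (k + kt) * protocol.v)
    return series, truth


def make_extraction_snapshot(seed: int = 0,
                             full_height: float = 15.0,
                             partial_height: float = 6.0
                             ) -> tuple[SystemModel, Frame, "object", dict]:
    """Late-pull bilayer snapshot: one lipid fully and one partially extracted.

    Two upper-leaflet lipids are translated upward so their COMs sit
    ``full_height`` and ``partial_height`` Å above the (pre-displacement)
    upper leaflet plane.  Returns (system, frame, mframe, truth).
    """
    from .docking import membrane_frame

    system, frame, _ = make_bilayer(n_per_leaflet=9, seed=seed)
    mframe = membrane_frame(system, frame)
    residue_ids = system.residue_ids
    masses = system.masses
    z = frame.coordinates[:, 2]
    upper_lipids = []
    for res in np.unique(residue_ids):
        idx = np.flatnonzero(residue_ids == res)
        com_z = float((masses[idx] * z[idx]).sum() / masses[idx].sum())
        if com_z > mframe.midplane_z:
            upper_lipids.append((res, idx, com_z))
    (res_full, idx_full, com_full), (res_part, idx_part, com_part) = upper_lipids[:2]
    coords = frame.coordinates.copy()
    coords[idx_full, 2] += mframe.leaflet_upper_z + full_height - com_full
    coords[idx_part, 2] += mframe.leaflet_upper_z + partial_height - com_part
    out = Frame(coords, box=frame.box, time=frame.time)
    truth = dict(kind="extraction_snapshot", seed=seed,
                 fully_extracted=[int(res_full)],
                 partially_extracted=[int(res_part)],
                 full_height=full_height, partial_height=partial_height)
    return system, out, mframe, truth


def make_peaklists(n_residues: int = 120,
                   perturbed: Iterable[int] | None = None,
                   effect_ppm: float = 0.10,
                   noise_ppm: float = 0.02,
                   ph_levels: Sequence[float] = (7.4, 6.8, 6.0),
                   first_residue: int = 261,
                   seed: int = 0
                   ) -> tuple[PeakList, dict[float, PeakList], dict]:
    """Free peak list plus per-pH bound lists with a planted perturbed subset.

    Perturbed residues shift by ``effect_ppm`` in ¹H (5× that in ¹⁵N, the
    usual dispersion ratio), scaled up linearly as pH decreases from the
    highest level; every residue carries Gaussian background jitter of
    ``noise_ppm`` (¹H; 5× in ¹⁵N) in the bound lists.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    residues = np.arange(first_residue, first_residue + n_residues)
    if perturbed is None:
        perturbed = rng.choice(residues, size=14, replace=False)
    perturbed = np.array(sorted(int(r) for r in perturbed))
    if not set(perturbed) <= set(residues.tolist()):
        raise ValueError("perturbed residues must belong to the sequence")

    names = _AA_NAMES[rng.integers(len(_AA_NAMES), size=n_residues)]
    h0 = rng.normal(8.2, 0.35, n_residues)
    n0 = rng.normal(118.0, 3.5, n_residues)
    free = PeakList(pd.DataFrame(dict(residue_id=residues, residue_name=names,
                                      h_ppm=h0, n_ppm=n0)),
                    condition="free")
    # fixed random signs so each residue moves in one direction across pH
    sign_h = rng.choice([-1.0, 1.0], n_residues)
    sign_n = rng.choice([-1.0, 1.0], n_residues)
    is_pert = np.isin(residues, perturbed)
    ph_ref = max(ph_levels)
    bound: dict[float, PeakList] = {}
    for ph in ph_levels:
        scale = 1.0 + 0.6 * (ph_ref - ph)
        dh = np.where(is_pert, effect_ppm * scale * sign_h, 0.0)
        dn = np.where(is_pert, 5.0 * effect_ppm * scale * sign_n, 0.0)
        h = h0 + dh + rng.normal(0.0, noise_ppm, n_residues)
        n = n0 + dn + rng.normal(0.0, 5.0 * noise_ppm, n_residues)
        bound[float(ph)] = PeakList(
            pd.DataFrame(dict(residue_id=residues, residue_name=names,
                              h_ppm=h, n_ppm=n)),
            condition=f"bound pH {ph:g}")
    truth = dict(kind="peaklists", seed=seed,
                 perturbed=perturbed.tolist(), effect_ppm=effect_ppm,
                 noise_ppm=noise_ppm, ph_levels=list(ph_levels))
    return free, bound, truth


def make_monolayer_series(pi_c_true: float = 28.0, slope: float = -0.7,
                          n_points: int = 6, noise: float = 0.2,
                          construct: str = "WT",
                          seed: int = 0) -> tuple[PenetrationSeries, dict]:
    """Linear Δπ(π₀) series with known x-intercept plus Gaussian noise.

    π₀ values span [10, π_c − 2] mN/m; Δπ = slope·(π₀ − π_c) + ε with
    ε ~ N(0, noise²).
    """
    if slope >= 0:
        raise ValueError("slope must be negative")
    if n_points < 3:
        raise ValueError("need at least 3 points")
    rng = np.random.default_rng(seed)
    pi0 = np.linspace(10.0, pi_c_true - 2.0, n_points)
    dpi = slope * (pi0 - pi_c_true) + rng.normal(0.0, noise, n_points)
    series = PenetrationSeries(pi0=pi0, dpi=dpi, construct=construct)
    truth = dict(kind="monolayer", seed=seed, pi_c_true=pi_c_true,
                 slope=slope, noise=noise, n_points=n_points,
                 construct=construct)
    return series, truth
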