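"""Contact counting, trajectory profiles and hydrogen-bond detection."""

import numpy as np
import pytest

from memprobe.contacts import (ContactCriteria, HBondCriteria,
                               count_contacts_frame, detect_hbonds,
                               hbond_occupancy, profile_contacts,
                               project_to_surface, residues_bonded)
from memprobe.model import (Frame, Trajectory, min_image_distance)


def contact_oracle(system, frame, cutoff=4.0):
    """O(N^2) reference: per-residue pair counts with min-image distances."""
    tails = system.role_indices("lipid_tail_carbon")
    heavies = system.role_indices("protein_heavy")
    res = system.residue_ids
    counts = {int(r): 0 for r in np.unique(res[heavies])}
    for t in tails:
        for h in heavies:
            d = min_image_distance(frame.coordinates[t], frame.coordinates[h],
                                   frame.box)
            if d < cutoff:
                counts[int(res[h])] += 1
    return counts


def random_contact_system(make_system, rng, n_atoms=50):
    n_tail = rng.integers(5, n_atoms // 2)
    spec = []
    for i in range(n_tail):
        spec.append((f"T{i+1}", "C", 1, "LIP", tuple(rng.uniform(-30, 30, 3))))
    n_prot = n_atoms - n_tail
    for i in range(n_prot):
        rid = 100 + int(i // 5)
        spec.append(("CA", "C", rid, "ALA", tuple(rng.uniform(-30, 30, 3))))
    box = rng.uniform(15, 25, 3)
    return make_system(spec, box=box)


class TestContactsFrame:
    def test_single_contact(self, make_system):
        spec = [("T1", "C", 1, "LIP", (0.0, 0.0, 0.0)),
                ("CA", "C", 300, "ALA", (3.9, 0.0, 0.0)),
                ("CA", "C", 301, "ALA", (50.0, 50.0, 50.0))]
        system, frame = make_system(spec, box=(200, 200, 200))
        counts = count_contacts_frame(system, frame)
        assert counts == {300: 1, 301: 0}

    def test_boundary_is_strict(self, make_system):
        spec = [("T1", "C", 1, "LIP", (0.0, 0.0, 0.0)),
                ("CA", "C", 300, "ALA", (4.0, 0.0, 0.0))]
        system, frame = make_system(spec, box=(100, 100, 100))
        assert count_contacts_frame(system, frame)[300] == 0

    def test_no_tails_errors(self, make_system):
        system, frame = make_system([("CA", "C", 1, "ALA", (0, 0, 0))])
        with pytest.raises(ValueError, match="no lipid tails"):
            count_contacts_frame(system, frame)

    def test_matches_brute_force_on_random_systems(self, make_system):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            system, frame = random_contact_system(make_system, rng)
            assert count_contacts_frame(system, frame) == contact_oracle(system, frame)

    def test_cell_list_path_matches_brute_force(self, make_system):
        rng = np.random.default_rng(5)
        system, frame = random_contact_system(make_system, rng, n_atoms=300)
        assert len(system) > 200  # exercises the KD-tree path
        assert count_contacts_frame(system, frame) == contact_oracle(system, frame)

    def test_translation_and_wrap_invariance(self, make_system):
        rng = np.random.default_rng(9)
        system, frame = random_contact_system(make_system, rng)
        base = count_contacts_frame(system, frame)
        shifted = frame.copy()
        shifted.coordinates = frame.coordinates + rng.uniform(-50, 50, 3)
        assert count_contacts_frame(system, shifted) == base
        wrapped = frame.copy()
        wrapped.coordinates = np.mod(frame.coordinates, frame.box)
        assert count_contacts_frame(system, wrapped) == base

    def test_cutoff_monotonicity(self, make_system):
        rng = np.random.default_rng(13)
        system, frame = random_contact_system(make_system, rng)
        small = count_contacts_frame(system, frame, ContactCriteria(cutoff=4.0))
        large = count_contacts_frame(system, frame, ContactCriteria(cutoff=8.0))
        assert all(large[r] >= c for r, c in small.items())


class TestProfile:
    def test_constant_trajectory(self, make_system):
        spec = [("T1", "C", 1, "LIP", (0.0, 0.0, 0.0)),
                ("CA", "C", 300, "ALA", (3.0, 0.0, 0.0))]
        system, frame = make_system(spec, box=(50, 50, 50))
        traj = Trajectory([Frame(frame.coordinates.copy(), box=frame.box,
                                 time=i * 0.01) for i in range(10)], dt=0.01)
        prof = profile_contacts(system, traj)
        row = prof.per_residue(300)
        assert row["mean_contacts_per_frame"] == pytest.approx(1.0)
        # per-ps normalisation: per-frame mean / 10 ps
        assert row["mean_contacts_per_ps"] == pytest.approx(0.1)

    def test_alternating_counts_average(self, make_system):
        spec = [("T1", "C", 1, "LIP", (0.0, 0.0, 0.0)),
                ("CA", "C", 300, "ALA", (3.0, 0.0, 0.0)),
                ("CB", "C", 300, "ALA", (3.2, 0.0, 0.0))]
        system, frame = make_system(spec, box=(60, 60, 60))
        near = frame.coordinates.copy()
        far = frame.coordinates.copy()
        far[1:, 0] += 25.0
        frames = []
        for i in range(10):
            c = near if i % 2 else far
            frames.append(Frame(c.copy(), box=frame.box, time=i * 0.01))
        prof = profile_contacts(system, Trajectory(frames, dt=0.01))
        assert prof.per_residue(300)["mean_contacts_per_frame"] == pytest.approx(1.0)

    def test_inserted_loop_fixture_80pct_occupancy(self, make_system):
        # 3 "loop" residues near the tails in 8 of 10 frames, retracted in 2
        spec = [("T1", "C", 1, "LIP", (0.0, 0.0, 0.0)),
                ("T2", "C", 1, "LIP", (0.0, 8.0, 0.0)),
                ("T3", "C", 1, "LIP", (0.0, 16.0, 0.0))]
        for j, rid in enumerate((346, 347, 348)):
            spec.append(("CA", "C", rid, "ALA", (2.0, 8.0 * j, 0.0)))
        system, frame = make_system(spec, box=(100, 100, 100))
        near = frame.coordinates.copy()
        per_frame = count_contacts_frame(
            system, Frame(near, box=frame.box))
        far = near.copy()
        far[3:, 2] += 40.0
        frames = [Frame((near if i < 8 else far).copy(), box=frame.box,
                        time=i * 0.01) for i in range(10)]
        prof = profile_contacts(system, Trajectory(frames, dt=0.01))
        for rid in (346, 347, 348):
            assert prof.per_residue(rid)["mean_contacts_per_frame"] == \
                pytest.approx(0.8 * per_frame[rid])

    def test_synthetic_docked_loop_dominates(self, docked):
        system, traj, truth = docked
        prof = profile_contacts(system, traj)
        table = prof.table.set_index("residue_id")
        loop = truth["inserted_loop_residues"]
        others = [r for r in table.index if r not in loop]
        assert min(table.loc[loop, "mean_contacts_per_frame"]) > \
            max(table.loc[others, "mean_contacts_per_frame"])


class TestSurfaceProjection:
    def test_clamping_to_colour_scale(self, make_system):
        import pandas as pd

        from memprobe.contacts import ContactProfile

        table = pd.DataFrame(dict(residue_id=[1, 2, 3], residue_name=["A"] * 3,
                                  mean_contacts_per_frame=[31, 0, 15],
                                  mean_contacts_per_ps=[3.1, 0.0, 1.5],
                                  frames_used=[10] * 3))
        out = project_to_surface(ContactProfile(table, dt_ps=10.0))
        assert list(out["surface_value"]) == pytest.approx([2.0, 0.0, 1.5])

    def test_bfactor_round_trip(self, tmp_path, make_system):
        import biotite.structure.io.pdb as pdb

        from memprobe.model import write_structure

        spec = [("CA", "C", rid, "ALA", (float(rid), 0.0, 0.0))
                for rid in (1, 2, 3)]
        system, frame = make_system(spec)
        write_structure(tmp_path / "b.pdb", system, frame,
                        b_factors=[2.0, 0.0, 1.5])
        arr = pdb.PDBFile.read(str(tmp_path / "b.pdb")).get_structure(
            model=1, extra_fields=["b_factor"])
        assert np.asarray(arr.b_factor) == pytest.approx([2.0, 0.0, 1.5], abs=0.01)


def hbond_oracle(system, frame, criteria):
    """Brute-force reference over every donor/hydrogen/acceptor triple."""
    import re

    bonds = set()
    atoms = system.atoms
    for di, d in enumerate(atoms):
        if d.element.upper() not in ("N", "O", "S", "F"):
            continue
        if not any(re.fullmatch(p, d.name) for p in criteria.donor_patterns):
            continue
        hydrogens = [j for j, h in enumerate(atoms)
                     if h.residue_id == d.residue_id and h.element.upper() == "H"
                     and h.name.upper().startswith("H")
                     and min_image_distance(frame.coordinates[di],
                                            frame.coordinates[j], frame.box) <= 1.2]
        for ai, a in enumerate(atoms):
            if ai == di or a.residue_id == d.residue_id:
                continue
            if a.element.upper() not in ("N", "O", "S", "F"):
                continue
            if not any(re.fullmatch(p, a.name) for p in criteria.acceptor_patterns):
                continue
            dda = min_image_distance(frame.coordinates[di], frame.coordinates[ai],
                                     frame.box)
            if dda > criteria.da_cutoff:
                continue
            for hi in hydrogens:
                from memprobe.model import min_image_displacement

                v1 = min_image_displacement(frame.coordinates[di],
                                            frame.coordinates[hi], frame.box)
                v2 = min_image_displacement(frame.coordinates[ai],
                                            frame.coordinates[hi], frame.box)
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if ang >= criteria.dha_min_angle:
                    bonds.add((d.atom_id, a.atom_id))
                    break
    return bonds


class TestHBonds:
    def linear_nh_o(self, make_system, angle_deg=180.0):
        # N-H...O with d(N,O)=2.9 A and the H bent off axis by (180-angle)
        theta = np.radians(180.0 - angle_deg)
        h = np.array([1.0 * np.cos(theta), 1.0 * np.sin(theta), 0.0])
        spec = [("N", "N", 1, "ALA", (0.0, 0.0, 0.0)),
                ("H", "H", 1, "ALA", tuple(h)),
                ("O", "O", 2, "SER", (2.9, 0.0, 0.0))]
        return make_system(spec)

    def test_ideal_linear_bond_detected(self, make_system):
        system, frame = self.linear_nh_o(make_system)
        bonds = detect_hbonds(system, frame)
        assert [(b.donor_atom, b.acceptor_atom) for b in bonds] == [(1, 3)]
        assert bonds[0].angle == pytest.approx(180.0, abs=1e-6)

    def test_bent_geometry_rejected(self, make_system):
        system, frame = self.linear_nh_o(make_system, angle_deg=120.0)
        assert detect_hbonds(system, frame) == []

    def test_heavy_only_mode_uses_distance_alone(self, make_system):
        system, frame = self.linear_nh_o(make_system, angle_deg=120.0)
        bonds = detect_hbonds(system, frame, HBondCriteria(heavy_only=True))
        assert any(b.donor_atom == 1 and b.acceptor_atom == 3 and b.heavy_only
                   for b in bonds)

    def test_empty_donor_table_rejected(self):
        with pytest.raises(ValueError, match="donor"):
            HBondCriteria(donor_patterns=[])

    def test_matches_brute_force_on_random_frames(self, make_system):
        rng = np.random.default_rng(77)
        crit = HBondCriteria()
        for _ in range(100):
            spec = []
            for r in range(10):  # 30 atoms: N,H,O per residue
                base = rng.uniform(0, 12, 3)
                spec.append(("N", "N", r, "ALA", tuple(base)))
                spec.append(("H1", "H", r, "ALA",
                             tuple(base + rng.uniform(-1, 1, 3) * 0.6)))
                spec.append(("O", "O", r, "ALA", tuple(rng.uniform(0, 12, 3))))
            system, frame = make_system(spec, box=(12, 12, 12))
            got = {(b.donor_atom, b.acceptor_atom)
                   for b in detect_hbonds(system, frame, crit)}
            assert got == hbond_oracle(system, frame, crit)


class TestOccupancy:
    def network(self, make_system, n_residues=11):
        """n protein residues each donating to its own ligand acceptor oxygen."""
        spec = []
        for i in range(n_residues):
            y = 10.0 * i
            spec.append(("N", "N", 270 + i, "LYS", (0.0, y, 0.0)))
            spec.append(("H", "H", 270 + i, "LYS", (1.0, y, 0.0)))
            spec.append((f"O{i+1}", "O", 400, "IP4", (2.9, y, 0.0)))
        return make_system(spec)

    def test_full_occupancy(self, make_system):
        system, frame = self.network(make_system, 2)
        traj = Trajectory([Frame(frame.coordinates.copy(), time=i * 0.01)
                           for i in range(5)], dt=0.01)
        occ = hbond_occupancy(system, traj)
        assert all(o.fraction == 1.0 for o in occ)

    def test_partial_occupancy_3_of_10(self, make_system):
        system, frame = self.network(make_system, 1)
        frames = []
        for i in range(10):
            c = frame.coordinates.copy()
            if i >= 3:
                c[2, 0] += 20.0  # move the acceptor away
            frames.append(Frame(c, time=i * 0.01))
        occ = hbond_occupancy(system, Trajectory(frames, dt=0.01))
        assert len(occ) == 1 and occ[0].fraction == pytest.approx(0.3)

    def test_persistent_11_residue_inventory(self, make_system):
        system, frame = self.network(make_system, 11)
        traj = Trajectory([Frame(frame.coordinates.copy(), time=i * 0.01)
                           for i in range(10)], dt=0.01)
        occ = hbond_occupancy(system, traj)
        got = residues_bonded(occ, min_fraction=0.10, partner_residues={400})
        assert got == list(range(270, 281))
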