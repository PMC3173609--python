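"""Spring force, pull work, pairwise energies and lipid-extraction calls."""

import numpy as np
import pytest

from memprobe.docking import MembraneFrame
from memprobe.model import AtomRecord, Frame, SystemModel, Trajectory
from memprobe.smd import (COULOMB_PREFACTOR, PN_A_TO_KJ_PER_MOL,
                          NonbondedParams, PullProtocol, PullSeries,
                          accumulate_work, decompose_pull,
                          detect_extracted_lipids, interaction_energy,
                          spring_force)
from memprobe.synth import make_extraction_snapshot, simulate_pull


class TestSpringForce:
    protocol = PullProtocol(k=500.0, v=0.5, duration=80.0, anchor0=0.0)

    def test_zero_lag_zero_force(self):
        anchor = self.protocol.anchor_at(10.0)
        assert spring_force(10.0, anchor, self.protocol) == 0.0

    def test_positive_lag(self):
        anchor = self.protocol.anchor_at(4.0)
        assert spring_force(4.0, anchor - 0.1, self.protocol) == pytest.approx(50.0)

    def test_negative_lag_sign_convention(self):
        anchor = self.protocol.anchor_at(4.0)
        assert spring_force(4.0, anchor + 0.2, self.protocol) == pytest.approx(-100.0)

    def test_outside_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            spring_force(81.0, 0.0, self.protocol)

    def test_both_standard_protocols_cover_40_A(self):
        fast = PullProtocol(k=500.0, v=1.0, duration=40.0)
        slow = PullProtocol(k=500.0, v=0.5, duration=80.0)
        assert fast.total_distance == slow.total_distance == 40.0


class TestWork:
    def test_constant_force(self):
        t = np.linspace(0, 10, 11)
        series = PullSeries(t=t, anchor_z=0.5 * t, com_z=np.zeros_like(t),
                            force=np.full_like(t, 10.0))
        w_pna, w_kj = accumulate_work(series)
        assert w_pna == pytest.approx(50.0)
        assert w_kj == pytest.approx(50.0 * PN_A_TO_KJ_PER_MOL)
        assert w_kj == pytest.approx(3.011, abs=1e-3)

    def test_zero_force(self):
        t = np.linspace(0, 10, 11)
        series = PullSeries(t=t, anchor_z=t, com_z=t, force=np.zeros_like(t))
        assert accumulate_work(series) == (0.0, 0.0)

    def test_piecewise_linear_matches_analytic(self):
        # F = 3x on [0, 2], F = 6 on [2, 5]: W = 6 + 18 = 24
        x = np.concatenate([np.linspace(0, 2, 201), np.linspace(2, 5, 301)[1:]])
        f = np.where(x <= 2, 3 * x, 6.0)
        series = PullSeries(t=x, anchor_z=x, com_z=np.zeros_like(x), force=f)
        w, _ = accumulate_work(series)
        assert w == pytest.approx(24.0, abs=1e-9)

    def test_refinement_invariance(self):
        # same linear F(anchor) sampled coarsely vs finely
        for n in (11, 101, 1001):
            x = np.linspace(0, 4, n)
            series = PullSeries(t=x, anchor_z=x, com_z=np.zeros_like(x),
                                force=2.5 * x)
            w, _ = accumulate_work(series)
            assert w == pytest.approx(2.5 * 16 / 2, abs=1e-9)

    def test_non_monotonic_anchor_rejected(self):
        t = np.array([0.0, 1.0, 2.0])
        series = PullSeries(t=t, anchor_z=np.array([0.0, 1.0, 0.5]),
                            com_z=np.zeros(3), force=np.ones(3))
        with pytest.raises(ValueError, match="monotonic"):
            accumulate_work(series)


def two_particle_system(r, q=1.0, resname="ION", sigma=3.0, eps=0.5):
    atoms = [AtomRecord(1, "Q1", "NA", 1, resname),
             AtomRecord(2, "Q2", "NA", 2, resname)]
    system = SystemModel(atoms, groups={"a": [1], "b": [2]})
    frame = Frame(np.array([[0.0, 0, 0], [r, 0.0, 0.0]]))
    params = NonbondedParams({"Q1": (q, sigma, eps), "Q2": (q, sigma, eps)})
    return system, frame, params


class TestInteractionEnergy:
    def test_coulomb_unit_charges_at_5A(self):
        system, frame, params = two_particle_system(5.0, eps=0.0)
        e = interaction_energy(system, frame, "a", "b", params)
        assert e.e_coul == pytest.approx(COULOMB_PREFACTOR / 5.0)
        assert e.e_coul == pytest.approx(277.87, abs=0.01)
        assert e.e_lj == 0.0

    def test_beyond_cutoff_is_zero(self):
        system, frame, params = two_particle_system(12.0)
        e = interaction_energy(system, frame, "a", "b", params, cutoff=10.0)
        assert e.e_lj == 0.0 and e.e_coul == 0.0

    def test_lj_closed_forms(self):
        sigma, eps = 3.2, 0.7
        for r, expected in ((sigma, 0.0), (2 ** (1 / 6) * sigma, -eps)):
            system, frame, params = two_particle_system(r, q=0.0,
                                                        sigma=sigma, eps=eps)
            e = interaction_energy(system, frame, "a", "b", params)
            assert e.e_lj == pytest.approx(expected, abs=1e-9)
            assert e.e_coul == 0.0

    def test_symmetry_in_group_order(self):
        system, frame, params = two_particle_system(4.0)
        e1 = interaction_energy(system, frame, "a", "b", params)
        e2 = interaction_energy(system, frame, "b", "a", params)
        assert e1.e_coul == pytest.approx(e2.e_coul)
        assert e1.e_lj == pytest.approx(e2.e_lj)

    def test_additive_over_partition(self):
        rng = np.random.default_rng(8)
        atoms = [AtomRecord(i + 1, f"Q{i+1}", "NA", i + 1, "ION")
                 for i in range(6)]
        system = SystemModel(atoms, groups={
            "a": [1, 2], "b": [3, 4, 5, 6], "b1": [3, 4], "b2": [5, 6]})
        frame = Frame(rng.uniform(0, 8, (6, 3)))
        params = NonbondedParams({f"Q{i+1}": (rng.uniform(-1, 1), 3.0, 0.4)
                                  for i in range(6)})
        whole = interaction_energy(system, frame, "a", "b", params)
        part = [interaction_energy(system, frame, "a", g, params)
                for g in ("b1", "b2")]
        assert whole.e_coul == pytest.approx(sum(p.e_coul for p in part))
        assert whole.e_lj == pytest.approx(sum(p.e_lj for p in part))

    def test_coulomb_linear_in_charge(self):
        system, frame, _ = two_particle_system(5.0)
        for scale in (0.5, 2.0, -1.0):
            params = NonbondedParams({"Q1": (scale, 3.0, 0.0),
                                      "Q2": (1.0, 3.0, 0.0)})
            e = interaction_energy(system, frame, "a", "b", params)
            assert e.e_coul == pytest.approx(scale * COULOMB_PREFACTOR / 5.0)

    def test_overlapping_groups_rejected(self):
        system, frame, params = two_particle_system(5.0)
        system.set_group("ab", [1, 2])
        with pytest.raises(ValueError, match="overlap"):
            interaction_energy(system, frame, "a", "ab", params)

    def test_missing_parameter_names_atom(self):
        system, frame, _ = two_particle_system(5.0)
        params = NonbondedParams({"Q1": (1.0, 3.0, 0.1)})
        with pytest.raises(KeyError, match="Q2"):
            interaction_energy(system, frame, "a", "b", params)


class TestDecomposePull:
    def build(self, lipid_rides=True):
        atoms = [AtomRecord(1, "CA", "C", 300, "ALA"),
                 AtomRecord(2, "P1", "P", 400, "IP4"),
                 AtomRecord(3, "T1", "C", 1, "LIP"),
                 AtomRecord(4, "T1", "C", 2, "LIP")]
        system = SystemModel(atoms, groups={
            "protein": [1], "PIP3": [2], "POPC": [3, 4]})
        params = NonbondedParams({"CA": (0.2, 3.0, 0.3), "P1": (-1.0, 3.5, 0.5),
                                  "T1": (0.0, 3.4, 0.4)})
        frames = []
        for i in range(10):
            z = i * 2.0
            c = np.array([[0.0, 0.0, z],  # protein rises
                          [0.0, 2.0, z],  # ligand rides along
                          [0.0, 4.0, z if lipid_rides else 0.0],  # lipid 1
                          [30.0, 30.0, 0.0]])  # distant lipid stays
            frames.append(Frame(c, time=i * 0.01))
        return system, Trajectory(frames, dt=0.01), params

    def test_coextracted_lipid_plateau(self):
        system, traj, params = self.build(lipid_rides=True)
        df = decompose_pull(system, traj, params)
        late = df.iloc[-1]
        assert late["lj_protein_lipid"] != 0.0
        assert np.allclose(df["lj_protein_lipid"], df["lj_protein_lipid"].iloc[0])

    def test_separated_groups_zero(self):
        system, traj, params = self.build(lipid_rides=False)
        df = decompose_pull(system, traj, params)
        assert df.iloc[-1]["lj_protein_lipid"] == 0.0
        assert df.iloc[-1]["coul_protein_lipid"] == 0.0

    def test_framewise_consistency_with_interaction_energy(self):
        system, traj, params = self.build()
        df = decompose_pull(system, traj, params)
        e0 = interaction_energy(system, traj.frames[0], "protein", "PIP3", params)
        assert df.iloc[0]["lj_protein_ligand"] == e0.e_lj
        assert df.iloc[0]["coul_protein_ligand"] == e0.e_coul


class TestExtractionDetection:
    mframe = MembraneFrame(leaflet_upper_z=20.0, leaflet_lower_z=-20.0,
                           midplane_z=0.0)

    def lipid_at(self, com_z):
        atoms = [AtomRecord(1, "P", "P", 1, "LIP"),
                 AtomRecord(2, "T1", "C", 1, "LIP")]
        system = SystemModel(atoms)
        from memprobe.model import classify_atoms

        classify_atoms(system)
        masses = system.masses
        # place both atoms so the mass-weighted COM z equals com_z
        frame = Frame(np.array([[0.0, 0, com_z], [0.0, 0, com_z]]))
        return system, frame

    def test_fully_extracted(self):
        system, frame = self.lipid_at(35.0)  # 15 A above upper leaflet
        assert detect_extracted_lipids(system, frame, self.mframe)[1] == \
            "fully_extracted"

    def test_at_leaflet_level_in_bilayer(self):
        system, frame = self.lipid_at(20.0)
        assert detect_extracted_lipids(system, frame, self.mframe)[1] == \
            "in_bilayer"

    def test_partial_band(self):
        system, frame = self.lipid_at(26.0)
        assert detect_extracted_lipids(system, frame, self.mframe)[1] == \
            "partially_extracted"

    def test_staged_snapshot_one_full_one_partial(self):
        system, frame, mframe, truth = make_extraction_snapshot(seed=4)
        classes = detect_extracted_lipids(system, frame, mframe)
        full = [r for r, c in classes.items() if c == "fully_extracted"]
        partial = [r for r, c in classes.items() if c == "partially_extracted"]
        assert full == truth["fully_extracted"]
        assert partial == truth["partially_extracted"]


class TestSimulatedPull:
    def test_force_ramps_linearly_then_drops(self):
        protocol = PullProtocol(k=500.0, v=0.5, duration=80.0)
        series, truth = simulate_pull(protocol, tether_k=50.0,
                                      rupture_force=400.0, dt=0.05)
        i_rup = int(np.flatnonzero(series.t == truth["t_rupture"])[0])
        # pre-rupture: F(t) = k*kt/(k+kt) * v * t (quasi-static balance)
        expect = truth["force_ramp_pN_per_ns"] * series.t[: i_rup + 1]
        assert series.force[: i_rup + 1] == pytest.approx(expect, abs=1e-9)
        assert series.force.max() <= 400.0 + truth["force_ramp_pN_per_ns"] * 0.05

    def test_post_rupture_force_decays_to_zero(self):
        series, truth = simulate_pull(rupture_force=300.0)
        assert truth["t_rupture"] is not None
        assert abs(series.force[-1]) < 1.0

    def test_work_is_positive_and_finite(self):
        series, _ = simulate_pull()
        w_pna, w_kj = accumulate_work(series)
        assert w_pna > 0
        assert np.isfinite(w_kj)
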